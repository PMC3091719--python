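"""SSR detection, canonicalisation, filtering, merging and ePCR."""

import numpy as np
import pytest

from ssrbinmap.io_formats import SequenceRecord
from ssrbinmap.pedigree_sim import plant_ssr_unigenes
from ssrbinmap.ssr_miner import (
    MiningConfig, SSRLocus, canonical_motif, class_share_pct, electronic_pcr,
    filter_end_proximity, find_tandem_repeats, merge_adjacent, mine_unigenes,
    revcomp, ssr_frequency_pct, summarize_catalog,
)

from oracles import brute_force_ssrs, epcr_scan_oracle, transitive_merge_oracle

CFG = MiningConfig()


class TestDetection:
    def test_pure_repeat(self):
        (loc,) = find_tandem_repeats("ACACACACACAC")
        assert (loc.start, loc.end, loc.unit, loc.n_repeats) == (0, 12, "AC", 6)

    def test_below_threshold_is_silent(self):
        assert find_tandem_repeats("ATATATAT") == []  # 4 < 5 dimer repeats

    def test_primitive_unit_only(self):
        loci = find_tandem_repeats("AGAGAGAGAGAG")
        assert [(l.unit, l.n_repeats) for l in loci] == [("AG", 6)]

    def test_homopolymer_never_reported(self):
        assert find_tandem_repeats("A" * 40) == []

    def test_run_with_n_excluded(self):
        assert find_tandem_repeats("ACACACNACACAC") == []

    def test_partial_trailing_unit_trimmed(self):
        (loc,) = find_tandem_repeats("T" * 0 + "ACGACGACGACGAC" + "TT")
        # 4 whole ACG units plus a partial "AC" tail
        assert (loc.start, loc.end, loc.n_repeats) == (0, 12, 4)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(150):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            got = [(l.start, l.end, l.unit) for l in find_tandem_repeats(seq, CFG)]
            assert got == brute_force_ssrs(seq, CFG)

    def test_strand_symmetry_of_class_counts(self, rng):
        records = [
            SequenceRecord(f"u{i}", "".join(rng.choice(list("ACGT"), size=800)))
            for i in range(60)
        ]
        flipped = [SequenceRecord(r.id, revcomp(r.sequence)) for r in records]
        _, fwd = mine_unigenes(records)
        _, rev = mine_unigenes(flipped)
        assert fwd.counts_by_unit_len == rev.counts_by_unit_len
        assert fwd.motif_class_counts == rev.motif_class_counts
        assert fwd.pct_by_unit_len == rev.pct_by_unit_len


class TestCanonicalMotif:
    @pytest.mark.parametrize("unit,expected", [
        ("GA", "AG"), ("TC", "AG"), ("CT", "AG"),
        ("CTT", "AAG"), ("AT", "AT"), ("ACC", "ACC"), ("GGT", "ACC"),
    ])
    def test_examples(self, unit, expected):
        assert canonical_motif(unit) == expected

    def test_dimer_classes_are_exactly_four(self):
        dimers = {a + b for a in "ACGT" for b in "ACGT" if a != b}
        assert {canonical_motif(u) for u in dimers} == {"AC", "AG", "AT", "CG"}

    def test_trimer_classes_number_ten(self):
        from ssrbinmap.ssr_miner import is_primitive
        trimers = {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"}
        classes = {canonical_motif(u) for u in trimers if is_primitive(u)}
        assert len(classes) == 10

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            canonical_motif("AN")


class TestEndFilterAndMerge:
    def _locus(self, start, end, unit="AC"):
        n = (end - start) // len(unit)
        return SSRLocus("u", start, end, unit, canonical_motif(unit),
                        len(unit), n)

    @pytest.mark.parametrize("span,kept", [
        ((20, 32), False),   # too close to the 5' end
        ((35, 47), True),    # boundary inclusive
        ((460, 472), False),  # 500 - 472 = 28 < 35
        ((453, 465), True),   # 500 - 465 = 35 exactly
    ])
    def test_end_margin_boundaries(self, span, kept):
        loci = [self._locus(*span)]
        out = filter_end_proximity(loci, seq_len=500, end_margin=35)
        assert (len(out) == 1) is kept

    def test_merge_close_pair(self):
        loci = [self._locus(10, 20), self._locus(25, 35)]
        (merged,) = merge_adjacent(loci, 30)
        assert merged.compound and (merged.start, merged.end) == (10, 35)
        assert len(merged.members) == 2

    def test_gap_exactly_30_not_merged(self):
        loci = [self._locus(10, 20), self._locus(50, 60)]
        assert len(merge_adjacent(loci, 30)) == 2

    def test_chain_merges_transitively(self):
        loci = [self._locus(0, 10), self._locus(20, 30), self._locus(40, 50)]
        (merged,) = merge_adjacent(loci, 30)
        assert (merged.start, merged.end) == (0, 50)

    def test_merge_matches_union_find_oracle(self, rng):
        for _ in range(50):
            starts = np.sort(rng.choice(2000, size=8, replace=False))
            spans = [(int(s), int(s) + 10) for s in starts]
            loci = [self._locus(s, e) for s, e in spans]
            got = [(l.start, l.end) for l in merge_adjacent(loci, 30)]
            assert sorted(got) == transitive_merge_oracle(spans, 30)

    def test_merging_never_increases_count(self, rng):
        starts = np.sort(rng.choice(500, size=6, replace=False))
        loci = [self._locus(int(s), int(s) + 10) for s in starts]
        assert len(merge_adjacent(loci, 30)) <= len(loci)


class TestMineUnigenes:
    def test_planted_catalog_recovered_exactly(self, rng):
        spec = {0: [("AAG", 5, 50)], 2: [("AC", 6, 100), ("AGC", 4, 200)]}
        records, truth = plant_ssr_unigenes(4, spec, rng, seq_len=300)
        catalog, summary = mine_unigenes(records)
        got = sorted((l.unigene_id, l.start, l.end) for l in catalog)
        want = sorted((l.unigene_id, l.start, l.end) for l in truth)
        assert got == want
        assert summary.n_ssrs_total == 3
        assert summary.n_sequences_with_ssr == 2

    def test_planted_close_pair_reported_compound(self, rng):
        spec = {0: [("AC", 5, 100), ("AC", 5, 120)]}  # 10-nt gap < 30
        records, _ = plant_ssr_unigenes(1, spec, rng, seq_len=300)
        catalog, summary = mine_unigenes(records)
        (loc,) = catalog
        assert loc.compound and (loc.start, loc.end) == (100, 130)
        assert summary.n_compound == 1

    def test_background_without_plants_is_clean(self, rng):
        records, truth = plant_ssr_unigenes(5, {}, rng, seq_len=400)
        catalog, _ = mine_unigenes(records)
        assert catalog == [] and truth == []

    def test_class_counts_sum_to_total(self, rng):
        records = [
            SequenceRecord(f"u{i}", "".join(rng.choice(list("ACGT"), size=1000)))
            for i in range(80)
        ]
        catalog, summary = mine_unigenes(records)
        assert (sum(summary.counts_by_unit_len.values()) + summary.n_compound
                == summary.n_ssrs_total == len(catalog))

    def test_summary_reporting_precision(self):
        assert ssr_frequency_pct(5218, 28024) == 18.6
        assert class_share_pct(2212, 5218) == 42


class TestElectronicPCR:
    F = "ACGTACGTACGTACG"   # 15-mers
    R = "TTGCATGCATGCATG"

    def _template(self, rng, f_at, r_end):
        seq = list(rng.choice(list("ACGT"), size=400))
        rc = revcomp(self.R)
        seq[f_at:f_at + 15] = list(self.F)
        seq[r_end - 15:r_end] = list(rc)
        return "".join(seq)

    def test_constructed_placement(self, rng):
        rec = SequenceRecord("t", self._template(rng, 100, 260))
        hits = electronic_pcr(self.F, self.R, [rec])
        assert ("t", 100, 260, 160) in hits

    def test_no_match_is_empty(self, rng):
        rec = SequenceRecord("t", "".join(rng.choice(list("AC"), size=200)))
        assert electronic_pcr(self.F, self.R, [rec]) == []

    def test_two_forward_sites_give_two_products(self, rng):
        seq = list(rng.choice(list("ACGT"), size=400))
        rc = revcomp(self.R)
        seq[20:35] = list(self.F)
        seq[120:135] = list(self.F)
        seq[300:315] = list(rc)
        rec = SequenceRecord("t", "".join(seq))
        hits = electronic_pcr(self.F, self.R, [rec])
        spans = {(h[1], h[2]) for h in hits}
        assert {(20, 315), (120, 315)} <= spans
        oracle = set(epcr_scan_oracle(rec.sequence, self.F, rc))
        assert spans == oracle

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            electronic_pcr("ACGT", self.R, [])


class TestCanonicalMotifProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    units = st.text(alphabet="ACGT", min_size=2, max_size=6)

    @given(unit=units)
    @settings(max_examples=200, deadline=None)
    def test_invariant_under_rotation_and_revcomp(self, unit):
        from hypothesis import assume
        assume(len(set(unit)) > 1)
        classes = {canonical_motif(unit[i:] + unit[:i]) for i in range(len(unit))}
        classes |= {canonical_motif(revcomp(unit))}
        assert classes == {canonical_motif(unit)}

    @given(unit=units)
    @settings(max_examples=200, deadline=None)
    def test_canonical_is_idempotent_and_in_class(self, unit):
        from hypothesis import assume
        assume(len(set(unit)) > 1)
        canon = canonical_motif(unit)
        assert canonical_motif(canon) == canon
        rotations = {unit[i:] + unit[:i] for i in range(len(unit))}
        rc = revcomp(unit)
        rotations |= {rc[i:] + rc[:i] for i in range(len(rc))}
        assert canon in rotations
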