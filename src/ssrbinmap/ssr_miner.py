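"""Perfect microsatellite (SSR) mining in unigene sequences.

Detection finds every *maximal perfect* tandem run of a primitive unit of
length 2-6 whose repeat count reaches a per-unit-length threshold
(defaults: 5 for di-, 4 for tri-, 3 for tetra-/penta-/hexanucleotides).
Runs touching a sequence end closer than ``end_margin`` (default 35 nt,
too little flank left for primer design) are discarded, and surviving runs
separated by less than ``merge_gap`` (default 30 nt) are merged into a
single compound locus.  Motifs are reported under their canonical class:
the lexicographic minimum over all cyclic rotations of the unit and of its
reverse complement, so e.g. GA/TC/CT/AG all collapse to AG and the dimer
classes are exactly {AC, AG, AT, CG}.

An electronic-PCR scan over a template collection is included to test
primer-pair transferability in silico.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import SequenceRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Minimum repeat counts per unit length: di >= 5, tri >= 4, tetra/penta/hexa >= 3.
DEFAULT_MIN_REPEATS: Mapping[int, int] = {2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds governing SSR detection, end filtering and merging."""

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    end_margin: int = 35
    merge_gap: int = 30

    def __post_init__(self) -> None:
        for unit_len, count in self.min_repeats.items():
            if not 2 <= unit_len <= 6:
                raise ValueError(f"unit length {unit_len} outside 2..6")
            if count < 2:
                raise ValueError(f"min repeat count {count} < 2 for unit length {unit_len}")
        if self.end_margin < 0 or self.merge_gap < 0:
            raise ValueError("margins must be >= 0")


@dataclass(frozen=True)
class SSRLocus:
    """One detected repeat run, 0-based half-open on its unigene.

    For a simple locus ``end - start == unit_len * n_repeats`` and the unit
    is primitive.  A compound locus spans several merged runs; it carries no
    single motif (``canonical`` is None) and keeps its constituents in
    ``members``.
    """

    unigene_id: str
    start: int
    end: int
    unit: str
    canonical: str | None
    unit_len: int
    n_repeats: int
    compound: bool = False
    members: tuple["SSRLocus", ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


def is_primitive(unit: str) -> bool:
    """True iff *unit* is not itself a repetition of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def canonical_motif(unit: str) -> str:
    """Canonical motif class: min over rotations of unit and its revcomp."""
    if not unit or any(c not in "ACGT" for c in unit):
        raise ValueError(f"motif {unit!r} is not a plain ACGT string")
    candidates = []
    rc = revcomp(unit)
    for s in (unit, rc):
        candidates.extend(s[i:] + s[:i] for i in range(len(s)))
    return min(candidates)


def find_tandem_repeats(
    seq: str, config: MiningConfig | None = None, unigene_id: str = ""
) -> list[SSRLocus]:
    """All maximal perfect tandem runs with primitive unit length 2-6.

    The run is reported at its longest perfect extent; a trailing partial
    unit is excluded from the span so ``end - start`` is a whole number of
    units.  Runs containing N are excluded.  Output is sorted by start.
    """
    config = config or MiningConfig()
    seq = seq.upper()
    L = len(seq)
    loci: list[SSRLocus] = []
    for unit_len, threshold in sorted(config.min_repeats.items()):
        limit = L - unit_len
        j = 0
        while j < limit:
            if seq[j] != seq[j + unit_len]:
                j += 1
                continue
            run_start = j
            while j < limit and seq[j] == seq[j + unit_len]:
                j += 1
            run_len = (j - run_start) + unit_len  # includes partial tail
            n_rep = run_len // unit_len
            if n_rep < threshold:
                continue
            unit = seq[run_start:run_start + unit_len]
            end = run_start + unit_len * n_rep
            if not is_primitive(unit):
                continue
            if "N" in seq[run_start:end]:
                continue
            loci.append(SSRLocus(
                unigene_id=unigene_id,
                start=run_start,
                end=end,
                unit=unit,
                canonical=canonical_motif(unit),
                unit_len=unit_len,
                n_repeats=n_rep,
            ))
    loci.sort(key=lambda l: (l.start, l.end, l.unit_len))
    return loci


def filter_end_proximity(
    loci: Iterable[SSRLocus], seq_len: int, end_margin: int = 35
) -> list[SSRLocus]:
    """Keep a locus iff start >= margin and seq_len - end >= margin.

    Boundary inclusive: a locus starting exactly at ``end_margin`` is kept.
    """
    return [
        loc for loc in loci
        if loc.start >= end_margin and seq_len - loc.end >= end_margin
    ]


def merge_adjacent(loci: Sequence[SSRLocus], merge_gap: int = 30) -> list[SSRLocus]:
    """Merge runs separated by less than *merge_gap* nt (strict inequality).

    Merging is the transitive closure over the sorted runs: any chain of
    runs with pairwise gaps below the threshold collapses into one compound
    locus spanning the union, which counts once in all summaries.
    """
    ordered = sorted(loci, key=lambda l: (l.start, l.end))
    merged: list[SSRLocus] = []
    group: list[SSRLocus] = []
    group_end = -1

    def flush() -> None:
        if not group:
            return
        if len(group) == 1:
            merged.append(group[0])
        else:
            merged.append(SSRLocus(
                unigene_id=group[0].unigene_id,
                start=group[0].start,
                end=max(l.end for l in group),
                unit="",
                canonical=None,
                unit_len=0,
                n_repeats=0,
                compound=True,
                members=tuple(group),
            ))

    for loc in ordered:
        if group and loc.start - group_end < merge_gap:
            group.append(loc)
            group_end = max(group_end, loc.end)
        else:
            flush()
            group = [loc]
            group_end = loc.end
    flush()
    return merged


# -- summaries -----------------------------------------------------------

def ssr_frequency_pct(n_ssrs: int, n_sequences: int) -> float:
    """SSR frequency in percent, one decimal (multiple hits per sequence count)."""
    if n_sequences <= 0:
        raise ValueError("n_sequences must be positive")
    return round(100.0 * n_ssrs / n_sequences, 1)


def class_share_pct(n_class: int, n_total: int) -> int:
    """Share of one SSR class in percent, rounded to the nearest integer."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return int(math.floor(100.0 * n_class / n_total + 0.5))


@dataclass
class MiningSummary:
    """Catalogue-level counts and reporting-precision percentages.

    Per-unit-length counts cover simple loci; compound loci (motif class
    ambiguous) are tallied separately under ``n_compound``.  All counts sum
    to ``n_ssrs_total``.
    """

    n_sequences: int
    n_sequences_with_ssr: int
    n_ssrs_total: int
    counts_by_unit_len: dict[int, int]
    n_compound: int
    pct_by_unit_len: dict[int, int]
    motif_class_counts: dict[int, Counter]
    ssr_frequency_pct: float


def summarize_catalog(catalog: Sequence[SSRLocus], n_sequences: int) -> MiningSummary:
    counts: dict[int, int] = {u: 0 for u in range(2, 7)}
    motif_counts: dict[int, Counter] = {u: Counter() for u in range(2, 7)}
    n_compound = 0
    for loc in catalog:
        if loc.compound:
            n_compound += 1
        else:
            counts[loc.unit_len] += 1
            motif_counts[loc.unit_len][loc.canonical] += 1
    total = len(catalog)
    pct = {u: class_share_pct(c, total) if total else 0 for u, c in counts.items()}
    return MiningSummary(
        n_sequences=n_sequences,
        n_sequences_with_ssr=len({loc.unigene_id for loc in catalog}),
        n_ssrs_total=total,
        counts_by_unit_len=counts,
        n_compound=n_compound,
        pct_by_unit_len=pct,
        motif_class_counts=motif_counts,
        ssr_frequency_pct=ssr_frequency_pct(total, n_sequences) if total else 0.0,
    )


def mine_unigenes(
    records: Sequence[SequenceRecord], config: MiningConfig | None = None
) -> tuple[list[SSRLocus], MiningSummary]:
    """Run the detect -> end-filter -> merge pipeline over a unigene set."""
    if not records:
        raise ValueError("mine_unigenes requires a non-empty record list")
    config = config or MiningConfig()
    catalog: list[SSRLocus] = []
    for rec in records:
        loci = find_tandem_repeats(rec.sequence, config, unigene_id=rec.id)
        loci = filter_end_proximity(loci, len(rec.sequence), config.end_margin)
        loci = merge_adjacent(loci, config.merge_gap)
        catalog.extend(loci)
    return catalog, summarize_catalog(catalog, len(records))


# -- electronic PCR ------------------------------------------------------

def _match_positions(template: str, probe: str, max_mismatch: int) -> list[int]:
    k = len(probe)
    if max_mismatch == 0:
        out = []
        i = template.find(probe)
        while i != -1:
            out.append(i)
            i = template.find(probe, i + 1)
        return out
    out = []
    for i in range(len(template) - k + 1):
        mm = 0
        for a, b in zip(template[i:i + k], probe):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            out.append(i)
    return out


def electronic_pcr(
    forward: str,
    reverse: str,
    records: Sequence[SequenceRecord],
    max_mismatch: int = 0,
) -> list[tuple[str, int, int, int]]:
    """In-silico PCR: all (record_id, start, end, product_size) placements.

    The forward primer must match the template and the reverse primer's
    reverse complement must match downstream of it, each with at most
    *max_mismatch* mismatches.  The product spans both primer footprints
    (``product_size = end - start``).  Every valid placement per template is
    reported, so one primer pair can yield several products.
    """
    forward = forward.upper()
    reverse = reverse.upper()
    if len(forward) < 15 or len(reverse) < 15:
        raise ValueError("primers must be at least 15 nt long")
    rc = revcomp(reverse)
    hits: list[tuple[str, int, int, int]] = []
    for rec in records:
        f_starts = _match_positions(rec.sequence, forward, max_mismatch)
        r_starts = _match_positions(rec.sequence, rc, max_mismatch)
        for i in f_starts:
            for j in r_starts:
                if j >= i + len(forward):
                    end = j + len(rc)
                    hits.append((rec.id, i, end, end - i))
    return hits
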