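"""Synthetic full-sib pedigrees and unigene sets with known truth.

The generator emulates the study design this pipeline targets: an outbred
F1 family genotyped under the two-way pseudo-testcross strategy, with 12
linkage groups per parental map, ~64 framework markers per map (a few of
them fully informative ab x cd anchors shared by both maps), 278
offspring, ~5% missing calls and ~1% genotyping error.  Meiosis follows a
no-interference model: crossover counts per group are Poisson with mean
length/100 Morgan and positions are uniform, so true recombination
fractions obey the Haldane map function.

A companion generator plants SSR motifs into otherwise SSR-free random
sequences (verified by rejection sampling against the miner itself run on
the assembled sequence), giving a ground-truth catalogue for the mining
stage.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeTable, SequenceRecord, validate_map
from .ssr_miner import MiningConfig, SSRLocus, canonical_motif, find_tandem_repeats, is_primitive

#: Segregation-type mix for simulated test markers (female testcross, male
#: testcross, fully informative outcross, intercross), matching a realistic
#: EST-derived marker panel where roughly half the loci are informative in
#: both parents and 1:2:1 loci are rare.
DEFAULT_SEG_MIX: Mapping[str, float] = {
    "lmxll": 77 / 283,
    "nnxnp": 65 / 283,
    "abxcd": 135 / 283,
    "hkxhk": 6 / 283,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic full-sib family."""

    n_lg: int = 12
    lg_length_cM: float = 75.0
    n_framework_per_map: int = 64
    anchors_per_lg: int = 2
    n_offspring: int = 278
    seg_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEG_MIX)
    )
    missing_rate: float = 0.05
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.seg_mix.values()) - 1.0) > 1e-9:
            raise ValueError("seg_mix proportions must sum to 1")
        for rate in (self.missing_rate, self.error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_lg < 1 or self.n_offspring < 1:
            raise ValueError("n_lg and n_offspring must be positive")


@dataclass(frozen=True)
class Gamete:
    """Phase of one transmitted gamete along one linkage group."""

    start_allele: int
    crossovers: tuple[float, ...]  # sorted cM positions

    def allele_at(self, pos: float) -> int:
        return self.start_allele ^ (bisect_right(self.crossovers, pos) & 1)


@dataclass
class TruthSet:
    """Everything the simulator knows that the pipeline must recover."""

    config: SimConfig
    map_f: pd.DataFrame
    map_m: pd.DataFrame
    anchor_ids: list[str]
    #: gametes[(parent, lg)] -> list of Gamete, one per offspring.
    gametes: dict[tuple[str, int], list[Gamete]]
    #: calls before the error/missing masks were applied.
    true_calls: pd.DataFrame
    #: marker metadata: seg_type, lg, position (cM); framework and test markers.
    marker_info: pd.DataFrame

    def allele(self, parent: str, lg: int, pos: float, offspring_index: int) -> int:
        return self.gametes[(parent, lg)][offspring_index].allele_at(pos)


# -- parental maps -------------------------------------------------------

def _per_group_counts(total: int, n_lg: int) -> list[int]:
    base, extra = divmod(total, n_lg)
    return [base + (1 if g < extra else 0) for g in range(n_lg)]


def simulate_parental_maps(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Draw female and male framework maps sharing ab x cd anchor markers.

    Marker positions are uniform on [0, lg_length] per group, then sorted.
    Anchors sit at identical positions on homologous groups of both maps.
    """
    counts = _per_group_counts(config.n_framework_per_map, config.n_lg)
    rows_f, rows_m, anchors = [], [], []
    for g in range(1, config.n_lg + 1):
        total = counts[g - 1]
        n_anchor = min(config.anchors_per_lg, total)
        n_specific = total - n_anchor
        apos = rng.uniform(0.0, config.lg_length_cM, size=n_anchor)
        for k, p in enumerate(sorted(apos), start=1):
            mid = f"X{g}_{k}"
            anchors.append(mid)
            rows_f.append((g, mid, p))
            rows_m.append((g, mid, p))
        fpos = rng.uniform(0.0, config.lg_length_cM, size=n_specific)
        for k, p in enumerate(sorted(fpos), start=1):
            rows_f.append((g, f"F{g}_{k}", p))
        mpos = rng.uniform(0.0, config.lg_length_cM, size=n_specific)
        for k, p in enumerate(sorted(mpos), start=1):
            rows_m.append((g, f"M{g}_{k}", p))
    cols = ["linkage_group", "marker", "position"]
    map_f = validate_map(pd.DataFrame(rows_f, columns=cols))
    map_m = validate_map(pd.DataFrame(rows_m, columns=cols))
    return map_f, map_m, anchors


# -- meiosis -------------------------------------------------------------

def simulate_gamete(length_cM: float, rng: np.random.Generator) -> Gamete:
    """One gamete under no-interference meiosis.

    Crossover count ~ Poisson(length/100), positions uniform on the group,
    starting phase a fair coin.  Adjacent positions d cM apart therefore
    recombine at the Haldane rate r = (1 - exp(-d/50)) / 2.
    """
    n_x = int(rng.poisson(length_cM / 100.0))
    pos = np.sort(rng.uniform(0.0, length_cM, size=n_x))
    return Gamete(start_allele=int(rng.integers(0, 2)),
                  crossovers=tuple(float(p) for p in pos))


def _encode_framework_call(seg_type: str, f_allele: int | None,
                           m_allele: int | None) -> str:
    if seg_type == "lmxll":
        return "lm" if f_allele else "ll"
    if seg_type == "nnxnp":
        return "np" if m_allele else "nn"
    if seg_type == "abxcd":
        return ("b" if f_allele else "a") + ("d" if m_allele else "c")
    if seg_type == "hkxhk":
        total = (f_allele or 0) + (m_allele or 0)
        return {0: "hh", 1: "hk", 2: "kk"}[total]
    raise ValueError(seg_type)


def _apply_noise(calls: pd.DataFrame, seg_type: pd.Series,
                 error_rate: float, missing_rate: float,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Symmetric call flips at error_rate, then a missing mask."""
    from .io_formats import SEG_TYPES

    noisy = calls.copy()
    n_m, n_i = noisy.shape
    err = rng.random((n_m, n_i)) < error_rate
    miss = rng.random((n_m, n_i)) < missing_rate
    values = noisy.to_numpy()
    for r in range(n_m):
        legal = sorted(SEG_TYPES[seg_type.iloc[r]])
        for c in range(n_i):
            if err[r, c]:
                others = [x for x in legal if x != values[r, c]]
                values[r, c] = others[int(rng.integers(0, len(others)))]
            if miss[r, c]:
                values[r, c] = MISSING
    return pd.DataFrame(values, index=noisy.index, columns=noisy.columns)


def simulate_fullsib(config: SimConfig) -> tuple[GenotypeTable, TruthSet]:
    """Simulate a full-sib family genotyped at the framework markers.

    Each offspring is one female plus one male gamete per linkage group.
    Parent-specific framework markers are testcross (lm x ll on the female
    map, nn x np on the male map); shared anchors are ab x cd and
    informative for both parents.  A symmetric call-flip error and a
    missing mask are applied after encoding; the truth (maps, gametes and
    pre-noise calls) is retained.
    """
    rng = np.random.default_rng(config.seed)
    map_f, map_m, anchors = simulate_parental_maps(config, rng)
    anchor_set = set(anchors)
    individuals = [f"ind{i:03d}" for i in range(config.n_offspring)]

    gametes: dict[tuple[str, int], list[Gamete]] = {}
    for parent in ("F", "M"):
        for g in range(1, config.n_lg + 1):
            gametes[(parent, g)] = [
                simulate_gamete(config.lg_length_cM, rng)
                for _ in range(config.n_offspring)
            ]

    marker_rows = []
    call_rows: dict[str, list[str]] = {}
    seg_types: dict[str, str] = {}
    for map_df, parent in ((map_f, "F"), (map_m, "M")):
        for row in map_df.itertuples(index=False):
            mid = row.marker
            if mid in call_rows:  # anchors appear on both maps; encode once
                continue
            g, pos = int(row.linkage_group), float(row.position)
            if mid in anchor_set:
                st = "abxcd"
            elif parent == "F":
                st = "lmxll"
            else:
                st = "nnxnp"
            seg_types[mid] = st
            marker_rows.append((mid, st, g, pos, True))
            fg = gametes[("F", g)]
            mg = gametes[("M", g)]
            call_rows[mid] = [
                _encode_framework_call(st, fg[i].allele_at(pos), mg[i].allele_at(pos))
                for i in range(config.n_offspring)
            ]

    true_calls = pd.DataFrame.from_dict(call_rows, orient="index",
                                        columns=individuals)
    seg_series = pd.Series(seg_types).loc[true_calls.index]
    noisy = _apply_noise(true_calls, seg_series, config.error_rate,
                         config.missing_rate, rng)
    table = GenotypeTable(
        calls=noisy,
        seg_type=seg_series.copy(),
        phase=pd.Series("coupling", index=true_calls.index),
    )
    marker_info = pd.DataFrame(
        marker_rows, columns=["marker", "seg_type", "lg", "position", "framework"]
    ).set_index("marker")
    truth = TruthSet(
        config=config,
        map_f=map_f,
        map_m=map_m,
        anchor_ids=anchors,
        gametes=gametes,
        true_calls=true_calls,
        marker_info=marker_info,
    )
    return table, truth


def simulate_test_markers(
    truth: TruthSet,
    n_markers: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Additional markers at random true positions, typed by the seg mix.

    Calls are derived from the stored gametes of the same meioses, then
    degraded with the configured error and missing rates.  Returns the
    genotype table and a truth frame (marker, seg_type, lg, position).
    The new markers are appended to ``truth.marker_info``.
    """
    config = truth.config
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(config.seed + 1 if rng is None else rng)
    individuals = list(truth.true_calls.columns)
    seg_names = list(config.seg_mix)
    seg_p = np.array([config.seg_mix[s] for s in seg_names])
    rows: dict[str, list[str]] = {}
    seg_types: dict[str, str] = {}
    info_rows = []
    for j in range(n_markers):
        mid = f"T{j:03d}"
        st = seg_names[int(rng.choice(len(seg_names), p=seg_p))]
        g = int(rng.integers(1, config.n_lg + 1))
        pos = float(rng.uniform(0.0, config.lg_length_cM))
        fg = truth.gametes[("F", g)]
        mg = truth.gametes[("M", g)]
        rows[mid] = [
            _encode_framework_call(st, fg[i].allele_at(pos), mg[i].allele_at(pos))
            for i in range(len(individuals))
        ]
        seg_types[mid] = st
        info_rows.append((mid, st, g, pos, False))
    true_calls = pd.DataFrame.from_dict(rows, orient="index", columns=individuals)
    seg_series = pd.Series(seg_types).loc[true_calls.index]
    noisy = _apply_noise(true_calls, seg_series, config.error_rate,
                         config.missing_rate, rng)
    table = GenotypeTable(
        calls=noisy,
        seg_type=seg_series.copy(),
        phase=pd.Series("coupling", index=true_calls.index),
    )
    info = pd.DataFrame(
        info_rows, columns=["marker", "seg_type", "lg", "position", "framework"]
    ).set_index("marker")
    truth.marker_info = pd.concat([truth.marker_info, info])
    return table, info


# -- SSR fixture generator ----------------------------------------------

def plant_ssr_unigenes(
    n_seqs: int,
    plant_spec: Mapping[int, Sequence[tuple[str, int, int]]],
    rng: np.random.Generator,
    seq_len: int = 500,
    config: MiningConfig | None = None,
    max_tries: int = 500,
) -> tuple[list[SequenceRecord], list[SSRLocus]]:
    """Random sequences carrying exactly the planted SSRs and nothing else.

    *plant_spec* maps a sequence index to (motif, n_repeats, start) triples.
    Each sequence is drawn, the motifs are written in, and the assembled
    sequence is re-mined: if detection does not recover exactly the planted
    spans (an unplanned run appeared, or a junction extended a planted
    one), the background is redrawn.  Motifs must be primitive and reach
    the detection threshold, and spans must fit and not overlap.
    """
    config = config or MiningConfig()
    alphabet = np.array(list("ACGT"))
    records: list[SequenceRecord] = []
    catalog: list[SSRLocus] = []
    for idx in range(n_seqs):
        plants = list(plant_spec.get(idx, ()))
        expected = []
        for motif, reps, start in plants:
            motif = motif.upper()
            if not is_primitive(motif) or not 2 <= len(motif) <= 6:
                raise ValueError(f"motif {motif!r} must be primitive, length 2-6")
            if reps < config.min_repeats[len(motif)]:
                raise ValueError(
                    f"{motif} x {reps} is below the detection threshold"
                )
            end = start + len(motif) * reps
            if start < 0 or end > seq_len:
                raise ValueError(
                    f"planted run [{start},{end}) does not fit in {seq_len} nt"
                )
            expected.append((start, end, motif))
        expected.sort()
        for a, b in zip(expected, expected[1:]):
            if b[0] < a[1]:
                raise ValueError("planted runs overlap")

        rec_id = f"u{idx}"
        for attempt in range(max_tries):
            seq = rng.choice(alphabet, size=seq_len)
            for start, end, motif in expected:
                run = (motif * ((end - start) // len(motif)))
                seq[start:end] = list(run)
            assembled = "".join(seq)
            found = find_tandem_repeats(assembled, config, unigene_id=rec_id)
            if [(l.start, l.end, l.unit) for l in found] == \
                    [(s, e, m) for s, e, m in expected]:
                records.append(SequenceRecord(rec_id, assembled))
                for loc in found:
                    catalog.append(loc)
                break
        else:
            raise RuntimeError(
                f"could not build sequence {idx} free of unplanned SSRs "
                f"after {max_tries} tries"
            )
    return records, catalog
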