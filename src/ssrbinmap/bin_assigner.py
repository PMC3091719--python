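"""Assign markers to bins by graphical genotyping of the bin set.

A new marker genotyped only on the bin-set individuals is matched against
every bin's genotype signature by Hamming distance (missing calls are
skipped; both global allele orientations are tried because linkage phase
is unknown).  A perfect match to exactly one bin is an exact assignment;
a profile explained by a single extra breakpoint strictly between two
adjacent bins is intermediate (both flanking codes are reported rather
than creating a new bin); otherwise the marker goes to the unique bin
implying the fewest extra double crossovers, within a cap, or is declared
ambiguous.  Markers segregating 1:2:1 cannot be phased into a parental
testcross and are excluded up front.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bin_builder import Bin, BinMap
from .io_formats import GenotypeTable
from .linkage import recode_to_parental

STATUSES = (
    "exact", "intermediate", "double_crossover_adjusted",
    "ambiguous", "excluded_1:2:1", "uninformative",
)

#: Statuses that place a marker on the map.
ASSIGNED_STATUSES = frozenset(
    {"exact", "intermediate", "double_crossover_adjusted"}
)


@dataclass(frozen=True)
class AssignOptions:
    """Informativeness floor, orientation handling and the DC cap."""

    min_informative: int = 10
    allow_phase_flip: bool = True
    max_double_crossovers: int = 1


@dataclass(frozen=True)
class AssignmentResult:
    marker_id: str
    parent: str
    bin_codes: tuple[str, ...]
    status: str
    mismatch_count: int
    n_informative_positions: int

    @property
    def assigned(self) -> bool:
        return self.status in ASSIGNED_STATUSES


def _distances(vec: np.ndarray, bins: Sequence[Bin]) -> np.ndarray:
    out = np.zeros(len(bins), dtype=int)
    valid_vec = ~np.isnan(vec)
    for i, b in enumerate(bins):
        sig = np.asarray(b.signature)
        ok = valid_vec & ~np.isnan(sig)
        out[i] = int(np.sum(vec[ok] != sig[ok]))
    return out


def _compatible_intermediate(
    vec: np.ndarray, left: Bin, right: Bin
) -> bool:
    """True iff every informative call matches the left or right signature."""
    sl = np.asarray(left.signature)
    sr = np.asarray(right.signature)
    ok = ~np.isnan(vec) & ~np.isnan(sl) & ~np.isnan(sr)
    return bool(np.all((vec[ok] == sl[ok]) | (vec[ok] == sr[ok])))


def assign_marker(
    vec: Sequence[float],
    binmap: BinMap,
    options: AssignOptions | None = None,
    marker_id: str = "",
) -> AssignmentResult:
    """Place one 0/1/NaN bin-set profile on one parental bin map.

    Resolution order: exact signature identity; intermediate between two
    adjacent bins; minimal-implied-double-crossover bin within the cap;
    otherwise ambiguous.  Profiles with fewer informative calls than
    ``min_informative`` are not assigned at all.
    """
    options = options or AssignOptions()
    vec = np.asarray(vec, dtype=float)
    if vec.shape[0] != len(binmap.individuals):
        raise ValueError(
            f"profile length {vec.shape[0]} != bin-set size {len(binmap.individuals)}"
        )
    n_inf = int(np.sum(~np.isnan(vec)))
    # the floor cannot exceed the bin-set size
    if n_inf < min(options.min_informative, len(binmap.individuals)):
        return AssignmentResult(marker_id, binmap.parent, (), "uninformative",
                                0, n_inf)

    bins = binmap.bins
    orientations = [vec]
    if options.allow_phase_flip:
        orientations.append(1.0 - vec)
    dists = [_distances(o, bins) for o in orientations]
    best_o = int(np.argmin([d.min() for d in dists]))
    if options.allow_phase_flip and dists[0].min() == dists[1].min():
        best_o = 0  # prefer the declared orientation on ties
    oriented = orientations[best_o]
    dist = dists[best_o]
    dmin = int(dist.min())

    zero = [b for b, d in zip(bins, dist) if d == 0]
    if len(zero) == 1:
        return AssignmentResult(marker_id, binmap.parent, (zero[0].code,),
                                "exact", 0, n_inf)
    if len(zero) >= 2:
        if len(zero) == 2 and binmap.adjacent(zero[0].code, zero[1].code):
            return AssignmentResult(
                marker_id, binmap.parent, (zero[0].code, zero[1].code),
                "intermediate", 0, n_inf)
        return AssignmentResult(
            marker_id, binmap.parent, tuple(b.code for b in zero),
            "ambiguous", 0, n_inf)

    # one extra breakpoint between two adjacent bins
    dist_by_code = {b.code: int(d) for b, d in zip(bins, dist)}
    pairs = []
    for lg in sorted({b.lg for b in bins}):
        group = [b for b in bins if b.lg == lg]
        for left, right in zip(group[:-1], group[1:]):
            dl = dist_by_code[left.code]
            dr = dist_by_code[right.code]
            if min(dl, dr) == dmin and _compatible_intermediate(oriented, left, right):
                pairs.append((left, right, min(dl, dr)))
    if len(pairs) == 1:
        left, right, mism = pairs[0]
        return AssignmentResult(
            marker_id, binmap.parent, (left.code, right.code),
            "intermediate", mism, n_inf)
    if len(pairs) > 1:
        codes = tuple(dict.fromkeys(c for l, r, _ in pairs for c in (l.code, r.code)))
        return AssignmentResult(marker_id, binmap.parent, codes,
                                "ambiguous", dmin, n_inf)

    cands = [b for b, d in zip(bins, dist) if d == dmin]
    if len(cands) == 1 and dmin <= options.max_double_crossovers:
        return AssignmentResult(marker_id, binmap.parent, (cands[0].code,),
                                "double_crossover_adjusted", dmin, n_inf)
    return AssignmentResult(marker_id, binmap.parent,
                            tuple(b.code for b in cands), "ambiguous",
                            dmin, n_inf)


def markers_per_bin(n_assigned: int, n_bins: int) -> float:
    """Mean markers per bin at reporting precision (one decimal)."""
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    return round(n_assigned / n_bins, 1)


def assign_catalog(
    table: GenotypeTable,
    bins_f: BinMap,
    bins_m: BinMap,
    options: AssignOptions | None = None,
) -> tuple[list[AssignmentResult], dict]:
    """Assign every marker of a bin-set genotype table on both parental maps.

    The table's individuals must cover the bin set.  Markers informative in
    both parents (ab x cd) are assigned on both maps; hk x hk markers are
    reported as excluded.  The summary gives, per parent, the assigned
    count, the one-decimal mean markers per bin, per-bin counts
    (intermediate markers are attributed to their first flanking bin) and
    the ambiguous/uninformative tallies.
    """
    options = options or AssignOptions()
    rec = recode_to_parental(table)
    results: list[AssignmentResult] = []
    for marker in rec.excluded:
        results.append(AssignmentResult(marker, "-", (), "excluded_1:2:1", 0, 0))
    for binmap, mat in ((bins_f, rec.female), (bins_m, rec.male)):
        cols = list(binmap.individuals)
        missing_inds = [c for c in cols if c not in mat.columns]
        if missing_inds:
            raise ValueError(f"table lacks bin-set individuals: {missing_inds}")
        sub = mat[cols]
        for marker in sub.index:
            results.append(assign_marker(
                sub.loc[marker].to_numpy(), binmap, options, marker_id=marker
            ))

    summary: dict = {"n_excluded": len(rec.excluded)}
    for parent, binmap in (("F", bins_f), ("M", bins_m)):
        mine = [r for r in results if r.parent == parent]
        assigned = [r for r in mine if r.assigned]
        per_bin = {b.code: 0 for b in binmap.bins}
        for r in assigned:
            per_bin[r.bin_codes[0]] += 1
        summary[parent] = {
            "n_markers": len(mine),
            "n_assigned": len(assigned),
            "n_exact": sum(r.status == "exact" for r in mine),
            "n_intermediate": sum(r.status == "intermediate" for r in mine),
            "n_double_crossover_adjusted": sum(
                r.status == "double_crossover_adjusted" for r in mine
            ),
            "n_ambiguous": sum(r.status == "ambiguous" for r in mine),
            "n_uninformative": sum(r.status == "uninformative" for r in mine),
            "mean_markers_per_bin": markers_per_bin(
                len(assigned), len(binmap.bins)
            ),
            "per_bin_counts": per_bin,
        }
    return results, summary
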