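"""Breakpoint inference, bin-set selection and bin construction.

Selective (bin) mapping genotypes only a small subset of offspring chosen
so that their crossover breakpoints dissect the framework maps as finely
as possible.  Breakpoints are observable only at the resolution of
framework-marker intervals, so the selection objective counts *distinct*
localising intervals across both parental maps: two individuals
recombining in the same interval contribute one breakpoint.  Selection is
greedy forward on that objective with deterministic tie-breaking (fewer
double crossovers, smaller maximum resulting bin, lower missingness,
lexicographic id) followed by a 1-swap local search.

Bins are then delimited by the union of the selected individuals'
breakpoints, each represented at the midpoint of its localising framework
interval, and coded ``LG.index`` (e.g. ``2.6``) in positional order.  Each
bin carries a genotype signature over the bin set; adjacent bins differ in
at least one genotypic point.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BreakpointKey = tuple[str, int, int, int]  # (parent, lg, left idx, right idx)


@dataclass(frozen=True)
class GroupProfile:
    """Breakpoints of one individual along one ordered linkage group."""

    intervals: tuple[tuple[int, int], ...]
    double_crossovers: int
    n_informative: int

    @property
    def empty(self) -> bool:
        return self.n_informative == 0


def infer_breakpoints(calls: Sequence[float]) -> GroupProfile:
    """Breakpoint intervals and double-crossover count for one 0/1/NaN vector.

    A breakpoint is one sign change between successive non-missing calls,
    localised to the open interval between the flanking informative
    markers (missing calls widen the interval).  A double crossover is an
    isolated call differing from both of its non-missing neighbours -- the
    classic genotyping-error signal.  An all-missing vector gives an empty
    profile.
    """
    v = np.asarray(calls, dtype=float)
    idx = np.flatnonzero(~np.isnan(v))
    vals = v[idx]
    intervals = tuple(
        (int(a), int(b))
        for a, b, va, vb in zip(idx[:-1], idx[1:], vals[:-1], vals[1:])
        if va != vb
    )
    dc = sum(
        1 for t in range(1, len(vals) - 1)
        if vals[t] != vals[t - 1] and vals[t] != vals[t + 1]
    )
    return GroupProfile(intervals=intervals, double_crossovers=dc,
                        n_informative=len(idx))


@dataclass
class BreakpointProfile:
    """All breakpoints of one offspring over both parental maps."""

    individual: str
    groups: dict[tuple[str, int], GroupProfile]
    missing_fraction: float

    @property
    def breakpoint_keys(self) -> frozenset[BreakpointKey]:
        return frozenset(
            (parent, lg, i, j)
            for (parent, lg), prof in self.groups.items()
            for (i, j) in prof.intervals
        )

    @property
    def n_double_crossovers(self) -> int:
        return sum(p.double_crossovers for p in self.groups.values())


def _ordered_markers(map_df: pd.DataFrame) -> dict[int, list[str]]:
    return {
        int(g): sub["marker"].tolist()
        for g, sub in map_df.groupby("linkage_group")
    }


def _positions(map_df: pd.DataFrame) -> dict[int, np.ndarray]:
    return {
        int(g): sub["position"].to_numpy()
        for g, sub in map_df.groupby("linkage_group")
    }


def build_profiles(
    female: pd.DataFrame,
    male: pd.DataFrame,
    map_f: pd.DataFrame,
    map_m: pd.DataFrame,
) -> dict[str, BreakpointProfile]:
    """Per-offspring breakpoint profiles from recoded parental matrices."""
    individuals = list(female.columns)
    if list(male.columns) != individuals:
        raise ValueError("female and male matrices must share individuals")
    order = {"F": _ordered_markers(map_f), "M": _ordered_markers(map_m)}
    mats = {"F": female, "M": male}
    profiles: dict[str, BreakpointProfile] = {}
    n_missing = np.zeros(len(individuals))
    n_total = 0
    per_group_arrays: dict[tuple[str, int], np.ndarray] = {}
    for parent, groups in order.items():
        for g, markers in groups.items():
            arr = mats[parent].loc[markers].to_numpy()
            per_group_arrays[(parent, g)] = arr
            n_missing += np.isnan(arr).sum(axis=0)
            n_total += len(markers)
    for k, ind in enumerate(individuals):
        groups: dict[tuple[str, int], GroupProfile] = {}
        for key, arr in per_group_arrays.items():
            groups[key] = infer_breakpoints(arr[:, k])
        profiles[ind] = BreakpointProfile(
            individual=ind,
            groups=groups,
            missing_fraction=float(n_missing[k] / n_total),
        )
    return profiles


# -- bin-set selection ---------------------------------------------------

@dataclass(frozen=True)
class SelectionConfig:
    """Bin-set size and eligibility/penalty settings.

    The objective is the count of distinct breakpoint intervals minus
    ``dc_weight`` per double crossover carried by the selected
    individuals: an isolated flip is the classic genotyping-error signal,
    so its two breakpoints should not buy map coverage at face value.
    The default weight of 1 cancels one covered interval per double
    crossover.  ``evenness_weight`` can fold the maximum resulting bin
    length into the objective as well; by default evenness, double
    crossovers and missingness act as deterministic tie-breakers.
    """

    k: int = 14
    max_missing: float = 0.10
    dc_weight: float = 1.0
    evenness_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("bin-set size k must be >= 1")


def _midpoints(
    keys: Iterable[BreakpointKey], positions: Mapping[str, Mapping[int, np.ndarray]]
) -> dict[tuple[str, int], list[float]]:
    out: dict[tuple[str, int], list[float]] = {}
    for parent, lg, i, j in keys:
        pos = positions[parent][lg]
        out.setdefault((parent, lg), []).append(float((pos[i] + pos[j]) / 2.0))
    for v in out.values():
        v.sort()
    return out


def _max_bin_length(
    keys: frozenset[BreakpointKey],
    positions: Mapping[str, Mapping[int, np.ndarray]],
    group_lengths: Mapping[str, Mapping[int, float]],
) -> float:
    mids = _midpoints(keys, positions)
    worst = 0.0
    for parent, groups in group_lengths.items():
        for lg, length in groups.items():
            cuts = mids.get((parent, lg), [])
            edges = [0.0, *cuts, length]
            worst = max(worst, max(b - a for a, b in zip(edges, edges[1:])))
    return worst


def _group_lengths(
    positions: Mapping[str, Mapping[int, np.ndarray]],
    group_length: float | Mapping[str, Mapping[int, float]] | None,
) -> dict[str, dict[int, float]]:
    out: dict[str, dict[int, float]] = {}
    for parent, groups in positions.items():
        out[parent] = {}
        for lg, pos in groups.items():
            if group_length is None:
                out[parent][lg] = float(pos[-1])
            elif isinstance(group_length, (int, float)):
                out[parent][lg] = float(group_length)
            else:
                out[parent][lg] = float(group_length[parent][lg])
    return out


def select_bin_set(
    profiles: Mapping[str, BreakpointProfile],
    map_f: pd.DataFrame,
    map_m: pd.DataFrame,
    config: SelectionConfig | None = None,
    group_length: float | Mapping[str, Mapping[int, float]] | None = None,
) -> tuple[list[str], dict]:
    """Choose the k most informative offspring for the bin set.

    Greedy forward selection maximises the number of distinct breakpoint
    intervals over both parental maps among individuals whose missing-call
    fraction is strictly below ``max_missing``; ties are broken by fewer
    double crossovers, smaller maximum resulting bin length, lower
    missingness, then id.  A 1-swap local search then runs to a local
    optimum.  Deterministic given the input.
    """
    config = config or SelectionConfig()
    positions = {"F": _positions(map_f), "M": _positions(map_m)}
    lengths = _group_lengths(positions, group_length)

    eligible = {
        ind: p for ind, p in profiles.items()
        if p.missing_fraction < config.max_missing
    }
    if len(eligible) < config.k:
        failures = {
            ind: f"missing fraction {p.missing_fraction:.3f} >= {config.max_missing}"
            for ind, p in profiles.items() if ind not in eligible
        }
        raise ValueError(
            f"only {len(eligible)} eligible individuals for k={config.k}; "
            f"excluded: {failures}"
        )
    keysets = {ind: p.breakpoint_keys for ind, p in eligible.items()}
    dcs = {ind: p.n_double_crossovers for ind, p in eligible.items()}
    miss = {ind: p.missing_fraction for ind, p in eligible.items()}

    def score(cover: frozenset[BreakpointKey], members: Sequence[str]) -> float:
        s = float(len(cover))
        if config.dc_weight:
            s -= config.dc_weight * sum(dcs[m] for m in members)
        if config.evenness_weight:
            s -= config.evenness_weight * _max_bin_length(cover, positions, lengths)
        return s

    selected: list[str] = []
    covered: frozenset[BreakpointKey] = frozenset()
    candidates = sorted(eligible)
    for _ in range(config.k):
        best = None
        for ind in candidates:
            if ind in selected:
                continue
            cover = covered | keysets[ind]
            trial = (*selected, ind)
            key = (
                -score(cover, trial),
                dcs[ind],
                _max_bin_length(cover, positions, lengths),
                miss[ind],
                ind,
            )
            if best is None or key < best[0]:
                best = (key, ind, cover)
        assert best is not None
        selected.append(best[1])
        covered = best[2]

    def state_key(members: Sequence[str]) -> tuple:
        cover = frozenset().union(*(keysets[m] for m in members))
        return (
            -score(cover, members),
            sum(dcs[m] for m in members),
            _max_bin_length(cover, positions, lengths),
            sum(miss[m] for m in members),
            tuple(sorted(members)),
        )

    current = state_key(selected)
    for _ in range(200):  # 1-swap passes; converges long before this
        improved = False
        for out_ind in list(selected):
            for in_ind in candidates:
                if in_ind in selected:
                    continue
                trial = [m for m in selected if m != out_ind] + [in_ind]
                trial_key = state_key(trial)
                if trial_key < current:
                    selected = trial
                    current = trial_key
                    improved = True
                    break  # restart the scan on the updated set
            if improved:
                break
        if not improved:
            break

    selected = sorted(selected)
    final_cover = frozenset().union(*(keysets[m] for m in selected))
    report = {
        "objective": len(final_cover),
        "n_eligible": len(eligible),
        "total_double_crossovers": sum(dcs[m] for m in selected),
        "max_bin_length": _max_bin_length(final_cover, positions, lengths),
        "per_individual": {
            m: {"breakpoints": len(keysets[m]), "double_crossovers": dcs[m],
                "missing_fraction": miss[m]}
            for m in selected
        },
    }
    return selected, report


# -- bin construction ----------------------------------------------------

@dataclass(frozen=True)
class Bin:
    """One map interval with its two-part code and genotype signature."""

    parent: str
    lg: int
    index: int
    code: str
    start: float
    end: float
    signature: tuple[float, ...]  # 0/1/NaN per bin-set individual

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class BinMap:
    """All bins of one parental map, plus the bin-set individual order."""

    parent: str
    individuals: tuple[str, ...]
    bins: list[Bin]
    group_lengths: dict[int, float]

    def bins_in_group(self, lg: int) -> list[Bin]:
        return [b for b in self.bins if b.lg == lg]

    def by_code(self, code: str) -> Bin:
        for b in self.bins:
            if b.code == code:
                return b
        raise KeyError(code)

    def find_bin(self, lg: int, pos: float) -> Bin:
        """The bin containing map position *pos* on group *lg*."""
        group = self.bins_in_group(lg)
        if not group:
            raise KeyError(f"no bins on group {lg}")
        for b in group:
            if b.start <= pos < b.end:
                return b
        return group[-1] if pos >= group[-1].end else group[0]

    def adjacent(self, code_a: str, code_b: str) -> bool:
        a, b = self.by_code(code_a), self.by_code(code_b)
        return a.lg == b.lg and abs(a.index - b.index) == 1


def _step_function(
    positions: np.ndarray, calls: np.ndarray
) -> tuple[list[float], list[float]]:
    """Piecewise-constant genotype along a group: (flip points, segment values)."""
    idx = np.flatnonzero(~np.isnan(calls))
    if idx.size == 0:
        return [], [float("nan")]
    vals = calls[idx]
    flips: list[float] = []
    seg_vals: list[float] = [float(vals[0])]
    for a, b, va, vb in zip(idx[:-1], idx[1:], vals[:-1], vals[1:]):
        if va != vb:
            flips.append(float((positions[a] + positions[b]) / 2.0))
            seg_vals.append(float(vb))
    return flips, seg_vals


def build_bins(
    bin_set: Sequence[str],
    female: pd.DataFrame,
    male: pd.DataFrame,
    map_f: pd.DataFrame,
    map_m: pd.DataFrame,
    group_length: float | Mapping[str, Mapping[int, float]] | None = None,
) -> tuple[BinMap, BinMap, dict]:
    """Partition each parental map into bins at the bin set's breakpoints.

    Each framework marker carries a genotype signature over the bin set
    (missing calls are filled from the individual's piecewise-constant
    genotype, whose flips sit at the midpoints of the localising
    framework intervals).  A bin is a maximal run of consecutive
    framework markers with identical signatures; the boundary between two
    runs is the midpoint of the framework interval separating them, and
    each group is the half-open partition of [0, group length].
    """
    bin_set = list(bin_set)
    positions = {"F": _positions(map_f), "M": _positions(map_m)}
    order = {"F": _ordered_markers(map_f), "M": _ordered_markers(map_m)}
    lengths = _group_lengths(positions, group_length)
    mats = {"F": female[bin_set], "M": male[bin_set]}

    maps: dict[str, BinMap] = {}
    stats: dict[str, dict] = {}
    for parent in ("F", "M"):
        bins: list[Bin] = []
        adj_dists: list[int] = []
        for lg in sorted(order[parent]):
            markers = order[parent][lg]
            pos = positions[parent][lg]
            length = lengths[parent][lg]
            sub = mats[parent].loc[markers].to_numpy()
            steps = [
                _step_function(pos, sub[:, k]) for k in range(len(bin_set))
            ]
            # imputed signature of every framework marker over the bin set
            sigs = np.array([
                [seg_vals[bisect_right(flips, p)] for flips, seg_vals in steps]
                for p in pos
            ])
            # maximal runs of identical signatures -> bins
            run_last = []  # index of the last marker of each run
            for t in range(len(markers) - 1):
                if not np.array_equal(sigs[t], sigs[t + 1], equal_nan=True):
                    run_last.append(t)
            run_last.append(len(markers) - 1)
            cuts = [
                float((pos[t] + pos[t + 1]) / 2.0) for t in run_last[:-1]
            ]
            edges = [0.0, *cuts, length]
            run_first = [0] + [t + 1 for t in run_last[:-1]]
            group_bins: list[Bin] = []
            for index, (a, b) in enumerate(zip(edges[:-1], edges[1:]), start=1):
                sig = tuple(float(s) for s in sigs[run_first[index - 1]])
                group_bins.append(Bin(
                    parent=parent, lg=lg, index=index,
                    code=f"{lg}.{index}", start=a, end=b, signature=sig,
                ))
            for u, v in zip(group_bins[:-1], group_bins[1:]):
                su, sv = np.asarray(u.signature), np.asarray(v.signature)
                ok = ~np.isnan(su) & ~np.isnan(sv)
                adj_dists.append(int(np.sum(su[ok] != sv[ok])))
            bins.extend(group_bins)
        maps[parent] = BinMap(
            parent=parent, individuals=tuple(bin_set), bins=bins,
            group_lengths=lengths[parent],
        )
        stats[parent] = {
            "n_bins": len(bins),
            "mean_length": float(np.mean([b.length for b in bins])),
            "mean_adjacent_genotypic_points": (
                float(np.mean(adj_dists)) if adj_dists else float("nan")
            ),
        }
    return maps["F"], maps["M"], stats


def exhaustive_bin_set(
    profiles: Mapping[str, BreakpointProfile], k: int,
    max_missing: float = 1.0,
) -> tuple[list[str], int]:
    """Exhaustively optimal bin set by distinct-breakpoint count (tiny n only)."""
    eligible = {
        ind: p.breakpoint_keys for ind, p in profiles.items()
        if p.missing_fraction < max_missing
    }
    best: tuple[int, tuple[str, ...]] | None = None
    for combo in combinations(sorted(eligible), k):
        count = len(frozenset().union(*(eligible[m] for m in combo)))
        key = (-count, combo)
        if best is None or key < best:
            best = key
    assert best is not None
    return list(best[1]), -best[0]


# -- serialization -------------------------------------------------------

def binmap_to_json(binmap: BinMap, path: str | Path | None = None) -> dict:
    doc = {
        "parent": binmap.parent,
        "individuals": list(binmap.individuals),
        "group_lengths": {str(k): v for k, v in binmap.group_lengths.items()},
        "bins": [
            {
                "code": b.code, "lg": b.lg, "index": b.index,
                "start": b.start, "end": b.end,
                "signature": [None if np.isnan(s) else int(s) for s in b.signature],
            }
            for b in binmap.bins
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def binmap_from_json(doc: dict | str | Path) -> BinMap:
    if not isinstance(doc, dict):
        doc = json.loads(Path(doc).read_text())
    bins = [
        Bin(
            parent=doc["parent"], lg=int(b["lg"]), index=int(b["index"]),
            code=b["code"], start=float(b["start"]), end=float(b["end"]),
            signature=tuple(
                float("nan") if s is None else float(s) for s in b["signature"]
            ),
        )
        for b in doc["bins"]
    ]
    return BinMap(
        parent=doc["parent"],
        individuals=tuple(doc["individuals"]),
        bins=bins,
        group_lengths={int(k): float(v) for k, v in doc["group_lengths"].items()},
    )
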