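"""Two-point linkage estimation and map functions for pseudo-testcross data.

In an outbred full-sib family each parent's heterozygous markers segregate
1:1, so after recoding every informative marker to a 0/1 parental-allele
vector, two-point linkage reduces to counting recombinant meioses.  With N
pairwise non-missing offspring and R recombinants (after choosing the
allele orientation that minimises R, since linkage phase is initially
unknown), the ML estimate is r = R/N and

    LOD = N log10(2) + R log10(r) + (N - R) log10(1 - r)

which is 0 at r = 0.5 (free recombination).  Kosambi and Haldane map
functions convert between recombination fraction and centimorgans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeTable


@dataclass(frozen=True)
class LinkagePair:
    """Two-point estimate between one marker pair."""

    r_hat: float
    lod: float
    n_informative: int

    @property
    def defined(self) -> bool:
        return self.n_informative > 0


# -- recoding ------------------------------------------------------------

_FEMALE_CODES = {
    "lmxll": {"ll": 0.0, "lm": 1.0},
    "abxcd": {"a": 0.0, "b": 1.0},  # first letter of the call
}
_MALE_CODES = {
    "nnxnp": {"nn": 0.0, "np": 1.0},
    "abxcd": {"c": 0.0, "d": 1.0},  # second letter of the call
}


@dataclass
class RecodeResult:
    """Parental 0/1/NaN matrices plus bookkeeping from recoding.

    ``female``/``male`` are float DataFrames (markers x individuals) holding
    0, 1 or NaN.  ``excluded`` maps marker id to the reason it appears in
    neither matrix; ``unknown_phase`` lists markers recoded under the
    coupling convention because no phase was declared.
    """

    female: pd.DataFrame
    male: pd.DataFrame
    excluded: dict[str, str]
    unknown_phase: list[str]


def recode_to_parental(table: GenotypeTable) -> RecodeResult:
    """Split a genotype table into per-parent 0/1/NaN matrices.

    lm x ll markers are informative for the female parent only, nn x np for
    the male only, and ab x cd for both (female allele a/b, male allele
    c/d).  hk x hk markers cannot be phased into either testcross and are
    excluded with a reason.  A declared repulsion phase flips the 0/1
    coding; unknown phase is treated as coupling and flagged (two-point
    estimation is orientation-invariant, so this only affects labelling).
    """
    female_rows: dict[str, np.ndarray] = {}
    male_rows: dict[str, np.ndarray] = {}
    excluded: dict[str, str] = {}
    unknown_phase: list[str] = []
    individuals = table.individual_ids
    for marker in table.marker_ids:
        st = table.seg_type.loc[marker]
        ph = table.phase.loc[marker]
        if st == "hkxhk":
            excluded[marker] = "1:2:1 segregation (hkxhk) cannot be split by parent"
            continue
        if ph == "unknown":
            unknown_phase.append(marker)
        flip = ph == "repulsion"
        calls = table.calls.loc[marker]
        if st in _FEMALE_CODES:
            mapping = _FEMALE_CODES[st]
            vec = np.full(len(individuals), np.nan)
            for k, call in enumerate(calls):
                if call == MISSING:
                    continue
                key = call if st == "lmxll" else call[0]
                vec[k] = mapping[key]
            if flip:
                vec = 1.0 - vec
            female_rows[marker] = vec
        if st in _MALE_CODES:
            mapping = _MALE_CODES[st]
            vec = np.full(len(individuals), np.nan)
            for k, call in enumerate(calls):
                if call == MISSING:
                    continue
                key = call if st == "nnxnp" else call[1]
                vec[k] = mapping[key]
            if flip:
                vec = 1.0 - vec
            male_rows[marker] = vec
    female = pd.DataFrame.from_dict(female_rows, orient="index", columns=individuals)
    male = pd.DataFrame.from_dict(male_rows, orient="index", columns=individuals)
    return RecodeResult(female=female, male=male, excluded=excluded,
                        unknown_phase=unknown_phase)


# -- two-point estimation ------------------------------------------------

def two_point(m1, m2) -> LinkagePair:
    """Two-point recombination fraction and LOD between two 0/1/NaN vectors.

    The allele-coding orientation minimising the recombinant count is used,
    making the result invariant to flipping either marker's coding.  With
    no shared informative meioses the pair is undefined (NaN, flagged by
    ``n_informative == 0``).
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    mask = ~np.isnan(a) & ~np.isnan(b)
    n = int(mask.sum())
    if n == 0:
        return LinkagePair(math.nan, math.nan, 0)
    mism = int(np.sum(a[mask] != b[mask]))
    r_count = min(mism, n - mism)
    if 2 * r_count >= n:
        return LinkagePair(0.5, 0.0, n)
    r = r_count / n
    lod = n * math.log10(2.0) + (n - r_count) * math.log10(1.0 - r)
    if r_count:
        lod += r_count * math.log10(r)
    return LinkagePair(r, lod, n)


def two_point_matrix(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised two-point estimates between all row pairs of *a* and *b*.

    Returns (r_hat, lod, n) arrays of shape (a rows, b rows).  Undefined
    pairs (n == 0) have NaN r_hat and lod.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    av = (~np.isnan(a)).astype(float)
    bv = (~np.isnan(b)).astype(float)
    a0 = np.nan_to_num(a)
    b0 = np.nan_to_num(b)
    n = av @ bv.T
    # mismatches: x(1-y) + (1-x)y over jointly valid entries
    mism = a0 @ (bv - b0).T + (av - a0) @ b0.T
    r_count = np.minimum(mism, n - mism)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n > 0, r_count / n, np.nan)
        r = np.where(2 * r_count >= n, 0.5, r)
        lod = (
            n * math.log10(2.0)
            + np.where(r_count > 0, r_count * np.log10(np.where(r > 0, r, 1.0)), 0.0)
            + (n - r_count) * np.log10(np.maximum(1.0 - r, 1e-300))
        )
    lod = np.where(r >= 0.5, 0.0, lod)
    lod = np.where(n > 0, lod, np.nan)
    return r, lod, n.astype(int)


# -- map functions -------------------------------------------------------

def _check_r(r: float) -> None:
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5)")


def kosambi_d(r: float) -> float:
    """Kosambi distance in cM: d = 25 ln((1 + 2r) / (1 - 2r))."""
    _check_r(r)
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_r(d: float) -> float:
    """Inverse Kosambi map function: r = tanh(d / 50) / 2."""
    if d < 0:
        raise ValueError("distance must be >= 0 cM")
    return 0.5 * math.tanh(d / 50.0)


def haldane_d(r: float) -> float:
    """Haldane distance in cM: d = -50 ln(1 - 2r)."""
    _check_r(r)
    return -50.0 * math.log(1.0 - 2.0 * r)


def haldane_r(d: float) -> float:
    """Inverse Haldane map function: r = (1 - exp(-d / 50)) / 2."""
    if d < 0:
        raise ValueError("distance must be >= 0 cM")
    return 0.5 * (1.0 - math.exp(-d / 50.0))


# -- framework screening and grouping ------------------------------------

def screen_framework(
    table: GenotypeTable,
    max_missing_individual: float = 0.5,
    framework_markers: list[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Apply the double screen: individuals by missingness, markers by map.

    Individuals are kept iff their missing-call fraction is strictly below
    *max_missing_individual* (an individual at exactly the threshold is
    dropped).  Framework markers come from the provided framework list /
    map -- their local-ordering support is upstream metadata, not
    recomputed here.
    """
    frac = table.missing_fraction_per_individual()
    kept_individuals = [ind for ind in table.individual_ids
                        if frac[ind] < max_missing_individual]
    if not kept_individuals:
        raise ValueError("screen removed every individual")
    if framework_markers is None:
        kept_markers = table.marker_ids
    else:
        wanted = set(framework_markers)
        kept_markers = [m for m in table.marker_ids if m in wanted]
    return kept_individuals, kept_markers


def group_markers(matrix: pd.DataFrame, lod_threshold: float = 3.0) -> list[list[str]]:
    """Cluster markers into linkage groups by two-point LOD.

    Builds the graph whose edges join marker pairs with LOD >= threshold
    and returns its connected components (singletons included), each sorted
    by marker id, components ordered by size then first member.
    """
    markers = list(matrix.index)
    _, lod, n = two_point_matrix(matrix.to_numpy(), matrix.to_numpy())
    graph = nx.Graph()
    graph.add_nodes_from(markers)
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            if n[i, j] > 0 and lod[i, j] >= lod_threshold:
                graph.add_edge(markers[i], markers[j])
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps
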