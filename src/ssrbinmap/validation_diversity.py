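"""Linkage-based validation of bin assignments, synteny checks and
marker-diversity statistics.

Validation re-genotypes assigned markers on an extended progeny set and
finds each marker's nearest framework marker by two-point LOD.  Markers
whose best LOD clears a threshold fall into class A (nearest framework
marker inside the assigned bin), B (adjacent bin) or C (a more distant bin
or another linkage group); markers below the threshold are class D.  The
headline rate is the A+B percentage (A+B+C is reported alongside).

Diversity statistics are the unbiased gene diversity

    He = N/(N-1) * (1 - sum_i (N_i/N)^2)

over N gene copies with allele counts N_i, and rarefied allelic richness

    A_g = sum_i [1 - C(N - N_i, g) / C(N, g)]

the expected number of distinct alleles in a subsample of g gene copies
drawn without replacement (El Mousadik & Petit rarefaction), which makes
locus sets genotyped on different sample sizes comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .bin_builder import BinMap
from .linkage import two_point

VALID_CLASSES = ("A", "B", "C", "D")


@dataclass(frozen=True)
class ValidationClass:
    """Outcome of validating one marker's bin assignment by linkage."""

    marker_id: str
    cls: str
    nearest_framework_marker: str | None
    lod: float
    relation: str  # same / adjacent / distant / unlinked


def classify_assignment(
    marker_id: str,
    marker_vec: Sequence[float],
    assigned_codes: Sequence[str],
    framework_matrix: pd.DataFrame,
    framework_bins: Mapping[str, str],
    binmap: BinMap,
    lod_threshold: float = 3.0,
) -> ValidationClass:
    """Classify one assignment against two-point linkage on extended progeny.

    The nearest framework marker is the one with maximal LOD (ties broken
    by larger informative count, then marker id).  The threshold is strict:
    classes A-C require LOD > threshold, otherwise the marker is class D.
    *framework_matrix* holds the framework markers' 0/1/NaN vectors over
    the same extended individuals as *marker_vec*; *framework_bins* maps
    each framework marker to its bin code on this parental map.
    """
    if framework_matrix.empty:
        raise ValueError("no framework markers to validate against")
    vec = np.asarray(marker_vec, dtype=float)
    best: tuple[float, int, str] | None = None
    best_lod = -np.inf
    for fm in framework_matrix.index:
        pair = two_point(vec, framework_matrix.loc[fm].to_numpy())
        if pair.n_informative == 0:
            continue
        key = (-pair.lod, -pair.n_informative, fm)
        if best is None or key < best:
            best = key
            best_lod = pair.lod
    if best is None:
        return ValidationClass(marker_id, "D", None, float("nan"), "unlinked")
    nearest = best[2]
    if not best_lod > lod_threshold:
        return ValidationClass(marker_id, "D", nearest, best_lod, "unlinked")
    fm_code = framework_bins[nearest]
    if fm_code in assigned_codes:
        return ValidationClass(marker_id, "A", nearest, best_lod, "same")
    if any(binmap.adjacent(fm_code, code) for code in assigned_codes):
        return ValidationClass(marker_id, "B", nearest, best_lod, "adjacent")
    return ValidationClass(marker_id, "C", nearest, best_lod, "distant")


def rate_pct(numerator: int, denominator: int) -> float:
    if denominator <= 0:
        raise ValueError("empty class list")
    return round(100.0 * numerator / denominator, 1)


def validation_summary(
    classes: Sequence[ValidationClass] | Mapping[str, int]
) -> dict:
    """Class counts plus the A+B (and A+B+C) validation rate, one decimal."""
    if isinstance(classes, Mapping):
        counts = {c: int(classes.get(c, 0)) for c in VALID_CLASSES}
    else:
        if not classes:
            raise ValueError("empty class list")
        counts = {c: sum(1 for v in classes if v.cls == c) for c in VALID_CLASSES}
    total = sum(counts.values())
    return {
        "counts": counts,
        "n_markers": total,
        "pct_ab": rate_pct(counts["A"] + counts["B"], total),
        "pct_abc": rate_pct(counts["A"] + counts["B"] + counts["C"], total),
    }


# -- macro-synteny and colinearity ---------------------------------------

def check_synteny(
    map_f: pd.DataFrame,
    map_m: pd.DataFrame,
    shared_ids: Sequence[str],
) -> tuple[pd.DataFrame, dict[tuple[int, int], dict]]:
    """Homologous-group table and per-group order concordance.

    Homology maps each female group to the male group holding the majority
    of their shared markers.  For each homologous pair, Kendall's tau is
    computed on the shared markers' positional ranks along with the number
    of discordant adjacent pairs (adjacent in female order, inverted in
    male order).  Pairs with fewer than two shared markers get tau = None.
    """
    shared = set(shared_ids)
    f = map_f[map_f["marker"].isin(shared)]
    m = map_m[map_m["marker"].isin(shared)].set_index("marker")
    rows = []
    concordance: dict[tuple[int, int], dict] = {}
    for fg, sub in f.groupby("linkage_group"):
        present = [mk for mk in sub["marker"] if mk in m.index]
        if not present:
            continue
        male_groups = m.loc[present, "linkage_group"]
        homolog = int(male_groups.value_counts().idxmax())
        members = [mk for mk in present if m.loc[mk, "linkage_group"] == homolog]
        rows.append({
            "female_lg": int(fg), "male_lg": homolog,
            "n_shared": len(present), "n_on_homolog": len(members),
        })
        entry: dict = {"n_shared": len(members)}
        if len(members) < 2:
            entry.update(tau=None, n_discordant_adjacent=None)
        else:
            fpos = sub.set_index("marker").loc[members, "position"].to_numpy()
            mpos = m.loc[members, "position"].to_numpy()
            order = np.argsort(fpos, kind="mergesort")
            mp = mpos[order]
            tau = kendalltau(np.arange(len(mp)), mp).statistic
            discordant = int(np.sum(np.diff(mp) < 0))
            entry.update(tau=float(tau), n_discordant_adjacent=discordant)
        concordance[(int(fg), homolog)] = entry
    homology = pd.DataFrame(
        rows, columns=["female_lg", "male_lg", "n_shared", "n_on_homolog"]
    )
    return homology, concordance


# -- diversity statistics ------------------------------------------------

def expected_het(allele_counts: Sequence[int]) -> float:
    """Unbiased gene diversity He over N = sum(counts) gene copies."""
    counts = np.asarray(list(allele_counts), dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("He needs at least 2 gene copies")
    freqs = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(freqs ** 2)))


def allelic_richness(allele_counts: Sequence[int], g: int) -> float:
    """Rarefied allelic richness A_g at standard sample size g gene copies.

    Exact evaluation with integer binomials: A_g = sum_i [1 - C(N - N_i, g)
    / C(N, g)], with C(a, b) = 0 when a < b.  A_1 = 1 and A_N equals the
    observed allele count.
    """
    counts = [int(c) for c in allele_counts if c > 0]
    n = sum(counts)
    if not 1 <= g <= n:
        raise ValueError(f"rarefaction size g={g} outside [1, {n}]")
    denom = comb(n, g)
    total = 0.0
    for ni in counts:
        rem = n - ni
        numer = comb(rem, g) if rem >= g else 0
        total += 1.0 - numer / denom
    return total


@dataclass(frozen=True)
class DiversityStats:
    """Per-locus diversity summary."""

    locus: str
    n_gene_copies: int
    n_alleles: int
    he: float
    richness: float
    rarefy_g: int
    size_range_bp: float


def locus_stats(
    locus: str, allele_counts: Mapping[float, int], g: int
) -> DiversityStats:
    """Stats for one locus; allele keys are sizes in bp (or any label)."""
    counts = [c for c in allele_counts.values() if c > 0]
    sizes = [s for s, c in allele_counts.items() if c > 0]
    try:
        size_range = float(max(sizes) - min(sizes))
    except TypeError:
        size_range = float("nan")
    return DiversityStats(
        locus=locus,
        n_gene_copies=sum(counts),
        n_alleles=len(counts),
        he=expected_het(counts),
        richness=allelic_richness(counts, g),
        rarefy_g=g,
        size_range_bp=size_range,
    )


def compare_marker_sets(
    set1: Mapping[str, Mapping[float, int]],
    set2: Mapping[str, Mapping[float, int]],
    names: tuple[str, str] = ("set1", "set2"),
) -> pd.DataFrame:
    """Mean diversity statistics for two locus sets on a common scale.

    Rarefaction uses g = the smallest number of gene copies observed at any
    locus of either set, so richness is comparable across loci and sets.
    """
    if not set1 or not set2:
        raise ValueError("both marker sets must be non-empty")
    g = min(
        sum(c for c in counts.values() if c > 0)
        for counts in list(set1.values()) + list(set2.values())
    )
    rows = []
    for name, loci in zip(names, (set1, set2)):
        stats = [locus_stats(loc, counts, g) for loc, counts in loci.items()]
        rows.append({
            "set": name,
            "n_loci": len(stats),
            "mean_he": float(np.mean([s.he for s in stats])),
            "mean_richness": float(np.mean([s.richness for s in stats])),
            "mean_n_alleles": float(np.mean([s.n_alleles for s in stats])),
            "mean_size_range_bp": float(np.mean([s.size_range_bp for s in stats])),
            "rarefy_g": g,
        })
    return pd.DataFrame(rows).set_index("set")
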