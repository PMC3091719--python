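"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results by exhaustive enumeration or direct
simulation so the implementation under test is checked against a separate
code path, not against itself.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from ssrbinmap.ssr_miner import MiningConfig, is_primitive


def brute_force_ssrs(seq: str, config: MiningConfig) -> list[tuple[int, int, str]]:
    """Enumerate every maximal perfect tandem run by per-start extension.

    For every (start, unit length) pair the run is extended one base at a
    time; left-maximality is checked explicitly.  Returns (start, end,
    unit) triples with the span trimmed to whole units, sorted like the
    miner's output.
    """
    seq = seq.upper()
    L = len(seq)
    out = []
    for u, thr in config.min_repeats.items():
        for i in range(L - 2 * u + 1):
            if i > 0 and seq[i - 1] == seq[i - 1 + u]:
                continue  # extendable to the left: not a run start
            ext = 0
            while i + ext + u < L and seq[i + ext] == seq[i + ext + u]:
                ext += 1
            n = (ext + u) // u
            if n < thr:
                continue
            unit = seq[i:i + u]
            if not is_primitive(unit):
                continue
            end = i + u * n
            if "N" in seq[i:end]:
                continue
            out.append((i, end, unit))
    out.sort(key=lambda t: (t[0], t[1], len(t[2])))
    return out


def transitive_merge_oracle(
    spans: list[tuple[int, int]], merge_gap: int
) -> list[tuple[int, int]]:
    """Union-find closure of spans whose gap is < merge_gap."""
    parent = list(range(len(spans)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (s1, e1) in enumerate(spans):
        for j, (s2, e2) in enumerate(spans):
            if i < j:
                gap = max(s1, s2) - min(e1, e2)
                if gap < merge_gap:
                    parent[find(i)] = find(j)
    groups: dict[int, list[tuple[int, int]]] = {}
    for i, span in enumerate(spans):
        groups.setdefault(find(i), []).append(span)
    merged = [
        (min(s for s, _ in grp), max(e for _, e in grp))
        for grp in groups.values()
    ]
    return sorted(merged)


def epcr_scan_oracle(template: str, forward: str, rc_reverse: str):
    """Exhaustive O(L^2) scan for exact primer placements."""
    hits = []
    for i in range(len(template) - len(forward) + 1):
        if template[i:i + len(forward)] != forward:
            continue
        for j in range(i + len(forward), len(template) - len(rc_reverse) + 1):
            if template[j:j + len(rc_reverse)] == rc_reverse:
                hits.append((i, j + len(rc_reverse)))
    return hits


def lod_grid_max(n: int, r_count: int, grid=None) -> float:
    """Maximum LOD over an explicit recombination-fraction grid."""
    if grid is None:
        grid = np.arange(0.001, 0.5, 0.001)
    best = -math.inf
    for r in grid:
        lod = (n * math.log10(2.0)
               + r_count * math.log10(r)
               + (n - r_count) * math.log10(1.0 - r))
        best = max(best, lod)
    return best


def exhaustive_distinct_breakpoints(keysets: dict[str, frozenset], k: int) -> int:
    """Best achievable distinct-breakpoint count over all k-subsets."""
    best = 0
    for combo in combinations(sorted(keysets), k):
        best = max(best, len(frozenset().union(*(keysets[m] for m in combo))))
    return best


def richness_monte_carlo(
    counts: list[int], g: int, n_draws: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Rarefied allele count by subsampling without replacement: (mean, SE)."""
    pool = np.repeat(np.arange(len(counts)), counts)
    vals = np.empty(n_draws)
    for t in range(n_draws):
        sample = rng.choice(pool, size=g, replace=False)
        vals[t] = len(np.unique(sample))
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(n_draws))
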