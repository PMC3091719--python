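"""End-to-end bin-mapping run on a synthetic full-sib family.

Glue for the common experiment: simulate the pedigree, screen individuals,
recode to parental testcross matrices, select the bin set, build bins,
assign a panel of freshly simulated test markers by graphical genotyping,
score them against the simulator's truth, and validate the assignments by
two-point linkage on an extended progeny subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bin_assigner import AssignmentResult, AssignOptions, assign_catalog
from .bin_builder import (
    BinMap, SelectionConfig, build_bins, build_profiles, select_bin_set,
)
from .io_formats import GenotypeTable
from .linkage import recode_to_parental, screen_framework
from .pedigree_sim import SimConfig, TruthSet, simulate_fullsib, simulate_test_markers
from .validation_diversity import (
    ValidationClass, classify_assignment, validation_summary,
)


@dataclass
class BinMappingRun:
    """Everything produced by one simulated bin-mapping experiment."""

    config: SimConfig
    truth: TruthSet
    framework_table: GenotypeTable
    test_table: GenotypeTable
    bin_set: list[str]
    selection_report: dict
    bins_f: BinMap
    bins_m: BinMap
    bin_stats: dict
    assignments: list[AssignmentResult]
    assignment_summary: dict
    test_info: pd.DataFrame
    accuracy: dict
    validation: dict = field(default_factory=dict)


def true_bin_hit(result: AssignmentResult, binmap: BinMap,
                 lg: int, position: float) -> bool:
    """Did an assignment land in the marker's true bin or an adjacent one?"""
    true_code = binmap.find_bin(lg, position).code
    if true_code in result.bin_codes:
        return True
    return any(binmap.adjacent(true_code, c) for c in result.bin_codes)


def score_assignments(
    assignments: list[AssignmentResult],
    bins_f: BinMap,
    bins_m: BinMap,
    test_info: pd.DataFrame,
) -> dict:
    """Fraction of non-ambiguous assignments in the true or an adjacent bin."""
    hits = {"F": 0, "M": 0}
    totals = {"F": 0, "M": 0}
    for res in assignments:
        if not res.assigned:
            continue
        binmap = bins_f if res.parent == "F" else bins_m
        info = test_info.loc[res.marker_id]
        totals[res.parent] += 1
        if true_bin_hit(res, binmap, int(info["lg"]), float(info["position"])):
            hits[res.parent] += 1
    total = totals["F"] + totals["M"]
    return {
        "n_scored": total,
        "hit_rate": (hits["F"] + hits["M"]) / total if total else float("nan"),
        "hit_rate_F": hits["F"] / totals["F"] if totals["F"] else float("nan"),
        "hit_rate_M": hits["M"] / totals["M"] if totals["M"] else float("nan"),
    }


def framework_bin_codes(binmap: BinMap, map_df: pd.DataFrame) -> dict[str, str]:
    """Bin code containing each framework marker's map position."""
    return {
        row.marker: binmap.find_bin(int(row.linkage_group), float(row.position)).code
        for row in map_df.itertuples(index=False)
    }


def validate_on_extended(
    assignments: list[AssignmentResult],
    framework_table,
    test_table,
    bins_f: BinMap,
    bins_m: BinMap,
    map_f: pd.DataFrame,
    map_m: pd.DataFrame,
    extended_individuals: list[str],
    lod_threshold: float = 3.0,
) -> dict:
    """Classify every assigned marker (classes A-D) on the extended progeny."""
    rec_fw = recode_to_parental(framework_table.subset(individuals=extended_individuals))
    rec_test = recode_to_parental(test_table.subset(individuals=extended_individuals))
    out: dict = {}
    for parent, binmap, map_df in (("F", bins_f, map_f), ("M", bins_m, map_m)):
        fw_mat = rec_fw.female if parent == "F" else rec_fw.male
        test_mat = rec_test.female if parent == "F" else rec_test.male
        fw_codes = framework_bin_codes(binmap, map_df)
        fw_mat = fw_mat.loc[[m for m in fw_mat.index if m in fw_codes]]
        classes: list[ValidationClass] = []
        for res in assignments:
            if res.parent != parent or not res.assigned:
                continue
            if res.marker_id not in test_mat.index:
                continue
            classes.append(classify_assignment(
                res.marker_id,
                test_mat.loc[res.marker_id].to_numpy(),
                res.bin_codes,
                fw_mat,
                fw_codes,
                binmap,
                lod_threshold=lod_threshold,
            ))
        out[parent] = {
            "classes": classes,
            "summary": validation_summary(classes) if classes else None,
        }
    both = out["F"]["classes"] + out["M"]["classes"]
    out["overall"] = validation_summary(both) if both else None
    return out


def run_binmapping(
    config: SimConfig | None = None,
    n_test_markers: int = 250,
    n_extended: int = 92,
    lod_threshold: float = 3.0,
    selection: SelectionConfig | None = None,
    options: AssignOptions | None = None,
    validate: bool = True,
) -> BinMappingRun:
    """Run the full simulated bin-mapping experiment."""
    config = config or SimConfig()
    selection = selection or SelectionConfig()

    table, truth = simulate_fullsib(config)
    kept_inds, kept_markers = screen_framework(table, max_missing_individual=0.5)
    rec = recode_to_parental(table.subset(individuals=kept_inds))

    profiles = build_profiles(rec.female, rec.male, truth.map_f, truth.map_m)
    bin_set, sel_report = select_bin_set(
        profiles, truth.map_f, truth.map_m, selection,
        group_length=config.lg_length_cM,
    )
    bins_f, bins_m, bin_stats = build_bins(
        bin_set, rec.female, rec.male, truth.map_f, truth.map_m,
        group_length=config.lg_length_cM,
    )

    test_table, test_info = simulate_test_markers(truth, n_test_markers)
    results, summary = assign_catalog(
        test_table.subset(individuals=bin_set), bins_f, bins_m, options
    )
    accuracy = score_assignments(results, bins_f, bins_m, test_info)

    run = BinMappingRun(
        config=config, truth=truth, framework_table=table,
        test_table=test_table, bin_set=bin_set,
        selection_report=sel_report, bins_f=bins_f, bins_m=bins_m,
        bin_stats=bin_stats, assignments=results, assignment_summary=summary,
        test_info=test_info, accuracy=accuracy,
    )
    if validate:
        rng = np.random.default_rng(config.seed + 2)
        pool = [i for i in kept_inds]
        ext = sorted(rng.choice(pool, size=min(n_extended, len(pool)),
                                replace=False).tolist())
        run.validation = validate_on_extended(
            results, table, test_table, bins_f, bins_m,
            truth.map_f, truth.map_m, ext, lod_threshold=lod_threshold,
        )
    return run
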