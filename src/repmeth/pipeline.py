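"""End-to-end orchestration: from count tables to a differential report.

``run_wgbs_analysis`` composes the library steps in the order the analysis
runs: library equalisation, genome-wide window survey, ICR purity check,
repeat scoring, differential calling, subfamily composition, distribution
shift test, TSS proximity, and control-class analyses.  ``run_benchmark``
wraps simulate-analyse-evaluate replicates against the truth table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .differential import (ControlClassResult, call_differential,
                           control_class_analysis, random_regions, shift_test,
                           subfamily_counts, tss_proximity,
                           write_differential_bed)
from .errors import ValidationError
from .methylation_io import (GenomicInterval, MethylomeSample,
                             equalize_libraries, merge_strands, read_bed4,
                             read_chrom_sizes, read_cytosine_report,
                             read_repeat_annotation)
from .repeat_methylation import icr_summary, score_repeats, window_scores
from .synthetic_data import SimulationConfig, build_genome, \
    simulate_methylomes


@dataclass
class RunConfig:
    """Inputs, filter parameters and seeds for one pipeline run."""

    wt_report: str
    mut_report: str
    repeats_bed: str
    tss_bed: str
    icr_bed: str
    chrom_sizes: str
    out_dir: str
    repeat_class: str = "LTR/ERVK"
    control_classes: tuple[str, ...] = ("LINE/L1", "SINE/B1")
    min_cov: int = 8
    bias_fraction: float = 0.6
    min_cpgs: int = 8
    dm_threshold_pp: float = 10.0
    window_size: int = 10_000
    tss_distance: int = 10_000
    shift_scope: str = "dm_subset"
    n_random_regions: int = 1000
    random_region_length: int = 1000
    seed: int = 0


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _check_chromosomes(samples: Sequence[MethylomeSample], sizes: dict[str, int],
                       annotation_chroms: set[str]) -> None:
    known = set(sizes)
    for sample in samples:
        extra = set(sample.chroms) - known
        if extra:
            raise ValidationError(
                f"sample {sample.sample_id} has chromosomes missing from the "
                f"size table: {sorted(extra)}")
    extra = annotation_chroms - known
    if extra:
        raise ValidationError(
            f"annotation has chromosomes missing from the size table: "
            f"{sorted(extra)}")


def run_wgbs_analysis(cfg: RunConfig) -> dict:
    """Run the full two-sample analysis and write all outputs plus a summary."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- load & validate everything before computing anything -------------
    wt = merge_strands(read_cytosine_report(cfg.wt_report), "wt")
    mut = merge_strands(read_cytosine_report(cfg.mut_report), "mut")
    sizes = read_chrom_sizes(cfg.chrom_sizes)
    repeats = read_repeat_annotation(cfg.repeats_bed)
    tss = [(chrom, start) for chrom, start, _end, _name in read_bed4(cfg.tss_bed)]
    icrs = [(GenomicInterval(chrom, start, end), name)
            for chrom, start, end, name in read_bed4(cfg.icr_bed)]
    _check_chromosomes([wt, mut], sizes,
                       {r.interval.chrom for r in repeats})

    # --- library equalisation ---------------------------------------------
    totals_before = (wt.total_count, mut.total_count)
    wt, mut = equalize_libraries(wt, mut, seed=cfg.seed)

    # --- genome-wide survey and purity check ------------------------------
    windows = window_scores(wt, mut, sizes, window_size=cfg.window_size)
    pd.DataFrame(
        [{"chrom": w.window.chrom, "start": w.window.start, "end": w.window.end,
          "meth_wt": w.meth_wt, "meth_mut": w.meth_mut, "n_cpgs": w.n_cpgs}
         for w in windows.windows]
    ).to_csv(out_dir / "windows.tsv", sep="\t", index=False)

    icr_table = icr_summary(wt, mut, icrs)
    icr_table.to_csv(out_dir / "icr_summary.tsv", sep="\t", index=False)

    # --- repeat scoring and differential calling --------------------------
    target = [r for r in repeats if r.class_family == cfg.repeat_class]
    if not target:
        raise ValidationError(f"no elements of class {cfg.repeat_class!r}")
    scoring = score_repeats(wt, mut, target, min_cpgs=cfg.min_cpgs,
                            min_cov=cfg.min_cov,
                            bias_fraction=cfg.bias_fraction)
    scoring.to_frame().to_csv(out_dir / "region_scores.tsv", sep="\t",
                              index=False)
    calls = call_differential(scoring.scores, cfg.dm_threshold_pp)
    write_differential_bed(calls, out_dir / "differential_calls.bed")
    subfam = subfamily_counts(calls)
    subfam.to_csv(out_dir / "subfamily_counts.tsv", sep="\t", index=False)

    shift_scope = cfg.shift_scope
    try:
        shift = shift_test(scoring.scores, scope=shift_scope,
                           threshold_pp=cfg.dm_threshold_pp)
    except ValueError:
        shift_scope = "all"
        shift = shift_test(scoring.scores, scope="all",
                           threshold_pp=cfg.dm_threshold_pp)

    hypo_calls = [c for c in calls if c.direction == "hypo"]
    n_hypo_near_tss = 0
    if hypo_calls and tss:
        n_hypo_near_tss, _ = tss_proximity(hypo_calls, tss, cfg.tss_distance)

    # --- control classes and random regions -------------------------------
    controls: dict[str, dict] = {}
    for control_class in cfg.control_classes:
        elements = [r for r in repeats if r.class_family == control_class]
        if not elements:
            continue
        res = control_class_analysis(
            wt, mut, elements, control_class, threshold_pp=cfg.dm_threshold_pp,
            min_cpgs=cfg.min_cpgs, min_cov=cfg.min_cov,
            bias_fraction=cfg.bias_fraction)
        controls[control_class] = _control_summary(res)
    if cfg.n_random_regions > 0:
        regions = random_regions(sizes, cfg.n_random_regions,
                                 cfg.random_region_length, seed=cfg.seed)
        res = control_class_analysis(
            wt, mut, regions, "random_1kb", threshold_pp=cfg.dm_threshold_pp,
            min_cpgs=cfg.min_cpgs, min_cov=cfg.min_cov,
            bias_fraction=cfg.bias_fraction)
        controls["random_1kb"] = _control_summary(res)

    summary = {
        "parameters": {
            "repeat_class": cfg.repeat_class, "min_cov": cfg.min_cov,
            "bias_fraction": cfg.bias_fraction, "min_cpgs": cfg.min_cpgs,
            "dm_threshold_pp": cfg.dm_threshold_pp,
            "window_size": cfg.window_size, "tss_distance": cfg.tss_distance,
            "shift_scope_requested": cfg.shift_scope,
            "n_random_regions": cfg.n_random_regions,
            "random_region_length": cfg.random_region_length,
            "seed": cfg.seed,
        },
        "inputs": {name: _sha256(path) for name, path in (
            ("wt_report", cfg.wt_report), ("mut_report", cfg.mut_report),
            ("repeats_bed", cfg.repeats_bed), ("tss_bed", cfg.tss_bed),
            ("icr_bed", cfg.icr_bed), ("chrom_sizes", cfg.chrom_sizes))},
        "library_totals_before": totals_before,
        "library_totals_after": (wt.total_count, mut.total_count),
        "n_windows": len(windows.windows),
        "window_median_wt": windows.median_wt,
        "window_median_mut": windows.median_mut,
        "icr_purity_ok": bool(icr_table["purity_ok"].all()),
        "n_input_elements": scoring.n_input,
        "n_scored": scoring.n_scored,
        "n_excluded": scoring.n_excluded,
        "n_dm": len(calls),
        "n_hypo": sum(c.direction == "hypo" for c in calls),
        "n_hyper": sum(c.direction == "hyper" for c in calls),
        "shift_scope": shift_scope,
        "shift_u": shift.u_statistic,
        "shift_p": shift.p_value,
        "n_hypo_near_tss": n_hypo_near_tss,
        "controls": controls,
        "multiple_testing_note": ("p-values are unadjusted; no multiple-"
                                  "testing correction is applied"),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _control_summary(res: ControlClassResult) -> dict:
    return {"n_scored": res.scoring.n_scored, "n_dm": len(res.calls),
            "fraction_dm": res.fraction_dm, "shift_p": res.shift.p_value}


# ---------------------------------------------------------------------------
# Benchmarking against the simulator's truth
# ---------------------------------------------------------------------------

def evaluate_recovery(scoring, calls, truth: pd.DataFrame
                      ) -> tuple[float, float, int, int]:
    """(sensitivity, FPR, n_planted_scored, n_unplanted_scored) vs truth.

    Evaluated over scored elements only: an unscored element (too few
    qualifying CpGs) does not count against either rate.  Sensitivity is NaN
    when no planted element was scored.
    """
    truth_idx = truth.set_index(["chrom", "start", "end"])["planted"]
    called = set()
    for c in calls:
        iv = c.score.interval
        called.add((iv.chrom, iv.start, iv.end))
    tp = fp = n_planted = n_unplanted = 0
    for s in scoring.scores:
        iv = s.interval
        key = (iv.chrom, iv.start, iv.end)
        is_planted = bool(truth_idx.get(key, False))
        if is_planted:
            n_planted += 1
            tp += key in called
        else:
            n_unplanted += 1
            fp += key in called
    sensitivity = tp / n_planted if n_planted else float("nan")
    fpr = fp / n_unplanted if n_unplanted else float("nan")
    return sensitivity, fpr, n_planted, n_unplanted


def analyse_simulation(cfg: SimulationConfig, repeat_class: str = "LTR/ERVK",
                       dm_threshold_pp: float = 10.0, min_cpgs: int = 8,
                       min_cov: int = 8, bias_fraction: float = 0.6,
                       shift_scope: str = "all") -> dict:
    """Simulate one methylome pair and analyse it in memory against truth."""
    genome = build_genome(cfg)
    wt, mut, truth = simulate_methylomes(genome, cfg)
    target = [r for r in genome.repeats if r.class_family == repeat_class]
    scoring = score_repeats(wt, mut, target, min_cpgs=min_cpgs,
                            min_cov=min_cov, bias_fraction=bias_fraction)
    calls = call_differential(scoring.scores, dm_threshold_pp)
    shift = shift_test(scoring.scores, scope=shift_scope,
                       threshold_pp=dm_threshold_pp)
    sensitivity, fpr, n_planted, n_unplanted = evaluate_recovery(
        scoring, calls, truth)
    return {
        "seed": cfg.seed, "n_scored": scoring.n_scored, "n_dm": len(calls),
        "n_hypo": sum(c.direction == "hypo" for c in calls),
        "n_hyper": sum(c.direction == "hyper" for c in calls),
        "sensitivity": sensitivity, "fpr": fpr,
        "n_planted_scored": n_planted, "n_unplanted_scored": n_unplanted,
        "shift_p": shift.p_value,
        "genome": genome, "scoring": scoring, "calls": calls, "truth": truth,
        "wt": wt, "mut": mut,
    }


def run_benchmark(cfg: SimulationConfig, replicates: int) -> pd.DataFrame:
    """Simulate/analyse/evaluate ``replicates`` seeds; one row per replicate."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for i in range(replicates):
        rep_cfg = replace(cfg, seed=cfg.seed + i)
        res = analyse_simulation(rep_cfg)
        rows.append({k: res[k] for k in
                     ("seed", "n_scored", "n_dm", "n_hypo", "n_hyper",
                      "sensitivity", "fpr", "shift_p")})
    return pd.DataFrame(rows)
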