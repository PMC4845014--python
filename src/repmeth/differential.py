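"""Differential-methylation calling and distribution-shift statistics.

A repeat element is called differentially methylated when the absolute
mutant-minus-wild-type difference exceeds a percentage-point threshold
(strictly; a delta of exactly the threshold is not called).  The overall
shift between the two samples' score distributions is tested with a
Mann-Whitney U test, and control analyses (abundant non-ERVK repeat classes,
random genomic regions) verify that the shift is class-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .methylation_io import GenomicInterval, MethylomeSample, RepeatElement
from .repeat_methylation import RegionScore, RepeatScoring, score_repeats

HYPO = "hypo"
HYPER = "hyper"


@dataclass(frozen=True)
class DifferentialCall:
    """A region score flagged hypo- (lower in mutant) or hypermethylated."""

    score: RegionScore
    direction: str

    @property
    def delta(self) -> float:
        return self.score.delta

    @property
    def subfamily(self) -> str | None:
        return self.score.subfamily


def call_differential(scores: Sequence[RegionScore],
                      threshold_pp: float = 10.0) -> list[DifferentialCall]:
    """All scores with |delta| strictly above ``threshold_pp``, labelled by sign."""
    if threshold_pp < 0:
        raise ValueError("threshold_pp must be >= 0")
    calls = []
    for s in scores:
        if abs(s.delta) > threshold_pp:
            calls.append(DifferentialCall(s, HYPO if s.delta < 0 else HYPER))
    return calls


def subfamily_counts(calls: Sequence[DifferentialCall],
                     top_n: int = 20) -> pd.DataFrame:
    """Per-subfamily hypo/hyper call counts, most frequent first.

    Sorted by total calls descending, ties broken lexicographically by
    subfamily name, truncated to the ``top_n`` most frequent subfamilies.
    """
    counts: dict[str, list[int]] = {}
    for c in calls:
        sub = c.subfamily or "."
        row = counts.setdefault(sub, [0, 0])
        row[0 if c.direction == HYPO else 1] += 1
    rows = [{"subfamily": sub, "n_hypo": h, "n_hyper": y, "total": h + y}
            for sub, (h, y) in counts.items()]
    frame = pd.DataFrame(rows, columns=["subfamily", "n_hypo", "n_hyper", "total"])
    if frame.empty:
        return frame
    frame = frame.sort_values(["total", "subfamily"],
                              ascending=[False, True], kind="stable")
    return frame.head(top_n).reset_index(drop=True)


@dataclass(frozen=True)
class ShiftTestResult:
    u_statistic: float
    p_value: float
    n: int
    scope: str
    alternative: str


def shift_test(scores: Sequence[RegionScore], scope: str = "dm_subset",
               alternative: str = "two-sided",
               threshold_pp: float = 10.0) -> ShiftTestResult:
    """Mann-Whitney U of mutant vs wild-type methylation values.

    ``scope`` selects either every scored element ("all") or only those past
    the differential threshold ("dm_subset").  Uses midranks for ties; exact
    null enumeration for small samples (both n <= 20, no ties), otherwise the
    tie-corrected normal approximation.
    """
    if scope == "dm_subset":
        selected = [s for s in scores if abs(s.delta) > threshold_pp]
    elif scope == "all":
        selected = list(scores)
    else:
        raise ValueError(f"scope must be 'all' or 'dm_subset', got {scope!r}")
    if len(selected) < 2:
        raise ValueError("need at least 2 elements in scope for the shift test")
    mut = np.array([s.meth_mut for s in selected])
    wt = np.array([s.meth_wt for s in selected])
    pooled = np.concatenate([mut, wt])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(selected) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(mut, wt, alternative=alternative, method=method)
    return ShiftTestResult(float(res.statistic), float(res.pvalue),
                           len(selected), scope, alternative)


def tss_proximity(calls: Sequence[DifferentialCall],
                  tss: Sequence[tuple[str, int]], max_distance: int = 10_000
                  ) -> tuple[int, list[tuple[DifferentialCall, int]]]:
    """Count calls whose element lies within ``max_distance`` bp of any TSS.

    Distance is measured from the element boundary (0 when the TSS falls
    inside the element); the bound is inclusive.
    """
    if not tss:
        raise ValueError("TSS list must be non-empty")
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in tss:
        by_chrom.setdefault(chrom, [])
    for chrom, pos in tss:
        by_chrom[chrom].append(pos)
    by_chrom = {c: np.sort(np.asarray(p, dtype=np.int64))
                for c, p in by_chrom.items()}
    annotated: list[tuple[DifferentialCall, int]] = []
    count = 0
    for call in calls:
        iv = call.score.interval
        positions = by_chrom.get(iv.chrom)
        if positions is None or len(positions) == 0:
            annotated.append((call, -1))
            continue
        # nearest TSS to the interval: gap from the closer boundary,
        # 0 when the TSS falls inside the element
        idx = np.searchsorted(positions, iv.start)
        candidates = positions[max(0, idx - 1): idx + 2]
        dist = int(min(max(iv.start - p, p - iv.end, 0) for p in candidates))
        annotated.append((call, dist))
        if dist <= max_distance:
            count += 1
    return count, annotated


def random_regions(chrom_sizes: Mapping[str, int], n: int, length: int = 1000,
                   seed: int = 0) -> list[GenomicInterval]:
    """Draw ``n`` random fixed-length intervals, chromosomes chosen by length."""
    if n <= 0:
        raise ValueError("n must be positive")
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    if np.any(sizes < length):
        raise ValueError(f"every chromosome must be at least {length} bp")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    regions = []
    for i in picks:
        start = int(rng.integers(0, chrom_sizes[chroms[i]] - length + 1))
        regions.append(GenomicInterval(chroms[i], start, start + length))
    return regions


@dataclass
class ControlClassResult:
    label: str
    scoring: RepeatScoring
    calls: list[DifferentialCall]
    shift: ShiftTestResult
    fraction_dm: float


def control_class_analysis(wt: MethylomeSample, mut: MethylomeSample,
                           annotation: Sequence[RepeatElement | GenomicInterval],
                           label: str, threshold_pp: float = 10.0,
                           min_cpgs: int = 8, min_cov: int = 8,
                           bias_fraction: float = 0.6,
                           shift_scope: str = "all") -> ControlClassResult:
    """Run the full score/call/shift analysis on a control annotation set.

    Applies filters identical to the main repeat analysis, so a control class
    with no real effect should show no distribution shift (p well above any
    significance bar) and few, direction-balanced differential calls.
    """
    if not annotation:
        raise ValueError("annotation must be non-empty")
    elements = [a if isinstance(a, RepeatElement)
                else RepeatElement(a, label, label) for a in annotation]
    scoring = score_repeats(wt, mut, elements, min_cpgs=min_cpgs,
                            min_cov=min_cov, bias_fraction=bias_fraction)
    calls = call_differential(scoring.scores, threshold_pp)
    shift = shift_test(scoring.scores, scope=shift_scope,
                       threshold_pp=threshold_pp)
    frac = len(calls) / scoring.n_scored if scoring.n_scored else float("nan")
    return ControlClassResult(label, scoring, calls, shift, frac)


def write_differential_bed(calls: Sequence[DifferentialCall], path) -> None:
    """BED6+4 export: name=subfamily, score=delta, then direction and scores."""
    with open(path, "w") as fh:
        for c in calls:
            iv = c.score.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.subfamily or '.'}\t"
                     f"{c.delta:.4f}\t{iv.strand}\t{c.direction}\t"
                     f"{c.score.n_cpgs}\t{c.score.meth_wt:.4f}\t"
                     f"{c.score.meth_mut:.4f}\n")
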