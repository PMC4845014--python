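"""CpG qualification and coverage-weighted methylation scoring of regions.

A CpG enters the two-sample repeat analysis only if it is covered by at
least ``min_cov`` reads in *both* samples and the lower of the two coverages
is at least ``bias_fraction`` of the higher (so a site sequenced deeply in
one sample and shallowly in the other cannot dominate a region).  A repeat
element is scored only if at least ``min_cpgs`` CpGs qualify; its score per
sample is the coverage-weighted mean of per-CpG methylation percentages,

    score = sum_i(meth_pct_i * cov_i) / sum_i(cov_i),

with each sample weighted by its own coverages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import UndefinedScoreError, ValidationError
from .methylation_io import GenomicInterval, MethylomeSample, RepeatElement

Region = Union[GenomicInterval, RepeatElement]

BIAS_RULES = ("ratio", "deviation")


@dataclass(frozen=True)
class QualifiedCpG:
    chrom: str
    pos: int
    cov_wt: int
    cov_mut: int
    meth_pct_wt: float
    meth_pct_mut: float


@dataclass(frozen=True)
class RegionScore:
    """Paired methylation score for one region.

    ``delta`` is mutant minus wild type in percentage points, so negative
    values mean the region lost methylation in the mutant.
    """

    region: Region
    n_cpgs: int
    meth_wt: float
    meth_mut: float

    @property
    def delta(self) -> float:
        return self.meth_mut - self.meth_wt

    @property
    def interval(self) -> GenomicInterval:
        return self.region.interval if isinstance(self.region, RepeatElement) else self.region

    @property
    def subfamily(self) -> str | None:
        return self.region.subfamily if isinstance(self.region, RepeatElement) else None


@dataclass(frozen=True)
class WindowScore:
    window: GenomicInterval
    meth_wt: float
    meth_mut: float
    n_cpgs: int


@dataclass
class RepeatScoring:
    """Scores plus bookkeeping about elements that failed the CpG threshold."""

    scores: list[RegionScore]
    n_input: int
    n_excluded: int

    @property
    def n_scored(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.scores:
            iv = s.interval
            rows.append({
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "subfamily": s.subfamily or ".",
                "class_family": (s.region.class_family
                                 if isinstance(s.region, RepeatElement) else "."),
                "n_cpgs": s.n_cpgs, "meth_wt": s.meth_wt,
                "meth_mut": s.meth_mut, "delta": s.delta,
            })
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "subfamily", "class_family",
                           "n_cpgs", "meth_wt", "meth_mut", "delta"])


def _interval_of(region: Region) -> GenomicInterval:
    return region.interval if isinstance(region, RepeatElement) else region


def _bias_ok(cov_a: np.ndarray, cov_b: np.ndarray, bias_fraction: float,
             bias_rule: str) -> np.ndarray:
    lo = np.minimum(cov_a, cov_b)
    hi = np.maximum(cov_a, cov_b)
    if bias_rule == "ratio":
        return lo >= bias_fraction * hi
    # "deviation": relative coverage difference no larger than bias_fraction
    return (hi - lo) <= bias_fraction * hi


def _paired_region(wt: MethylomeSample, mut: MethylomeSample, region: Region
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Aligned (pos, m_wt, cov_wt, m_mut, cov_mut) for CpGs present in both samples."""
    iv = _interval_of(region)
    pos_w, m_w, u_w = wt.region_arrays(iv.chrom, iv.start, iv.end)
    pos_m, m_m, u_m = mut.region_arrays(iv.chrom, iv.start, iv.end)
    common, iw, im = np.intersect1d(pos_w, pos_m, return_indices=True)
    return common, m_w[iw], m_w[iw] + u_w[iw], m_m[im], m_m[im] + u_m[im]


def qualify_cpgs(wt: MethylomeSample, mut: MethylomeSample, region: Region,
                 min_cov: int = 8, bias_fraction: float = 0.6,
                 bias_rule: str = "ratio") -> list[QualifiedCpG]:
    """CpGs inside ``region`` passing the two-sample coverage filters.

    Boundary behaviour: coverage exactly ``min_cov`` in both samples passes;
    a site with coverages (10, 5) fails the default ratio rule (5 < 0.6*10)
    while (10, 6) passes.
    """
    if min_cov < 1:
        raise ValueError(f"min_cov must be >= 1, got {min_cov}")
    if not (0 < bias_fraction <= 1):
        raise ValueError(f"bias_fraction must be in (0, 1], got {bias_fraction}")
    if bias_rule not in BIAS_RULES:
        raise ValueError(f"bias_rule must be one of {BIAS_RULES}")
    pos, m_w, c_w, m_m, c_m = _paired_region(wt, mut, region)
    keep = (c_w >= min_cov) & (c_m >= min_cov) & _bias_ok(c_w, c_m, bias_fraction,
                                                          bias_rule)
    return [
        QualifiedCpG(_interval_of(region).chrom, int(p), int(cw), int(cm),
                     100.0 * mw / cw, 100.0 * mm / cm)
        for p, mw, cw, mm, cm in zip(pos[keep], m_w[keep], c_w[keep],
                                     m_m[keep], c_m[keep])
    ]


def weighted_region_score(cpgs: Sequence[tuple[float, int]]) -> float:
    """Coverage-weighted mean of per-CpG methylation percentages.

    Equivalent to normalising each CpG's percentage by the region's total
    read count, weighting by the CpG's own read count and summing.
    """
    if len(cpgs) == 0:
        raise UndefinedScoreError("cannot score a region with no CpGs")
    meth = np.array([m for m, _ in cpgs], dtype=float)
    cov = np.array([c for _, c in cpgs], dtype=float)
    if np.any(cov <= 0):
        raise ValueError("all coverages must be positive")
    return float(np.dot(meth, cov) / cov.sum())


def score_repeats(wt: MethylomeSample, mut: MethylomeSample,
                  repeats: Sequence[RepeatElement], min_cpgs: int = 8,
                  min_cov: int = 8, bias_fraction: float = 0.6,
                  bias_rule: str = "ratio") -> RepeatScoring:
    """Score every repeat with at least ``min_cpgs`` qualifying CpGs.

    Elements below the CpG threshold are excluded (never imputed) and counted
    in the returned summary.  Overlapping elements are scored independently.
    """
    if min_cpgs < 1:
        raise ValueError(f"min_cpgs must be >= 1, got {min_cpgs}")
    scores: list[RegionScore] = []
    n_excluded = 0
    for elem in repeats:
        cpgs = qualify_cpgs(wt, mut, elem, min_cov=min_cov,
                            bias_fraction=bias_fraction, bias_rule=bias_rule)
        if len(cpgs) < min_cpgs:
            n_excluded += 1
            continue
        meth_wt = weighted_region_score([(c.meth_pct_wt, c.cov_wt) for c in cpgs])
        meth_mut = weighted_region_score([(c.meth_pct_mut, c.cov_mut) for c in cpgs])
        scores.append(RegionScore(elem, len(cpgs), meth_wt, meth_mut))
    return RepeatScoring(scores, n_input=len(repeats), n_excluded=n_excluded)


@dataclass
class WindowResult:
    windows: list[WindowScore]
    median_wt: float
    median_mut: float


def _sample_window_score(sample: MethylomeSample, chrom: str, start: int,
                         end: int) -> tuple[float, int] | None:
    pos, meth, unmeth = sample.region_arrays(chrom, start, end)
    cov = meth + unmeth
    covered = cov > 0
    if not covered.any():
        return None
    total = cov[covered].sum()
    return float(100.0 * meth[covered].sum() / total), int(covered.sum())


def window_scores(wt: MethylomeSample, mut: MethylomeSample,
                  chrom_sizes: Mapping[str, int], window_size: int = 10_000,
                  min_cpgs: int = 1) -> WindowResult:
    """Tile the genome into fixed windows and score each sample per window.

    Windows run from coordinate 0 in non-overlapping steps; the last window
    of a chromosome may be shorter.  The global filters are deliberately lax
    here (any covered CpG counts, no between-sample bias rule) because the
    genome-wide survey precedes the stringent repeat-level filtering.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if not chrom_sizes:
        raise ValueError("empty chromosome-size table")
    windows: list[WindowScore] = []
    for chrom, length in chrom_sizes.items():
        for start in range(0, length, window_size):
            end = min(start + window_size, length)
            res_wt = _sample_window_score(wt, chrom, start, end)
            res_mut = _sample_window_score(mut, chrom, start, end)
            if res_wt is None or res_mut is None:
                continue
            if res_wt[1] < min_cpgs or res_mut[1] < min_cpgs:
                continue
            windows.append(WindowScore(GenomicInterval(chrom, start, end),
                                       res_wt[0], res_mut[0],
                                       max(res_wt[1], res_mut[1])))
    if windows:
        median_wt = float(np.median([w.meth_wt for w in windows]))
        median_mut = float(np.median([w.meth_mut for w in windows]))
    else:
        median_wt = median_mut = float("nan")
    return WindowResult(windows, median_wt, median_mut)


def icr_summary(wt: MethylomeSample, mut: MethylomeSample,
                icrs: Sequence[tuple[GenomicInterval, str]],
                maternal_threshold: float = 15.0) -> pd.DataFrame:
    """Score imprinting control regions and flag sperm-purity consistency.

    Sperm is globally hypomethylated at maternally methylated ICRs, so a
    maternal ICR scoring below ``maternal_threshold`` percent in both samples
    supports sample purity.  Paternal ICRs are reported but not flagged.
    """
    rows = []
    for interval, label in icrs:
        row: dict = {"chrom": interval.chrom, "start": interval.start,
                     "end": interval.end, "label": label}
        for name, sample in (("meth_wt", wt), ("meth_mut", mut)):
            pos, meth, unmeth = sample.region_arrays(interval.chrom,
                                                     interval.start, interval.end)
            cov = meth + unmeth
            covered = cov > 0
            row[name] = (float(100.0 * meth[covered].sum() / cov[covered].sum())
                         if covered.any() else float("nan"))
        if label == "maternal":
            row["purity_ok"] = bool(row["meth_wt"] < maternal_threshold
                                    and row["meth_mut"] < maternal_threshold)
        else:
            row["purity_ok"] = True
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label",
                                       "meth_wt", "meth_mut", "purity_ok"])
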