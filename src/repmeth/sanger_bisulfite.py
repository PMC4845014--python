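"""Clone-based Sanger bisulphite analysis.

Each amplicon is PCR-amplified from bisulphite-converted DNA, cloned, and a
handful of clones sequenced per individual, giving a clones x CpG-positions
matrix of methylated/unmethylated calls.  Conversion efficiency is estimated
from non-CpG cytosines (which should all convert); individuals are summarised
as the percentage of methylated CpG calls pooled over their clones, and
genotype groups are compared with a two-sided t-test on those percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ParseError, UndefinedScoreError, ValidationError

CONVERSION_THRESHOLD = 97.0  # percent; standard bisulphite QC bar

METHYLATED = 1.0
UNMETHYLATED = 0.0
# missing calls are np.nan in the matrix


@dataclass
class CloneMatrix:
    """Clone x CpG call matrix for one amplicon in one individual.

    ``calls`` holds 1.0 (methylated), 0.0 (unmethylated) or NaN (missing);
    ``non_cpg_c_*`` are the conversion-QC counts over non-CpG cytosines.
    """

    amplicon_id: str
    individual_id: str
    genotype: str
    calls: np.ndarray
    non_cpg_c_total: int = 0
    non_cpg_c_converted: int = 0

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2 or self.calls.size == 0:
            raise ValidationError("calls must be a non-empty 2-D matrix")
        valid = np.isnan(self.calls) | (self.calls == 0.0) | (self.calls == 1.0)
        if not valid.all():
            raise ValidationError("calls must contain only 0, 1 or NaN")
        if self.non_cpg_c_converted > self.non_cpg_c_total:
            raise ValidationError("converted count exceeds total non-CpG cytosines")
        if self.genotype not in ("wt", "mut"):
            raise ValidationError(f"genotype must be wt or mut, got {self.genotype!r}")

    @property
    def n_clones(self) -> int:
        return self.calls.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.calls.shape[1]


def conversion_rate(m: CloneMatrix,
                    threshold: float = CONVERSION_THRESHOLD) -> tuple[float, bool]:
    """Percent of non-CpG cytosines converted, with a pass/fail QC flag.

    The flag is True when the rate meets the threshold (a rate exactly at
    the threshold passes).
    """
    if m.non_cpg_c_total == 0:
        raise UndefinedScoreError("no non-CpG cytosines observed; rate undefined")
    rate = 100.0 * m.non_cpg_c_converted / m.non_cpg_c_total
    return rate, rate >= threshold


def individual_percent(m: CloneMatrix) -> float:
    """Percent methylated CpG calls, pooled over all clones of the individual."""
    observed = ~np.isnan(m.calls)
    n_obs = int(observed.sum())
    if n_obs == 0:
        raise UndefinedScoreError("all calls missing; percentage undefined")
    return float(100.0 * np.nansum(m.calls) / n_obs)


def genotype_ttest(wt_percents: Sequence[float], mut_percents: Sequence[float],
                   equal_var: bool = False) -> tuple[float, float]:
    """Two-sided t-test on per-individual methylation percentages.

    Welch (unequal-variance) by default; set ``equal_var=True`` for the
    pooled-variance variant.  Two groups with zero variance and equal means
    return (0, 1) by convention.
    """
    wt = np.asarray(wt_percents, dtype=float)
    mut = np.asarray(mut_percents, dtype=float)
    if len(wt) < 2 or len(mut) < 2:
        raise ValueError("need at least 2 individuals per genotype group")
    if wt.std() == 0 and mut.std() == 0:
        if wt.mean() == mut.mean():
            return 0.0, 1.0
    res = stats.ttest_ind(wt, mut, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def amplicon_summary(matrices: Sequence[CloneMatrix]
                     ) -> dict[str, dict[str, object]]:
    """Per-amplicon group means and t-test over individual percentages."""
    by_amplicon: dict[str, dict[str, list[float]]] = {}
    for m in matrices:
        groups = by_amplicon.setdefault(m.amplicon_id, {"wt": [], "mut": []})
        groups[m.genotype].append(individual_percent(m))
    out: dict[str, dict[str, object]] = {}
    for amplicon, groups in by_amplicon.items():
        t, p = genotype_ttest(groups["wt"], groups["mut"])
        out[amplicon] = {
            "mean_wt": float(np.mean(groups["wt"])),
            "mean_mut": float(np.mean(groups["mut"])),
            "n_wt": len(groups["wt"]),
            "n_mut": len(groups["mut"]),
            "t": t,
            "p": p,
        }
    return out


# ---------------------------------------------------------------------------
# TSV round-trip and lollipop export
# ---------------------------------------------------------------------------

def write_clone_tsv(matrices: Iterable[CloneMatrix], path: str | Path,
                    conversion_path: str | Path | None = None) -> None:
    """One row per clone: amplicon, individual, genotype, clone, calls (1/0/NA)."""
    matrices = list(matrices)
    with open(path, "w") as fh:
        for m in matrices:
            for i, row in enumerate(m.calls):
                cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
                fh.write(f"{m.amplicon_id}\t{m.individual_id}\t{m.genotype}\t"
                         f"clone{i + 1}\t" + "\t".join(cells) + "\n")
    if conversion_path is not None:
        with open(conversion_path, "w") as fh:
            for m in matrices:
                fh.write(f"{m.amplicon_id}\t{m.individual_id}\t"
                         f"{m.non_cpg_c_total}\t{m.non_cpg_c_converted}\n")


def read_clone_tsv(path: str | Path,
                   conversion_path: str | Path | None = None) -> list[CloneMatrix]:
    groups: dict[tuple[str, str, str], list[list[float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}: line {lineno}: expected >= 5 fields")
            amplicon, individual, genotype = fields[0], fields[1], fields[2]
            row: list[float] = []
            for cell in fields[4:]:
                if cell == "NA":
                    row.append(float("nan"))
                elif cell in ("0", "1"):
                    row.append(float(cell))
                else:
                    raise ParseError(
                        f"{path}: line {lineno}: call must be 0, 1 or NA, got {cell!r}")
            groups.setdefault((amplicon, individual, genotype), []).append(row)
    conversion: dict[tuple[str, str], tuple[int, int]] = {}
    if conversion_path is not None:
        with open(conversion_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                a, i, total, conv = line.rstrip("\n").split("\t")
                conversion[(a, i)] = (int(total), int(conv))
    matrices = []
    for (amplicon, individual, genotype), rows in groups.items():
        total, conv = conversion.get((amplicon, individual), (0, 0))
        matrices.append(CloneMatrix(amplicon, individual, genotype,
                                    np.array(rows), total, conv))
    return matrices


def lollipop_strings(m: CloneMatrix, methylated: str = "●",
                     unmethylated: str = "○", missing: str = "-") -> list[str]:
    """Per-clone strings of filled/open circles for lollipop-style figures."""
    out = []
    for row in m.calls:
        out.append("".join(methylated if v == 1.0
                           else unmethylated if v == 0.0 else missing
                           for v in row))
    return out
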