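"""Coat-colour penetrance analysis for the agouti viable yellow (Avy) allele.

Avy is a metastable epiallele: expression of the yellow coat depends on the
methylation state of an IAP insertion upstream of agouti, so the spectrum of
offspring coat colours (yellow through mottled to silenced pseudoagouti)
reads out epigenetic silencing.  Animals are scored into five categories by
percent yellow coat, pooled into three groups (Y / M / psi), and group
proportions are compared between crosses or genotypes with Pearson
chi-squared tests; genotype ratios are checked against Mendelian expectation
with a goodness-of-fit chi-squared.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ParseError, ValidationError

CATEGORIES5 = ("yellow", "yellow_mottled", "mottled",
               "pseudoagouti_mottled", "pseudoagouti")
CATEGORIES3 = ("Y", "M", "psi")

_POOL = {
    "yellow": "Y",
    "yellow_mottled": "Y",
    "mottled": "M",
    "pseudoagouti_mottled": "psi",
    "pseudoagouti": "psi",
}


@dataclass(frozen=True)
class CoatColourRecord:
    animal_id: str
    cross_id: str
    sire_genotype: str
    dam_genotype: str
    offspring_genotype: str
    avy_parent: str
    category5: str

    def __post_init__(self) -> None:
        if self.category5 not in CATEGORIES5:
            raise ValidationError(f"unknown category {self.category5!r}")
        for g in (self.sire_genotype, self.dam_genotype, self.offspring_genotype):
            if g not in ("wt", "het"):
                raise ValidationError(f"genotype must be wt or het, got {g!r}")
        if self.avy_parent not in ("dam", "sire"):
            raise ValidationError(f"avy_parent must be dam or sire")

    @property
    def category3(self) -> str:
        return _POOL[self.category5]


def categorize(percent_yellow: float) -> str:
    """Map percent yellow coat to the five-category score.

    100 -> yellow; (95, 100) -> yellow_mottled; (25, 95] -> mottled;
    [5, 25] -> pseudoagouti_mottled; [0, 5) -> pseudoagouti.  The category
    edges use half-open conventions so the mapping is total and deterministic
    (in practice the score is assigned by a trained observer, so only the
    broad bands matter).
    """
    if not (0 <= percent_yellow <= 100):
        raise ValueError(f"percent_yellow must be in [0, 100], got {percent_yellow}")
    if percent_yellow == 100:
        return "yellow"
    if percent_yellow > 95:
        return "yellow_mottled"
    if percent_yellow > 25:
        return "mottled"
    if percent_yellow >= 5:
        return "pseudoagouti_mottled"
    return "pseudoagouti"


def pool_categories(category5: str) -> str:
    """Pool five coat categories into Y (yellow), M (mottled), psi (silenced)."""
    if category5 not in _POOL:
        raise ValueError(f"unknown category {category5!r}")
    return _POOL[category5]


@dataclass
class PenetranceTable:
    """Pooled Y/M/psi counts for one group of Avy-carrier offspring."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = {c: int(self.counts.get(c, 0)) for c in CATEGORIES3}
        if any(v < 0 for v in self.counts.values()):
            raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float]:
        if self.total == 0:
            raise ValidationError("cannot take proportions of an empty table")
        return {c: v / self.total for c, v in self.counts.items()}

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[c] for c in CATEGORIES3], dtype=float)


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float
    low_expected: bool  # any expected cell count < 5


def chi_squared_2x3(a: PenetranceTable, b: PenetranceTable) -> Chi2Result:
    """Pearson chi-squared on the 2x3 Y/M/psi contingency table.

    No continuity correction.  Columns empty in both groups are collapsed
    (reducing df accordingly); the result carries a flag when any expected
    count is below 5.
    """
    table = np.vstack([a.as_array(), b.as_array()])
    if table.sum() == 0 or a.total == 0 or b.total == 0:
        raise ValueError("both groups must contain at least one animal")
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("need at least two non-empty categories to compare")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    df = table.shape[1] - 1
    p = float(stats.chi2.sf(chi2, df))
    return Chi2Result(chi2, df, p, bool((expected < 5).any()))


def mendelian_test(genotype_counts: Mapping[str, int],
                   expected_ratio: Mapping[str, float]) -> Chi2Result:
    """Goodness-of-fit chi-squared of genotype counts against a Mendelian ratio."""
    missing = set(expected_ratio) - set(genotype_counts)
    if missing:
        raise ValueError(f"missing genotype counts for {sorted(missing)}")
    keys = sorted(expected_ratio)
    observed = np.array([genotype_counts[k] for k in keys], dtype=float)
    weights = np.array([expected_ratio[k] for k in keys], dtype=float)
    if observed.sum() == 0:
        raise ValueError("no animals to test")
    if np.any(weights <= 0):
        raise ValueError("expected-ratio weights must be positive")
    expected = observed.sum() * weights / weights.sum()
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = len(keys) - 1
    p = float(stats.chi2.sf(chi2, df))
    return Chi2Result(chi2, df, p, bool((expected < 5).any()))


@dataclass
class PenetranceReport:
    tables: dict[str, PenetranceTable]
    proportions: dict[str, dict[str, float]]
    comparisons: dict[tuple[str, str], Chi2Result]


def penetrance_report(records: Sequence[CoatColourRecord],
                      group_key: Callable[[CoatColourRecord], str],
                      comparisons: Sequence[tuple[str, str]] | None = None
                      ) -> PenetranceReport:
    """Tabulate pooled coat categories per group and compare groups pairwise.

    ``group_key`` maps each record to its group label (e.g. by offspring
    genotype or by sire genotype).  Records should already be restricted to
    Avy carriers; non-carriers show no yellow spectrum and are excluded from
    penetrance by design.  ``comparisons`` defaults to all pairs.
    """
    if not records:
        raise ValueError("no records to report on")
    grouped: dict[str, dict[str, int]] = {}
    for r in records:
        grouped.setdefault(group_key(r), {c: 0 for c in CATEGORIES3})
        grouped[group_key(r)][r.category3] += 1
    tables = {g: PenetranceTable(c) for g, c in grouped.items()}
    proportions = {g: t.proportions for g, t in tables.items()}
    if comparisons is None:
        labels = sorted(tables)
        comparisons = [(a, b) for i, a in enumerate(labels)
                       for b in labels[i + 1:]]
    results = {}
    for a, b in comparisons:
        if a not in tables or b not in tables:
            raise ValueError(f"comparison references unknown group ({a!r}, {b!r})")
        results[(a, b)] = chi_squared_2x3(tables[a], tables[b])
    return PenetranceReport(tables, proportions, results)


# ---------------------------------------------------------------------------
# Cohort TSV round-trip
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = ("animal_id", "cross_id", "sire_genotype", "dam_genotype",
                   "offspring_genotype", "avy_parent", "category5")


def write_cohort_tsv(records: Iterable[CoatColourRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COHORT_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join(getattr(r, c) for c in _COHORT_COLUMNS) + "\n")


def read_cohort_tsv(path: str | Path) -> list[CoatColourRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _COHORT_COLUMNS:
            raise ParseError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_COHORT_COLUMNS):
                raise ParseError(f"{path}: line {lineno}: expected "
                                 f"{len(_COHORT_COLUMNS)} fields")
            try:
                records.append(CoatColourRecord(*fields))
            except ValidationError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}")
    return records
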