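"""Input/output and normalisation of per-cytosine bisulphite count data.

Bisulphite sequencing reports, for every cytosine, how many reads carried a
methylated C and how many an unmethylated (converted) C.  A CpG dinucleotide
has one informative cytosine on each strand; downstream analysis works per
dinucleotide, so calls from the two strands are merged onto the plus-strand C.

Coordinate conventions
----------------------
* cytosine report: 1-based position of the cytosine itself;
* coverage file: 1-based start == end, one row per merged CpG;
* BED annotations: 0-based half-open intervals.

A merged CpG at 1-based plus-strand position ``p`` occupies the 0-based
coordinate ``p - 1`` for interval-membership purposes.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import ParseError, ValidationError

CPG = "CpG"
CONTEXTS = ("CpG", "CHG", "CHH")
STRANDS = ("+", "-")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine's methylated/unmethylated read counts on one strand."""

    chrom: str
    pos: int  # 1-based position of the cytosine
    strand: str
    meth_count: int
    unmeth_count: int
    context: str = CPG

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValidationError("read counts must be non-negative")
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")

    @property
    def is_cpg(self) -> bool:
        return self.context == CPG


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatElement:
    """A RepeatMasker-style repeat: an interval plus subfamily and class/family."""

    interval: GenomicInterval
    subfamily: str
    class_family: str

    def __post_init__(self) -> None:
        if not self.subfamily:
            raise ValidationError("subfamily must be non-empty")
        if not self.class_family:
            raise ValidationError("class_family must be non-empty")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class MethylomeSample:
    """Strand-merged per-CpG counts for one individual.

    Stores, per chromosome, three parallel arrays sorted by position: the
    1-based plus-strand C position, the methylated count and the unmethylated
    count.  Sorted storage makes interval queries O(log n).
    """

    def __init__(self, sample_id: str,
                 data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.sample_id = sample_id
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (pos, meth, unmeth) in data.items():
            pos = np.asarray(pos, dtype=np.int64)
            meth = np.asarray(meth, dtype=np.int64)
            unmeth = np.asarray(unmeth, dtype=np.int64)
            if not (len(pos) == len(meth) == len(unmeth)):
                raise ValidationError(f"ragged arrays for {chrom}")
            order = np.argsort(pos, kind="stable")
            pos, meth, unmeth = pos[order], meth[order], unmeth[order]
            if len(pos) > 1 and np.any(np.diff(pos) == 0):
                raise ValidationError(f"duplicate CpG position on {chrom}")
            if np.any(meth < 0) or np.any(unmeth < 0):
                raise ValidationError("negative counts")
            self._data[chrom] = (pos, meth, unmeth)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_sites(cls, sample_id: str,
                   sites: Mapping[tuple[str, int], tuple[int, int]]) -> "MethylomeSample":
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for (chrom, pos), (m, u) in sites.items():
            per_chrom.setdefault(chrom, []).append((pos, m, u))
        data = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            arr = np.array(rows, dtype=np.int64).reshape(-1, 3)
            data[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls(sample_id, data)

    # -- accessors ---------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p, _, _ in self._data.values())

    @property
    def total_count(self) -> int:
        return int(sum(int(m.sum()) + int(u.sum()) for _, m, u in self._data.values()))

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._data.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int64)),
        )

    def region_arrays(self, chrom: str, start: int, end: int
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """CpGs whose 0-based C coordinate (pos - 1) lies in [start, end)."""
        pos, meth, unmeth = self.arrays(chrom)
        lo = np.searchsorted(pos, start + 1, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return pos[lo:hi], meth[lo:hi], unmeth[lo:hi]

    def site(self, chrom: str, pos: int) -> tuple[int, int] | None:
        p, m, u = self.arrays(chrom)
        i = np.searchsorted(p, pos)
        if i < len(p) and p[i] == pos:
            return int(m[i]), int(u[i])
        return None

    def sites(self) -> Iterator[tuple[str, int, int, int]]:
        for chrom in sorted(self._data):
            pos, meth, unmeth = self._data[chrom]
            for p, m, u in zip(pos, meth, unmeth):
                yield chrom, int(p), int(m), int(u)

    def methylation_percent(self, chrom: str, pos: int) -> float:
        site = self.site(chrom, pos)
        if site is None or site[0] + site[1] == 0:
            raise ValidationError(f"no coverage at {chrom}:{pos}")
        m, u = site
        return 100.0 * m / (m + u)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylomeSample):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(
            all(np.array_equal(a, b) for a, b in zip(self._data[c], other._data[c]))
            for c in self._data
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_cytosine_report(path: str | Path) -> list[CytosineRecord]:
    """Read a per-cytosine report: chrom, pos, strand, meth, unmeth, context.

    Non-CpG-context lines are retained (flagged by ``record.is_cpg``) because
    they feed conversion-rate QC.  An empty file yields an empty list.
    """
    records: list[CytosineRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, strand, m_s, u_s, context = fields
            try:
                pos, m, u = int(pos_s), int(m_s), int(u_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer field ({exc})")
            try:
                records.append(CytosineRecord(chrom, pos, strand, m, u, context))
            except ValidationError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}")
    return records


def write_cytosine_report(records: Iterable[CytosineRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.meth_count}\t"
                     f"{r.unmeth_count}\t{r.context}\n")


def read_coverage_file(path: str | Path, sample_id: str = "sample") -> MethylomeSample:
    """Read the per-CpG coverage dialect: chrom, start(=pos), end, pct, meth, unmeth."""
    sites: dict[tuple[str, int], tuple[int, int]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 fields")
            chrom, start_s, _end, _pct, m_s, u_s = fields
            try:
                pos, m, u = int(start_s), int(m_s), int(u_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer field ({exc})")
            key = (chrom, pos)
            if key in sites:
                raise ValidationError(f"{path}: line {lineno}: duplicate site {key}")
            sites[key] = (m, u)
    return MethylomeSample.from_sites(sample_id, sites)


def write_coverage_file(sample: MethylomeSample, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, m, u in sample.sites():
            cov = m + u
            pct = 100.0 * m / cov if cov else 0.0
            fh.write(f"{chrom}\t{pos}\t{pos}\t{pct:.6g}\t{m}\t{u}\n")


def read_repeat_annotation(path: str | Path,
                           class_family: str | None = None) -> list[RepeatElement]:
    """Read a BED6+2 repeat annotation; optionally keep one class/family only."""
    elements: list[RepeatElement] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(f"{path}: line {lineno}: expected >= 7 fields")
            chrom, start_s, end_s, subfamily, _score, strand, cf = fields[:7]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate ({exc})")
            try:
                elem = RepeatElement(GenomicInterval(chrom, start, end, strand),
                                     subfamily, cf)
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}")
            if class_family is None or elem.class_family == class_family:
                elements.append(elem)
    return elements


def write_repeat_annotation(elements: Iterable[RepeatElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in elements:
            iv = e.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{e.subfamily}\t0\t"
                     f"{iv.strand}\t{e.class_family}\n")


def read_bed4(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED4 rows (chrom, start, end, name) — used for TSS and ICR inputs."""
    rows: list[tuple[str, int, int, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected >= 4 fields")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate ({exc})")
            if start >= end:
                raise ValidationError(f"{path}: line {lineno}: start >= end")
            rows.append((chrom, start, end, name))
    return rows


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read the standard two-column chrom.sizes table."""
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer length ({exc})")
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# Strand merging and library normalisation
# ---------------------------------------------------------------------------

def merge_strands(records: Sequence[CytosineRecord],
                  sample_id: str = "sample") -> MethylomeSample:
    """Merge the two strands of each CpG into a single dinucleotide call.

    The plus-strand C of a CpG sits at 1-based position p and the minus-strand
    C at p + 1; their counts are summed and reported at p.  Sites covered on
    one strand only pass through (a minus-strand-only call is still assigned
    to p = pos - 1).  Only CpG-context records are used.
    """
    seen: set[tuple[str, int, str]] = set()
    sites: dict[tuple[str, int], list[int]] = {}
    for r in records:
        if not r.is_cpg:
            continue
        key3 = (r.chrom, r.pos, r.strand)
        if key3 in seen:
            raise ValidationError(f"duplicate record for {key3}")
        seen.add(key3)
        p = r.pos if r.strand == "+" else r.pos - 1
        if p < 1:
            raise ValidationError(
                f"minus-strand CpG at {r.chrom}:{r.pos} maps to position 0"
            )
        acc = sites.setdefault((r.chrom, p), [0, 0])
        acc[0] += r.meth_count
        acc[1] += r.unmeth_count
    return MethylomeSample.from_sites(
        sample_id, {k: (m, u) for k, (m, u) in sites.items()}
    )


def thin_counts(sample: MethylomeSample, ratio: float, seed: int) -> MethylomeSample:
    """Binomially thin every count by ``ratio``; seeded and reproducible.

    Each methylated and unmethylated count is replaced by a Binomial(count,
    ratio) draw, which preserves the expected methylation fraction at every
    site while scaling the library to the target depth.
    """
    if not (0 < ratio <= 1):
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    if ratio == 1.0:
        return MethylomeSample(sample.sample_id,
                               {c: sample.arrays(c) for c in sample.chroms})
    rng = np.random.default_rng(seed)
    data = {}
    for chrom in sample.chroms:
        pos, meth, unmeth = sample.arrays(chrom)
        data[chrom] = (pos, rng.binomial(meth, ratio), rng.binomial(unmeth, ratio))
    return MethylomeSample(sample.sample_id, data)


def equalize_libraries(a: MethylomeSample, b: MethylomeSample, seed: int
                       ) -> tuple[MethylomeSample, MethylomeSample]:
    """Downsample the larger of two libraries so total counts match in expectation."""
    ta, tb = a.total_count, b.total_count
    if ta == 0 or tb == 0:
        raise ValidationError("cannot equalize a library with zero total count")
    if ta == tb:
        return a, b
    if ta > tb:
        return thin_counts(a, tb / ta, seed), b
    return a, thin_counts(b, ta / tb, seed)
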