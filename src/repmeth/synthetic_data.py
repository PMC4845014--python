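"""Synthetic inputs with known truth for the whole pipeline.

The generator emulates the structure of the real study inputs: a two-sample
sperm methylome at roughly 30-fold coverage where regional methylation is
high (beta-distributed around 90%), repeat elements grouped into labelled
subfamilies (ERVK-like IAPEY/RLTRETN/IAPLTR3/RNERVK23-int plus LINE1 and B1
control classes), a planted hypomethylation effect confined to a fraction of
ERVK-like elements, maternally/paternally methylated ICRs, multinomial
coat-colour cohorts and clone x CpG bisulphite matrices with imperfect
conversion.  Every output is paired with a truth table so recovery can be
scored exactly.

All randomness flows from one root seed through named sub-streams (genome,
methylome, cohort, clones, strand_split) so each component can be
regenerated independently and reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coat_colour import CATEGORIES3, CoatColourRecord, write_cohort_tsv
from .errors import ValidationError
from .methylation_io import (CytosineRecord, GenomicInterval, MethylomeSample,
                             RepeatElement, write_chrom_sizes,
                             write_cytosine_report, write_repeat_annotation)
from .sanger_bisulfite import CloneMatrix, write_clone_tsv


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of the root seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubfamilySpec:
    subfamily: str
    class_family: str
    element_length: int
    n_elements: int


@dataclass(frozen=True)
class PlantedEffect:
    subfamily: str
    fraction_of_elements: float
    delta_pp: float
    direction: str = "hypo"

    def __post_init__(self) -> None:
        if not (0 < self.fraction_of_elements <= 1):
            raise ValidationError("fraction_of_elements must be in (0, 1]")
        if not (0 <= self.delta_pp <= 100):
            raise ValidationError("delta_pp must be in [0, 100]")
        if self.direction not in ("hypo", "hyper"):
            raise ValidationError("direction must be hypo or hyper")


def _default_catalogue() -> tuple[SubfamilySpec, ...]:
    # 2,000 ERVK-like elements plus abundant control classes.  Lengths are
    # chosen so a typical element carries enough CpGs to pass the min_cpgs
    # filter, not to mimic true repeat length distributions.
    return (
        SubfamilySpec("IAPEY", "LTR/ERVK", 1200, 600),
        SubfamilySpec("RLTRETN", "LTR/ERVK", 1200, 600),
        SubfamilySpec("IAPLTR3", "LTR/ERVK", 1200, 500),
        SubfamilySpec("RNERVK23-int", "LTR/ERVK", 1200, 300),
        SubfamilySpec("LINE1", "LINE/L1", 1500, 400),
        SubfamilySpec("B1", "SINE/B1", 1000, 400),
    )


def _default_beta() -> dict[str, tuple[float, float]]:
    # Beta(27, 3): mean 0.9, sd ~0.054 — high sperm-like methylation.
    return {"LTR/ERVK": (27.0, 3.0), "LINE/L1": (27.0, 3.0),
            "SINE/B1": (27.0, 3.0), "background": (27.0, 3.0)}


@dataclass(frozen=True)
class CohortGroupSpec:
    label: str
    probabilities: dict[str, float]  # over Y / M / psi
    n: int
    sire_genotype: str = "wt"
    offspring_genotype: str = "wt"


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; defaults mirror the study conditions."""

    seed: int
    n_chroms: int = 2
    chrom_length: int = 3_000_000
    cpg_spacing_mean: int = 100
    subfamily_catalogue: tuple[SubfamilySpec, ...] = field(
        default_factory=_default_catalogue)
    baseline_meth: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_beta)
    coverage_mean: float = 30.0
    coverage_dispersion: float = 10.0  # NB size parameter; var = m + m^2/size
    coverage_imbalance: float = 1.0  # multiplier on mutant coverage mean
    planted_effects: tuple[PlantedEffect, ...] = (
        PlantedEffect("IAPEY", 1 / 6, 25.0, "hypo"),)
    tss_count: int = 200
    icr_count: int = 20
    icr_length: int = 2000
    maternal_icr_meth: float = 0.03
    paternal_icr_meth: float = 0.90
    cohort_groups: tuple[CohortGroupSpec, ...] = (
        CohortGroupSpec("control_cross",
                        {"Y": 0.29, "M": 0.56, "psi": 0.15}, 150, "wt", "wt"),
        CohortGroupSpec("het_sire_wt_offspring",
                        {"Y": 0.47, "M": 0.418, "psi": 0.112}, 150, "het", "wt"),
    )
    clone_individuals_per_group: int = 3
    clone_clones: int = 10
    clone_cpgs: int = 20
    clone_p_meth: Mapping[str, float] = field(
        default_factory=lambda: {"wt": 0.59, "mut": 0.26})
    clone_conversion_eff: float = 0.99

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < 1 or self.cpg_spacing_mean < 1:
            raise ValidationError("genome dimensions must be positive")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValidationError("coverage parameters must be positive")


@dataclass
class Genome:
    chrom_sizes: dict[str, int]
    cpg_positions: dict[str, np.ndarray]  # 1-based plus-strand C positions
    repeats: list[RepeatElement]
    tss: list[tuple[str, int]]
    icrs: list[tuple[GenomicInterval, str]]  # label: maternal / paternal


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def build_genome(cfg: SimulationConfig) -> Genome:
    """Lay out chromosomes, CpG positions, non-overlapping repeats, TSSs, ICRs."""
    rng = substream(cfg.seed, "genome")
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    chroms = list(chrom_sizes)

    # CpG positions: geometric gaps with the configured mean spacing.
    cpg_positions = {}
    for chrom, length in chrom_sizes.items():
        n_est = int(2 * length / cfg.cpg_spacing_mean) + 10
        gaps = rng.geometric(1.0 / cfg.cpg_spacing_mean, size=n_est)
        pos = np.cumsum(gaps)
        while pos[-1] < length - 1:  # pragma: no cover - generous oversampling
            extra = rng.geometric(1.0 / cfg.cpg_spacing_mean, size=n_est)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        cpg_positions[chrom] = pos[pos <= length - 1].astype(np.int64)

    # Items to place without overlap: repeats and ICRs.
    items: list[tuple[str, object, int]] = []
    for spec in cfg.subfamily_catalogue:
        for _ in range(spec.n_elements):
            items.append(("repeat", spec, spec.element_length))
    n_mat = cfg.icr_count // 2
    for i in range(cfg.icr_count):
        label = "maternal" if i < n_mat else "paternal"
        items.append(("icr", label, cfg.icr_length))
    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    per_chrom: dict[str, list[tuple[str, object, int]]] = {c: [] for c in chroms}
    for i, item in enumerate(items):
        per_chrom[chroms[i % len(chroms)]].append(item)

    repeats: list[RepeatElement] = []
    icrs: list[tuple[GenomicInterval, str]] = []
    for chrom, chrom_items in per_chrom.items():
        total = sum(length for _, _, length in chrom_items)
        free = chrom_sizes[chrom] - total
        if free < 0:
            raise ValidationError(
                f"{chrom} too short ({chrom_sizes[chrom]} bp) for "
                f"{total} bp of requested elements")
        cuts = np.sort(rng.integers(0, free + 1, size=len(chrom_items)))
        offset = 0
        for (kind, payload, length), cut in zip(chrom_items, cuts):
            start = int(cut + offset)
            iv = GenomicInterval(chrom, start, start + length,
                                 "+" if rng.random() < 0.5 else "-")
            if kind == "repeat":
                spec: SubfamilySpec = payload  # type: ignore[assignment]
                repeats.append(RepeatElement(iv, spec.subfamily, spec.class_family))
            else:
                icrs.append((GenomicInterval(chrom, start, start + length),
                             str(payload)))
            offset += length

    tss = []
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    picks = rng.choice(len(chroms), size=cfg.tss_count, p=sizes / sizes.sum())
    for i in picks:
        tss.append((chroms[i], int(rng.integers(0, chrom_sizes[chroms[i]]))))
    return Genome(chrom_sizes, cpg_positions, repeats, tss, icrs)


# ---------------------------------------------------------------------------
# Methylome simulation
# ---------------------------------------------------------------------------

def _nb_coverage(rng: np.random.Generator, mean: float, size_param: float,
                 n: int) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def simulate_methylomes(genome: Genome, cfg: SimulationConfig
                        ) -> tuple[MethylomeSample, MethylomeSample, pd.DataFrame]:
    """Draw two beta-binomial methylomes with planted subfamily effects.

    Each element gets one true methylation level from its class beta,
    shared between the samples unless the element carries a planted effect,
    in which case the mutant level is shifted by delta_pp (clamped to
    [0, 1]).  Background CpGs draw one level each from the genome-wide beta;
    ICR CpGs are overridden with the maternal/paternal sperm pattern.
    Coverage is negative-binomial per CpG per sample; methylated counts are
    binomial at the true level.  Returns (wt, mut, truth table).
    """
    rng = substream(cfg.seed, "methylome")
    bg_a, bg_b = cfg.baseline_meth.get("background", (27.0, 3.0))

    # Plant effects: choose elements per subfamily without replacement.
    by_subfamily: dict[str, list[int]] = {}
    for i, elem in enumerate(genome.repeats):
        by_subfamily.setdefault(elem.subfamily, []).append(i)
    planted: dict[int, PlantedEffect] = {}
    for effect in cfg.planted_effects:
        members = by_subfamily.get(effect.subfamily, [])
        n_pick = int(round(effect.fraction_of_elements * len(members)))
        for i in rng.choice(len(members), size=n_pick, replace=False):
            planted[members[int(i)]] = effect

    # Per-element true levels.
    truth_rows = []
    elem_levels: list[tuple[int, float, float]] = []  # index, wt, mut
    for i, elem in enumerate(genome.repeats):
        a, b = cfg.baseline_meth.get(elem.class_family, (bg_a, bg_b))
        level_wt = float(rng.beta(a, b))
        effect = planted.get(i)
        if effect is None:
            level_mut = level_wt
        elif effect.direction == "hypo":
            level_mut = max(0.0, level_wt - effect.delta_pp / 100.0)
        else:
            level_mut = min(1.0, level_wt + effect.delta_pp / 100.0)
        elem_levels.append((i, level_wt, level_mut))
        iv = elem.interval
        truth_rows.append({
            "element_id": f"{iv.chrom}:{iv.start}-{iv.end}:{elem.subfamily}",
            "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "subfamily": elem.subfamily, "class_family": elem.class_family,
            "true_meth_wt": 100.0 * level_wt, "true_meth_mut": 100.0 * level_mut,
            "planted": effect is not None,
        })
    truth = pd.DataFrame(truth_rows)

    data_wt: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    data_mut: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, pos in genome.cpg_positions.items():
        n = len(pos)
        level_wt = rng.beta(bg_a, bg_b, size=n)
        level_mut = level_wt.copy()
        coord = pos - 1  # 0-based coordinate of the plus-strand C
        for i, lw, lm in elem_levels:
            iv = genome.repeats[i].interval
            if iv.chrom != chrom:
                continue
            lo = np.searchsorted(coord, iv.start)
            hi = np.searchsorted(coord, iv.end)
            level_wt[lo:hi] = lw
            level_mut[lo:hi] = lm
        for iv, label in genome.icrs:
            if iv.chrom != chrom:
                continue
            lo = np.searchsorted(coord, iv.start)
            hi = np.searchsorted(coord, iv.end)
            level = (cfg.maternal_icr_meth if label == "maternal"
                     else cfg.paternal_icr_meth)
            level_wt[lo:hi] = level
            level_mut[lo:hi] = level
        cov_wt = _nb_coverage(rng, cfg.coverage_mean, cfg.coverage_dispersion, n)
        cov_mut = _nb_coverage(rng, cfg.coverage_mean * cfg.coverage_imbalance,
                               cfg.coverage_dispersion, n)
        m_wt = rng.binomial(cov_wt, level_wt)
        m_mut = rng.binomial(cov_mut, level_mut)
        data_wt[chrom] = (pos, m_wt, cov_wt - m_wt)
        data_mut[chrom] = (pos, m_mut, cov_mut - m_mut)
    return (MethylomeSample("wt", data_wt), MethylomeSample("mut", data_mut),
            truth)


# ---------------------------------------------------------------------------
# Cohorts and clone matrices
# ---------------------------------------------------------------------------

_CAT5_BY_POOL = {"Y": ("yellow", "yellow_mottled"),
                 "M": ("mottled",),
                 "psi": ("pseudoagouti_mottled", "pseudoagouti")}


def simulate_cohort(probabilities: Mapping[str, float], n: int, seed: int,
                    cross_id: str = "cross", sire_genotype: str = "wt",
                    dam_genotype: str = "wt", offspring_genotype: str = "wt",
                    avy_parent: str = "dam") -> list[CoatColourRecord]:
    """Multinomial coat-colour cohort over the pooled Y/M/psi categories."""
    if n <= 0:
        raise ValueError("n must be positive")
    p = np.array([probabilities.get(c, 0.0) for c in CATEGORIES3], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
    rng = substream(seed, "cohort")
    pooled = rng.choice(len(CATEGORIES3), size=n, p=p)
    records = []
    for i, k in enumerate(pooled):
        options = _CAT5_BY_POOL[CATEGORIES3[int(k)]]
        cat5 = options[int(rng.integers(len(options)))]
        records.append(CoatColourRecord(
            animal_id=f"{cross_id}_{i + 1}", cross_id=cross_id,
            sire_genotype=sire_genotype, dam_genotype=dam_genotype,
            offspring_genotype=offspring_genotype, avy_parent=avy_parent,
            category5=cat5))
    return records


def simulate_clones(n_individuals_per_group: int, n_clones: int, n_cpgs: int,
                    p_meth: Mapping[str, float], conversion_eff: float,
                    seed: int, amplicon_id: str = "amplicon1",
                    non_cpg_c_per_individual: int = 150,
                    missing_rate: float = 0.0) -> list[CloneMatrix]:
    """Bernoulli clone x CpG matrices per genotype plus conversion-QC counts."""
    for genotype, frac in p_meth.items():
        if not (0 <= frac <= 1):
            raise ValueError(f"p_meth[{genotype!r}] must be in [0, 1]")
    if not (0 <= conversion_eff <= 1):
        raise ValueError("conversion_eff must be in [0, 1]")
    rng = substream(seed, "clones")
    matrices = []
    for genotype in ("wt", "mut"):
        for i in range(n_individuals_per_group):
            calls = rng.binomial(1, p_meth[genotype],
                                 size=(n_clones, n_cpgs)).astype(float)
            if missing_rate > 0:
                calls[rng.random(calls.shape) < missing_rate] = np.nan
            converted = int(rng.binomial(non_cpg_c_per_individual, conversion_eff))
            matrices.append(CloneMatrix(
                amplicon_id, f"{genotype}{i + 1}", genotype, calls,
                non_cpg_c_per_individual, converted))
    return matrices


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------

def _split_strands(sample: MethylomeSample, rng: np.random.Generator
                   ) -> list[CytosineRecord]:
    """Split each merged CpG's counts over the two strands (sums preserved)."""
    records = []
    for chrom, pos, m, u in sample.sites():
        m_plus = int(rng.binomial(m, 0.5))
        u_plus = int(rng.binomial(u, 0.5))
        records.append(CytosineRecord(chrom, pos, "+", m_plus, u_plus, "CpG"))
        m_minus, u_minus = m - m_plus, u - u_plus
        if m_minus or u_minus:
            records.append(CytosineRecord(chrom, pos + 1, "-", m_minus,
                                          u_minus, "CpG"))
    return records


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(cfg: SimulationConfig, directory: str | Path) -> dict[str, str]:
    """Generate and write a complete input fixture; returns the manifest.

    Emits per-sample cytosine reports (counts split over the two strands so
    strand merging is exercised), repeat/TSS/ICR annotations, chrom.sizes,
    the truth table, a coat-colour cohort, clone matrices and a JSON
    manifest with sha256 checksums.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    genome = build_genome(cfg)
    wt, mut, truth = simulate_methylomes(genome, cfg)
    split_rng = substream(cfg.seed, "strand_split")

    files: dict[str, Path] = {}

    for name, sample in (("wt", wt), ("mut", mut)):
        path = directory / f"{name}.cytosine_report.tsv"
        write_cytosine_report(_split_strands(sample, split_rng), path)
        files[path.name] = path

    path = directory / "repeats.bed"
    write_repeat_annotation(genome.repeats, path)
    files[path.name] = path

    path = directory / "tss.bed"
    with open(path, "w") as fh:
        for i, (chrom, pos) in enumerate(genome.tss):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\ttss{i + 1}\n")
    files[path.name] = path

    path = directory / "icrs.bed"
    with open(path, "w") as fh:
        for iv, label in genome.icrs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")
    files[path.name] = path

    path = directory / "chrom.sizes"
    write_chrom_sizes(genome.chrom_sizes, path)
    files[path.name] = path

    path = directory / "truth.tsv"
    truth.to_csv(path, sep="\t", index=False)
    files[path.name] = path

    cohort = []
    for group in cfg.cohort_groups:
        cohort.extend(simulate_cohort(
            group.probabilities, group.n,
            seed=cfg.seed + zlib.crc32(group.label.encode()) % 100_000,
            cross_id=group.label, sire_genotype=group.sire_genotype,
            offspring_genotype=group.offspring_genotype))
    path = directory / "cohort.tsv"
    write_cohort_tsv(cohort, path)
    files[path.name] = path

    clones = simulate_clones(
        cfg.clone_individuals_per_group, cfg.clone_clones, cfg.clone_cpgs,
        cfg.clone_p_meth, cfg.clone_conversion_eff, seed=cfg.seed)
    clone_path = directory / "clones.tsv"
    conv_path = directory / "clones.conversion.tsv"
    write_clone_tsv(clones, clone_path, conv_path)
    files[clone_path.name] = clone_path
    files[conv_path.name] = conv_path

    manifest = {name: _sha256(p) for name, p in sorted(files.items())}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
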