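"""Synthetic sequencing cohorts with the statistical structure the
analysis assumes.

TERRA-derived reads are pure telomeric repeat tracts: concatenations of the
canonical DNA unit ``TTAGGG`` interspersed with variant repeat units drawn
by per-unit probabilities, started at a random phase within the unit,
truncated to the read length, subjected to per-base substitution error, and
emitted on either strand (each read reverse-complemented with probability
``strand_flip_prob``). Background reads are i.i.d. bases at a configurable
GC fraction. Each sample draws each read as TERRA-derived with its
category's ``terra_fraction``, so the TERRA read fraction can be elevated
in one exposure category relative to the others.

Defaults encode the package's reference study conditions: 6 ground vs 6
space_effect samples, 20,000 reads of length 100 per sample, TERRA read
fractions 0.005 vs 0.015, variant units TGAGGG (5%) and TCAGGG (3%),
substitution error 0.005. A single root seed spawns one child seed per
sample, so cohorts are reproducible and samples independent.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .errors import TerraMotifError
from .io import SampleRecord, SequenceRead, write_fastq

__all__ = [
    "VariantModel",
    "CategoryConfig",
    "SyntheticConfig",
    "generate_terra_read",
    "generate_background_read",
    "iter_cohort_samples",
    "generate_cohort",
]

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class VariantModel:
    """Repeat-unit substitution model for TERRA read synthesis.

    Each emitted unit is the canonical unit with probability
    1 - sum(variants.values()), otherwise a variant unit drawn by its
    probability. Variant units may have length 5-7 (a non-6 unit length
    deliberately exercises the cross-k counting behavior).
    """

    canonical_unit: str = "TTAGGG"
    variants: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        total = 0.0
        for unit, p in self.variants.items():
            if not (5 <= len(unit) <= 7) or set(unit) - set(_BASES):
                raise TerraMotifError(f"invalid variant unit {unit!r}")
            if p < 0:
                raise TerraMotifError(f"negative probability for variant {unit!r}")
            total += p
        if total > 1.0 + 1e-12:
            raise TerraMotifError(f"variant probabilities sum to {total} > 1")
        if set(self.canonical_unit) - set(_BASES):
            raise TerraMotifError(f"invalid canonical unit {self.canonical_unit!r}")

    def unit_pool(self) -> tuple[list[str], np.ndarray]:
        units = [self.canonical_unit] + list(self.variants)
        probs = np.array(
            [1.0 - sum(self.variants.values())] + list(self.variants.values())
        )
        return units, np.cumsum(probs)


@dataclass(frozen=True)
class CategoryConfig:
    n_samples: int
    terra_fraction: float

    def __post_init__(self):
        if self.n_samples < 1:
            raise TerraMotifError("n_samples must be >= 1")
        if not 0.0 <= self.terra_fraction <= 1.0:
            raise TerraMotifError("terra_fraction must lie in [0, 1]")


def _default_categories() -> dict[str, CategoryConfig]:
    return {
        "ground": CategoryConfig(n_samples=6, terra_fraction=0.005),
        "space_effect": CategoryConfig(n_samples=6, terra_fraction=0.015),
    }


def _default_variants() -> VariantModel:
    return VariantModel(variants={"TGAGGG": 0.05, "TCAGGG": 0.03})


@dataclass
class SyntheticConfig:
    """Full parameterization of a simulated cohort."""

    categories: dict[str, CategoryConfig] = field(default_factory=_default_categories)
    reads_per_sample: int = 20_000
    read_length: int = 100
    variant_model: VariantModel = field(default_factory=_default_variants)
    error_rate: float = 0.005
    background_gc: float = 0.5
    strand_flip_prob: float = 0.5
    seed: int = 0
    gzip_output: bool = True

    def __post_init__(self):
        if self.read_length < 7:
            raise TerraMotifError("read_length must be >= 7")
        for p, name in [
            (self.error_rate, "error_rate"),
            (self.background_gc, "background_gc"),
            (self.strand_flip_prob, "strand_flip_prob"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise TerraMotifError(f"{name} must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return sum(c.n_samples for c in self.categories.values())

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        cats = {
            label: CategoryConfig(**spec) for label, spec in d.pop("categories").items()
        }
        vm = d.pop("variant_model", None)
        model = VariantModel(**vm) if vm else VariantModel()
        return cls(categories=cats, variant_model=model, **d)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "categories": {
                label: {"n_samples": c.n_samples, "terra_fraction": c.terra_fraction}
                for label, c in self.categories.items()
            },
            "reads_per_sample": self.reads_per_sample,
            "read_length": self.read_length,
            "variant_model": {
                "canonical_unit": self.variant_model.canonical_unit,
                "variants": dict(self.variant_model.variants),
            },
            "error_rate": self.error_rate,
            "background_gc": self.background_gc,
            "strand_flip_prob": self.strand_flip_prob,
            "seed": self.seed,
            "gzip_output": self.gzip_output,
        }


# ---------------------------------------------------------------------------
# read-level generators


def _apply_substitutions(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in _BASES if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def generate_terra_read(
    length: int,
    variant_model: VariantModel,
    error_rate: float,
    strand_flip_prob: float,
    rng: np.random.Generator,
    read_id: str = "terra",
    phase: int | None = None,
) -> tuple[SequenceRead, dict]:
    """One TERRA-derived read plus its truth labels.

    The read is a concatenation of repeat units (canonical or variant,
    drawn per unit), started at phase offset ``phase`` within the first
    unit (uniform random when None), truncated to ``length``, then mutated
    at ``error_rate`` per base and reverse-complemented with probability
    ``strand_flip_prob``. Truth records the unit sequence used, the phase
    and the emitted strand.
    """
    units_pool, cum = variant_model.unit_pool()
    if length < max(len(u) for u in units_pool):
        raise TerraMotifError("read length shorter than the longest repeat unit")
    if phase is None:
        phase = int(rng.integers(0, len(variant_model.canonical_unit)))
    parts: list[str] = []
    used: list[str] = []
    total = 0
    needed = length + phase
    while total < needed:
        u = units_pool[int(np.searchsorted(cum, rng.random(), side="right"))]
        parts.append(u)
        used.append(u)
        total += len(u)
    seq = "".join(parts)[phase : phase + length]
    seq = _apply_substitutions(seq, error_rate, rng)
    strand = "+"
    if rng.random() < strand_flip_prob:
        seq = seq.translate(_COMPLEMENT)[::-1]
        strand = "-"
    truth = {"units": used, "phase": phase, "strand": strand}
    return SequenceRead(read_id, seq), truth


def _background_bases(n_bases: int, gc_fraction: float, rng: np.random.Generator) -> np.ndarray:
    if abs(gc_fraction - 0.5) < 1e-12:
        return rng.integers(0, 4, size=n_bases, dtype=np.int64)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    cum = np.cumsum([at, gc, gc, at])  # A C G T
    return np.searchsorted(cum, rng.random(n_bases), side="right")


def _background_block(
    n_reads: int, length: int, gc_fraction: float, rng: np.random.Generator
) -> list[str]:
    if n_reads == 0:
        return []
    idx = _background_bases(n_reads * length, gc_fraction, rng)
    buf = _BASE_BYTES[idx].tobytes()
    return [buf[i * length : (i + 1) * length].decode("ascii") for i in range(n_reads)]


def generate_background_read(
    length: int,
    gc_fraction: float,
    rng: np.random.Generator,
    forbid_motif: bool = False,
    read_id: str = "bg",
    max_retries: int = 1000,
) -> SequenceRead:
    """One background read of i.i.d. bases with P(G)=P(C)=gc/2.

    With ``forbid_motif`` reads containing TTAGGG or CCCTAA are rejected
    and resampled (bounded retries), guaranteeing a motif-free read.
    """
    if length < 1:
        raise TerraMotifError("length must be >= 1")
    for _ in range(max_retries):
        seq = _background_block(1, length, gc_fraction, rng)[0]
        if not forbid_motif or ("TTAGGG" not in seq and "CCCTAA" not in seq):
            return SequenceRead(read_id, seq)
    raise TerraMotifError(
        f"could not draw a motif-free background read of length {length} "
        f"in {max_retries} tries; parameters look infeasible"
    )


# ---------------------------------------------------------------------------
# cohort-level generation


def _sample_reads(
    sample_id: str, terra_fraction: float, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[SequenceRead], int]:
    """All reads of one sample (file order) and its true TERRA read count."""
    n = config.reads_per_sample
    is_terra = rng.random(n) < terra_fraction
    n_terra = int(is_terra.sum())
    terra_reads = [
        generate_terra_read(
            config.read_length,
            config.variant_model,
            config.error_rate,
            config.strand_flip_prob,
            rng,
        )[0].sequence
        for _ in range(n_terra)
    ]
    background = _background_block(
        n - n_terra, config.read_length, config.background_gc, rng
    )
    reads: list[SequenceRead] = []
    it_t, it_b = iter(terra_reads), iter(background)
    for i in range(n):
        seq = next(it_t) if is_terra[i] else next(it_b)
        reads.append(SequenceRead(f"{sample_id}_read{i:06d}", seq))
    return reads, n_terra


def iter_cohort_samples(
    config: SyntheticConfig,
) -> Iterator[tuple[SampleRecord, list[SequenceRead], int]]:
    """Generate the cohort sample by sample, in memory.

    Yields ``(record, reads, n_terra_reads)`` with a placeholder
    ``reads_path``; :func:`generate_cohort` materializes the same reads to
    FASTQ files. One child seed per sample index keeps samples independent
    and the whole cohort reproducible from ``config.seed``.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_samples)
    index = 0
    for category, cat_cfg in config.categories.items():
        for j in range(cat_cfg.n_samples):
            sample_id = f"{category}_{j + 1:02d}"
            rng = np.random.default_rng(children[index])
            reads, n_terra = _sample_reads(sample_id, cat_cfg.terra_fraction, config, rng)
            record = SampleRecord(
                sample_id=sample_id,
                subject_id=f"S{index + 1:02d}",
                timepoint=f"T{j + 1}",
                category=category,
                reads_path=Path(f"{sample_id}.fastq"),
            )
            yield record, reads, n_terra
            index += 1


def generate_cohort(config: SyntheticConfig, out_dir) -> tuple[Path, Path]:
    """Write a full synthetic cohort: one FASTQ per sample, a manifest
    consumable by :func:`terramotif.io.load_manifest`, and a truth table
    with per-sample TERRA read counts and the generating parameters.

    Returns ``(manifest_path, truth_path)``. Outputs are byte-reproducible
    from ``config.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if config.gzip_output else ".fastq"
    manifest_rows = []
    truth_rows = []
    for record, reads, n_terra in iter_cohort_samples(config):
        fname = record.sample_id + suffix
        write_fastq(reads, out_dir / fname)
        manifest_rows.append(
            (record.sample_id, record.subject_id, record.timepoint, record.category, fname)
        )
        truth_rows.append(
            (
                record.sample_id,
                record.category,
                config.categories[record.category].terra_fraction,
                len(reads),
                n_terra,
            )
        )
    manifest_path = out_dir / "manifest.tsv"
    pd.DataFrame(
        manifest_rows,
        columns=["sample_id", "subject_id", "timepoint", "category", "reads_path"],
    ).to_csv(manifest_path, sep="\t", index=False)
    truth_path = out_dir / "truth.tsv"
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "category", "terra_fraction", "n_reads", "n_terra_reads"],
    )
    truth["seed"] = config.seed
    truth["error_rate"] = config.error_rate
    truth["read_length"] = config.read_length
    truth.to_csv(truth_path, sep="\t", index=False)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return manifest_path, truth_path
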