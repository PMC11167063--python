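"""End-to-end orchestration: count -> normalize -> correlate -> select ->
test -> report over a cohort manifest.

Per sample the pipeline computes baseline counts of all raw k-mers (QC and
optional normalization denominator), filters reads for the canonical
motif on either strand, orients retained reads to the G-rich strand and
counts rotation classes. Across samples it assembles the normalized
abundance matrix, ranks motifs by correlation to the canonical motif,
selects the top set, runs grouped Mann-Whitney comparisons with one pooled
Benjamini-Hochberg family, and z-scores the selected motifs for reporting.

All numeric output is serialized with fixed formatting (scientific
notation, 6 significant digits) so repeated runs on identical inputs are
byte-identical.
"""
from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .abundance import (
    MotifAbundanceMatrix,
    MotifCorrelation,
    build_abundance_matrix,
    correlate_to_canonical,
    select_top_motifs,
    zscore_rows,
)
from .errors import StageError, TerraMotifError
from .io import DEFAULT_CATEGORY_LABELS, SampleRecord, load_manifest, read_sequences
from .kmers import (
    CANONICAL_MOTIF_DNA,
    DEFAULT_KS,
    KmerClass,
    KmerCountTable,
    canonical_rotation,
    count_kmer_classes,
    filter_terra_reads,
    orient_to_g_strand,
)
from .simulate import SyntheticConfig, iter_cohort_samples
from .stats import ComparisonResult, GroupDesign, results_frame, run_comparisons, triangular_q_frame

__all__ = [
    "RunConfig",
    "RunOutputs",
    "AnalysisResult",
    "count_sample",
    "analyze_tables",
    "analyze_synthetic_cohort",
    "run_pipeline",
]

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6e"


@dataclass
class RunConfig:
    """Run-level configuration mirroring the study's analysis choices
    (k in {5,6,7}, motif TTAGGG, top 10 motifs, pooled BH) with every
    gap decision exposed as an explicit key."""

    manifest: Path
    out_dir: Path
    categories: Sequence[str] = DEFAULT_CATEGORY_LABELS
    design_mode: str = "two_category"
    focal: str = "space_effect"
    background: Sequence[str] = ("ground", "recovery")
    group_by: str = "timepoint"  # pairwise_groups mode only
    ks: Sequence[int] = DEFAULT_KS
    motif: str = CANONICAL_MOTIF_DNA
    canonicalize: bool = True
    collapse_strands: bool = False
    min_occurrences: int = 1
    denominator: str = "filtered"
    top_n: int = 10
    alternative: str = "two-sided"
    test_method: str = "auto"
    heatmap: bool = False
    seed: int = 0

    def __post_init__(self):
        self.manifest = Path(self.manifest)
        self.out_dir = Path(self.out_dir)
        if self.design_mode not in ("two_category", "pairwise_groups"):
            raise TerraMotifError(f"unknown design mode {self.design_mode!r}")
        if self.design_mode == "two_category":
            labels = set(self.categories)
            wanted = {self.focal, *self.background}
            if not wanted <= labels:
                raise TerraMotifError(
                    f"focal/background labels {sorted(wanted)} must be drawn from "
                    f"the category set {sorted(labels)}"
                )

    def to_dict(self) -> dict:
        d = {
            "manifest": str(self.manifest),
            "out_dir": str(self.out_dir),
            "categories": list(self.categories),
            "design_mode": self.design_mode,
            "focal": self.focal,
            "background": list(self.background),
            "group_by": self.group_by,
            "ks": list(self.ks),
            "motif": self.motif,
            "canonicalize": self.canonicalize,
            "collapse_strands": self.collapse_strands,
            "min_occurrences": self.min_occurrences,
            "denominator": self.denominator,
            "top_n": self.top_n,
            "alternative": self.alternative,
            "test_method": self.test_method,
            "heatmap": self.heatmap,
            "seed": self.seed,
        }
        return d


@dataclass
class RunOutputs:
    """Paths of everything a run writes."""

    counts_dir: Path
    abundance_matrix: Path
    correlations: Path
    selected_motifs: Path
    comparisons: Path
    zscores: Path
    triangular: list[Path]
    run_log: Path
    run_summary: Path
    heatmap: Path | None = None

    def all_paths(self) -> list[Path]:
        paths = [
            self.abundance_matrix, self.correlations, self.selected_motifs,
            self.comparisons, self.zscores, self.run_log, self.run_summary,
        ]
        paths.extend(self.triangular)
        if self.heatmap:
            paths.append(self.heatmap)
        return paths


@dataclass
class AnalysisResult:
    """In-memory results of the cross-sample analysis stages."""

    matrix: MotifAbundanceMatrix
    correlations: list[MotifCorrelation]
    selected: list[KmerClass]
    comparisons: list[ComparisonResult]
    zscores: pd.DataFrame


@contextmanager
def _stage(name: str):
    try:
        yield
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, str(exc)) from exc


def count_sample(
    record: SampleRecord, config: RunConfig
) -> tuple[KmerCountTable, KmerCountTable]:
    """Baseline and filtered count tables for one sample's read file."""
    reads = list(read_sequences(record.reads_path))
    return _count_reads(reads, record.sample_id, config)


def _count_reads(reads, sample_id: str, config: RunConfig, baseline: bool = True):
    baseline_table = None
    if baseline:
        baseline_table = count_kmer_classes(
            reads, ks=config.ks, canonicalize=False, sample_id=sample_id, scope="baseline"
        )
        baseline_table.n_reads_scanned = len(reads)
    retained = [
        orient_to_g_strand(r, config.motif)
        for r in filter_terra_reads(reads, config.motif, config.min_occurrences)
    ]
    filtered_table = count_kmer_classes(
        retained,
        ks=config.ks,
        canonicalize=config.canonicalize,
        collapse_strands=config.collapse_strands,
        sample_id=sample_id,
        scope="filtered",
    )
    filtered_table.n_reads_scanned = len(reads)
    filtered_table.n_reads_retained = len(retained)
    return baseline_table, filtered_table


def _canonical_class(config: RunConfig) -> KmerClass:
    if config.canonicalize:
        return KmerClass(canonical_rotation(config.motif, config.collapse_strands))
    return KmerClass(config.motif)


def analyze_tables(
    filtered_tables: Sequence[KmerCountTable],
    samples: Sequence[SampleRecord],
    config: RunConfig,
    baseline_tables: dict[str, KmerCountTable] | None = None,
) -> AnalysisResult:
    """Cross-sample stages: matrix, correlation, selection, tests, z-scores."""
    order = [s.sample_id for s in samples]
    with _stage("normalize"):
        matrix = build_abundance_matrix(
            filtered_tables,
            denominator=config.denominator,
            baseline_tables=baseline_tables,
            sample_order=order,
        )
    canonical = _canonical_class(config)
    with _stage("correlate"):
        correlations = correlate_to_canonical(matrix, canonical)
    with _stage("select"):
        selected = select_top_motifs(correlations, n=config.top_n, canonical=canonical)
    with _stage("test"):
        if config.design_mode == "two_category":
            design = GroupDesign.two_category(
                samples, focal=config.focal, background=config.background
            )
        else:
            design = GroupDesign.pairwise_groups(samples, by=config.group_by)
        comparisons = run_comparisons(
            matrix, design, selected,
            alternative=config.alternative, method=config.test_method,
        )
    with _stage("zscore"):
        zscores = zscore_rows(matrix, selected)
    return AnalysisResult(matrix, correlations, selected, comparisons, zscores)


def write_outputs(
    result: AnalysisResult,
    samples: Sequence[SampleRecord],
    config: RunConfig,
    counts_dir: Path,
) -> RunOutputs:
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    matrix_path = out / "abundance_matrix.tsv"
    result.matrix.to_frame().to_csv(matrix_path, sep="\t", float_format=FLOAT_FORMAT)
    corr_path = out / "correlations.tsv"
    selected_set = set(result.selected)
    pd.DataFrame(
        [
            (c.motif.display, c.motif.k, c.r, int(c.motif in selected_set))
            for c in sorted(
                result.correlations,
                key=lambda c: (-(c.r if c.defined else -2.0), c.motif.canonical),
            )
        ],
        columns=["motif_rna", "k", "r", "selected"],
    ).to_csv(corr_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    selected_path = out / "selected_motifs.tsv"
    pd.DataFrame(
        [(m.display, m.canonical, m.k) for m in result.selected],
        columns=["motif_rna", "motif_dna", "k"],
    ).to_csv(selected_path, sep="\t", index=False)
    comparisons_path = out / "comparisons.tsv"
    results_frame(result.comparisons).to_csv(
        comparisons_path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    zscores_path = out / "zscores.tsv"
    zdf = result.zscores.copy()
    zdf.index = pd.Index([m.replace("T", "U") for m in zdf.index], name="motif_rna")
    zdf.to_csv(zscores_path, sep="\t", float_format=FLOAT_FORMAT)
    triangular: list[Path] = []
    if config.design_mode == "pairwise_groups":
        for motif in result.selected:
            tri = triangular_q_frame(result.comparisons, motif)
            tri_path = out / f"pairwise_q_{motif.display}.tsv"
            tri.to_csv(tri_path, sep="\t", float_format=FLOAT_FORMAT)
            triangular.append(tri_path)
    heatmap_path = None
    if config.heatmap:
        from .plotting import plot_zscore_heatmap

        groups = {s.sample_id: s.category for s in samples}
        heatmap_path = plot_zscore_heatmap(result.zscores, out / "zscore_heatmap.png", groups)
    summary_path = out / "run_summary.yaml"
    import numpy, scipy  # noqa: PLC0415 - version echo only

    summary = {
        "config": config.to_dict(),
        "versions": {
            "terramotif": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "n_samples": len(samples),
        "n_motifs": len(result.matrix.motifs),
        "n_comparisons": len(result.comparisons),
    }
    with open(summary_path, "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    return RunOutputs(
        counts_dir=counts_dir,
        abundance_matrix=matrix_path,
        correlations=corr_path,
        selected_motifs=selected_path,
        comparisons=comparisons_path,
        zscores=zscores_path,
        triangular=triangular,
        run_log=out / "run.log",
        run_summary=summary_path,
        heatmap=heatmap_path,
    )


def run_pipeline(config: RunConfig) -> RunOutputs:
    """Execute the full pipeline over a manifest and write all outputs.

    Deterministic: two invocations on identical inputs and configuration
    produce byte-identical result tables. Any stage failure raises a
    :class:`~terramotif.errors.StageError` tagged with the stage name.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    log_path = config.out_dir / "run.log"
    log_lines: list[str] = []
    with _stage("load_manifest"):
        samples = load_manifest(config.manifest, category_labels=config.categories)
    counts_dir = config.out_dir / "counts"
    baseline_tables: dict[str, KmerCountTable] = {}
    filtered_tables: list[KmerCountTable] = []
    with _stage("count"):
        for record in samples:
            baseline, filtered = count_sample(record, config)
            baseline.write_tsv(counts_dir)
            filtered.write_tsv(counts_dir)
            baseline_tables[record.sample_id] = baseline
            filtered_tables.append(filtered)
            totals = " ".join(f"k{k}={t}" for k, t in sorted(filtered.totals.items()))
            log_lines.append(
                f"sample={record.sample_id} scanned={filtered.n_reads_scanned} "
                f"retained={filtered.n_reads_retained} {totals}"
            )
    try:
        result = analyze_tables(
            filtered_tables,
            samples,
            config,
            baseline_tables if config.denominator == "baseline" else None,
        )
        outputs = write_outputs(result, samples, config, counts_dir)
    except StageError as exc:
        log_lines.append(f"FAILED stage={exc.stage}: {exc}")
        log_path.write_text("\n".join(log_lines) + "\n")
        raise
    log_lines.append("status=ok")
    log_path.write_text("\n".join(log_lines) + "\n")
    return outputs


def analyze_synthetic_cohort(
    synth: SyntheticConfig,
    config: RunConfig | None = None,
    compute_baseline: bool = False,
    canonical_only: bool = False,
) -> tuple[AnalysisResult, list[SampleRecord]]:
    """Generate a synthetic cohort in memory and run the analysis stages on
    it, without file I/O.

    With ``canonical_only`` the correlation/selection stages are skipped
    and only the canonical motif is tested — the fast path for null
    calibration sweeps. Returns the analysis result and the sample records.
    """
    if config is None:
        labels = tuple(synth.categories)
        background = tuple(l for l in labels if l != "space_effect") or labels[:1]
        config = RunConfig(
            manifest=Path("<memory>"), out_dir=Path("<memory>"),
            categories=labels, focal="space_effect", background=background,
        )
    samples: list[SampleRecord] = []
    filtered_tables: list[KmerCountTable] = []
    baseline_tables: dict[str, KmerCountTable] = {}
    for record, reads, _n_terra in iter_cohort_samples(synth):
        samples.append(record)
        baseline, filtered = _count_reads(
            reads, record.sample_id, config, baseline=compute_baseline
        )
        if baseline is not None:
            baseline_tables[record.sample_id] = baseline
        filtered_tables.append(filtered)
    if not canonical_only:
        return (
            analyze_tables(
                filtered_tables, samples, config,
                baseline_tables if config.denominator == "baseline" else None,
            ),
            samples,
        )
    order = [s.sample_id for s in samples]
    matrix = build_abundance_matrix(
        filtered_tables, denominator=config.denominator, sample_order=order
    )
    canonical = _canonical_class(config)
    design = GroupDesign.two_category(
        samples, focal=config.focal, background=config.background
    )
    comparisons = run_comparisons(
        matrix, design, [canonical],
        alternative=config.alternative, method=config.test_method,
    )
    result = AnalysisResult(
        matrix=matrix,
        correlations=[MotifCorrelation(canonical, 1.0)],
        selected=[canonical],
        comparisons=comparisons,
        zscores=zscore_rows(matrix, [canonical]),
    )
    return result, samples
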