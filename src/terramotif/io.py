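"""Sequencing-read and cohort-manifest input.

All sequences are handled internally in DNA space: RNA ``U`` is mapped to
``T`` at ingest and lowercase is folded to uppercase, so downstream k-mer
code only ever sees the alphabet {A,C,G,T,N}. Motif *reporting* maps back
to RNA form (see :mod:`terramotif.kmers`), because TERRA motifs are
conventionally written as RNA (5'-UUAGGG-3').
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ManifestError, SequenceFormatError, SequenceParseError

__all__ = [
    "SequenceRead",
    "SampleRecord",
    "DEFAULT_CATEGORY_LABELS",
    "read_sequences",
    "load_manifest",
    "write_fasta",
    "write_fastq",
]

#: Category scheme used for the longitudinal exposure designs: pre-flight /
#: ground control, in-flight or immediate post-flight, and later recovery.
DEFAULT_CATEGORY_LABELS = ("ground", "space_effect", "recovery")

_FASTA_EXT = {".fa", ".fasta", ".fna"}
_FASTQ_EXT = {".fq", ".fastq"}
_VALID_BASES = frozenset("ACGTN")

_MANIFEST_COLUMNS = ("sample_id", "subject_id", "timepoint", "category", "reads_path")


@dataclass(frozen=True)
class SequenceRead:
    """One sequencing read: an id and an uppercase DNA-space sequence."""

    read_id: str
    sequence: str


@dataclass(frozen=True)
class SampleRecord:
    """One sequencing sample of a cohort.

    ``timepoint`` is a free label (e.g. ``"L-92"``, ``"FD259"``, ``"R+1"``);
    ``category`` is drawn from a configured label set, by default
    :data:`DEFAULT_CATEGORY_LABELS`.
    """

    sample_id: str
    subject_id: str
    timepoint: str
    category: str
    reads_path: Path


def _strip_gz(path: Path) -> tuple[Path, bool]:
    if path.suffix == ".gz":
        return path.with_suffix(""), True
    return path, False


def _infer_format(path: Path) -> str:
    inner, _ = _strip_gz(path)
    suffix = inner.suffix.lower()
    if suffix in _FASTA_EXT:
        return "fasta"
    if suffix in _FASTQ_EXT:
        return "fastq"
    raise SequenceFormatError(
        f"cannot infer sequence format from extension {path.suffix!r} of {path}; "
        "expected .fa/.fasta/.fq/.fastq (optionally .gz)"
    )


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _ingest(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_sequences(path, format: str = "auto") -> Iterator[SequenceRead]:
    """Stream :class:`SequenceRead` records from a FASTA/FASTQ file.

    Parameters
    ----------
    path:
        File path, optionally gzip-compressed.
    format:
        ``"fasta"``, ``"fastq"`` or ``"auto"`` (inferred from extension).

    Yields records in file order. RNA ``U`` is mapped to ``T`` and lowercase
    folded to uppercase; FASTQ quality strings are parsed (and validated
    against the sequence length by the parser) but discarded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path) if format == "auto" else format
    if fmt not in ("fasta", "fastq"):
        raise SequenceFormatError(f"unsupported format {fmt!r}")
    n = 0
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, fmt):
                n += 1
                seq = _ingest(str(rec.seq))
                if not seq:
                    raise SequenceParseError(
                        f"{path}: empty sequence for record {rec.id!r} (record {n})"
                    )
                bad = set(seq) - _VALID_BASES
                if bad:
                    raise SequenceParseError(
                        f"{path}: record {rec.id!r} (record {n}) contains "
                        f"non-{{A,C,G,T,N}} characters {sorted(bad)}"
                    )
                yield SequenceRead(rec.id, seq)
        except ValueError as exc:  # Biopython signals malformed records this way
            raise SequenceParseError(
                f"{path}: malformed {fmt} near record {n + 1}: {exc}"
            ) from exc


def write_fasta(reads: Iterable[SequenceRead], path) -> Path:
    """Write reads as (optionally gzipped) FASTA; returns the path."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")
    return path


def write_fastq(reads: Iterable[SequenceRead], path, quality_char: str = "I") -> Path:
    """Write reads as (optionally gzipped) Sanger FASTQ with uniform quality."""
    path = Path(path)
    if path.suffix == ".gz":
        # mtime=0 keeps the gzip container byte-reproducible across runs
        import io as _io

        with open(path, "wb") as raw:
            gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
            with _io.TextIOWrapper(gz, encoding="ascii") as fh:
                _write_fastq_records(reads, fh, quality_char)
    else:
        with open(path, "wt") as fh:
            _write_fastq_records(reads, fh, quality_char)
    return path


def _write_fastq_records(reads, fh, quality_char: str) -> None:
    for r in reads:
        fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quality_char * len(r.sequence)}\n")


def load_manifest(
    path,
    category_labels: Sequence[str] = DEFAULT_CATEGORY_LABELS,
    check_paths: bool = True,
) -> list[SampleRecord]:
    """Load a cohort manifest (TSV/CSV with a header row).

    Required columns: ``sample_id, subject_id, timepoint, category,
    reads_path``. The delimiter is taken from the extension (``.csv`` comma,
    otherwise tab). Relative ``reads_path`` entries are resolved against the
    manifest's directory. Duplicate sample ids and categories outside
    ``category_labels`` are rejected.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest column(s) {missing}")
    if df[list(_MANIFEST_COLUMNS)].isna().any().any():
        raise ManifestError(f"{path}: manifest contains empty cells in required columns")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ManifestError(f"{path}: duplicate sample_id(s) {sorted(set(dupes))}")
    labels = set(category_labels)
    offenders = sorted(set(df["category"]) - labels)
    if offenders:
        raise ManifestError(
            f"{path}: categories {offenders} not in configured labels {sorted(labels)}"
        )
    records = []
    for row in df.itertuples(index=False):
        reads_path = Path(row.reads_path)
        if not reads_path.is_absolute():
            reads_path = path.parent / reads_path
        if check_paths and not reads_path.exists():
            raise ManifestError(
                f"{path}: reads file {reads_path} for sample {row.sample_id!r} does not exist"
            )
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                subject_id=row.subject_id,
                timepoint=row.timepoint,
                category=row.category,
                reads_path=reads_path,
            )
        )
    return records
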