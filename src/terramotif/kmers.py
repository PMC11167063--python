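"""Canonical-motif read filtering and k-mer counting under rotation equivalence.

The sliding windows of a tandem repeat cycle through every rotation of its
repeat unit: a read of ``TTAGGGTTAGGG...`` contains the 6-mers ``TTAGGG``,
``TAGGGT``, ``AGGGTT``, ... in equal measure. K-mers are therefore pooled
into *circular-shift equivalence classes*, each named by the
lexicographically smallest rotation of its members (``AGGGTT`` for the
telomeric unit ``TTAGGG``). Optionally a class may also be collapsed with
its reverse complement, merging G-strand and C-strand forms.

Counting is vectorized: reads are joined with ``N`` separators, bases are
2-bit encoded, window codes are accumulated with shifted adds, and windows
containing ``N`` (including the artificial separators) are masked out. A
precomputed per-``k`` lookup table maps every raw k-mer code to its
canonical-class code.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import AlphabetError, AmbiguousKmerError, TerraMotifError
from .io import SequenceRead

__all__ = [
    "CANONICAL_MOTIF_DNA",
    "DEFAULT_KS",
    "KmerClass",
    "KmerCountTable",
    "reverse_complement",
    "canonical_rotation",
    "contains_motif",
    "motif_occurrences",
    "filter_terra_reads",
    "orient_to_g_strand",
    "count_kmer_classes",
    "dna_to_rna",
    "rna_to_dna",
]

#: The canonical TERRA repeat unit in DNA space (RNA 5'-UUAGGG-3').
CANONICAL_MOTIF_DNA = "TTAGGG"

#: The k range analyzed: all 5-, 6- and 7-mers.
DEFAULT_KS = (5, 6, 7)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")
_ACGT = frozenset("ACGT")


def dna_to_rna(seq: str) -> str:
    """Render a DNA-space motif in RNA space (T -> U)."""
    return seq.replace("T", "U")


def rna_to_dna(seq: str) -> str:
    """Map an RNA-space motif into DNA space (U -> T, case-folded)."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise AlphabetError(f"sequence contains non-{{A,C,G,T,N}} characters {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def _rotations(s: str) -> list[str]:
    return [s[i:] + s[:i] for i in range(len(s))]


@lru_cache(maxsize=262_144)
def canonical_rotation(kmer: str, collapse_strands: bool = False) -> str:
    """Lexicographically smallest rotation of ``kmer``.

    With ``collapse_strands`` the minimum is additionally taken over the
    rotations of the reverse complement, merging the two strand forms of a
    repeat unit into one class. The result is idempotent and identical for
    every rotation of the input.
    """
    if "N" in kmer:
        raise AmbiguousKmerError(f"k-mer {kmer!r} contains N and has no rotation class")
    if not set(kmer) <= _ACGT:
        raise AlphabetError(f"k-mer {kmer!r} contains non-DNA characters")
    candidates = _rotations(kmer)
    if collapse_strands:
        candidates += _rotations(reverse_complement(kmer))
    return min(candidates)


@dataclass(frozen=True)
class KmerClass:
    """A k-mer rotation-equivalence class, named by its canonical rotation.

    ``canonical`` is a DNA string; :attr:`display` renders it in RNA space,
    the convention used for reporting TERRA motifs.
    """

    canonical: str

    def __post_init__(self):
        if not self.canonical or not set(self.canonical) <= _ACGT:
            raise AlphabetError(f"invalid class representative {self.canonical!r}")

    @property
    def k(self) -> int:
        return len(self.canonical)

    @property
    def display(self) -> str:
        return dna_to_rna(self.canonical)

    @classmethod
    def from_kmer(cls, kmer: str, collapse_strands: bool = False) -> "KmerClass":
        return cls(canonical_rotation(rna_to_dna(kmer), collapse_strands))

    def sort_key(self) -> tuple[int, str]:
        return (self.k, self.canonical)


#: Rotation class of the canonical TERRA unit (``AGGGTT`` / RNA ``AGGGUU``).
CANONICAL_CLASS = KmerClass(canonical_rotation(CANONICAL_MOTIF_DNA))
__all__.append("CANONICAL_CLASS")


def _count_overlapping(haystack: str, needle: str) -> int:
    n = 0
    start = haystack.find(needle)
    while start != -1:
        n += 1
        start = haystack.find(needle, start + 1)
    return n


def _seq_of(read) -> str:
    return read.sequence if isinstance(read, SequenceRead) else str(read)


def motif_occurrences(read, motif: str = CANONICAL_MOTIF_DNA, both_strands: bool = True) -> int:
    """Number of (overlapping) motif occurrences, optionally on either strand."""
    if not set(motif) <= _ACGT:
        raise AlphabetError(f"motif {motif!r} must be over {{A,C,G,T}}")
    seq = _seq_of(read)
    n = _count_overlapping(seq, motif)
    if both_strands:
        rc = reverse_complement(motif)
        if rc != motif:
            n += _count_overlapping(seq, rc)
    return n


def contains_motif(read, motif: str = CANONICAL_MOTIF_DNA, both_strands: bool = True) -> bool:
    """True iff the read contains ``motif`` (or, optionally, its reverse
    complement) as an exact substring. N never matches."""
    if not set(motif) <= _ACGT:
        raise AlphabetError(f"motif {motif!r} must be over {{A,C,G,T}}")
    seq = _seq_of(read)
    if motif in seq:
        return True
    return both_strands and reverse_complement(motif) in seq


def filter_terra_reads(
    reads: Iterable[SequenceRead],
    motif: str = CANONICAL_MOTIF_DNA,
    min_occurrences: int = 1,
    both_strands: bool = True,
) -> Iterator[SequenceRead]:
    """Yield reads carrying at least ``min_occurrences`` motif occurrences
    on either strand, preserving input order."""
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be >= 1")
    if min_occurrences == 1:
        for read in reads:
            if contains_motif(read, motif, both_strands):
                yield read
    else:
        for read in reads:
            if motif_occurrences(read, motif, both_strands) >= min_occurrences:
                yield read


def orient_to_g_strand(read: SequenceRead, motif: str = CANONICAL_MOTIF_DNA) -> SequenceRead:
    """Return the read oriented so the motif lies on the forward strand.

    A read matching on the forward strand (which takes priority when both
    strands match) is returned unchanged; a read matching only via the
    reverse complement is reverse-complemented whole. Used so that motif
    classes report on the G-rich transcript strand (RNA UUAGGG form).
    """
    if motif in read.sequence:
        return read
    if reverse_complement(motif) in read.sequence:
        return SequenceRead(read.read_id, reverse_complement(read.sequence))
    raise TerraMotifError(
        f"read {read.read_id!r} contains motif {motif!r} on neither strand; "
        "orient_to_g_strand expects motif-filtered reads"
    )


# ---------------------------------------------------------------------------
# vectorized counting

_BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i

_canon_tables: dict[tuple[int, bool], np.ndarray] = {}


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for j in range(k):
        out.append(_BASES[(code >> (2 * (k - 1 - j))) & 3])
    return "".join(out)


def _encode_kmer(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = (code << 2) | int(_CODE[ord(b)])
    return code


def _canonical_code_table(k: int, collapse_strands: bool) -> np.ndarray:
    key = (k, collapse_strands)
    table = _canon_tables.get(key)
    if table is None:
        table = np.empty(4**k, dtype=np.int64)
        for code in range(4**k):
            table[code] = _encode_kmer(canonical_rotation(_decode_kmer(code, k), collapse_strands))
        _canon_tables[key] = table
    return table


def _window_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Codes of all valid (N-free) width-k windows of an encoded base array."""
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    a = arr.astype(np.int64)
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + a[j : j + m]
    bad = (arr == 255).astype(np.int64)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    good = (cbad[k:] - cbad[:-k]) == 0
    return codes[good]


@dataclass
class KmerCountTable:
    """Per-sample counts of k-mer classes for one counting scope.

    ``scope`` is ``"baseline"`` (all reads, raw k-mers) or ``"filtered"``
    (motif-containing reads, rotation classes). ``totals[k]`` is the number
    of counted width-``k`` windows, the per-``k`` normalization denominator.
    """

    sample_id: str
    scope: str
    counts: dict[KmerClass, int] = field(default_factory=dict)
    totals: dict[int, int] = field(default_factory=dict)
    n_reads_scanned: int = 0
    n_reads_retained: int | None = None

    def validate(self) -> None:
        per_k: dict[int, int] = {}
        for mc, c in self.counts.items():
            if c < 0:
                raise TerraMotifError(f"negative count for {mc.canonical}")
            per_k[mc.k] = per_k.get(mc.k, 0) + c
        for k, total in per_k.items():
            if total != self.totals.get(k, 0):
                raise TerraMotifError(
                    f"totals[{k}]={self.totals.get(k, 0)} != sum of counts {total}"
                )
        if self.n_reads_retained is not None and self.n_reads_retained > self.n_reads_scanned:
            raise TerraMotifError("n_reads_retained exceeds n_reads_scanned")

    # -- serialization -----------------------------------------------------
    def counts_frame(self) -> pd.DataFrame:
        rows = [
            (self.sample_id, self.scope, mc.k, mc.canonical, mc.display, c)
            for mc, c in sorted(self.counts.items(), key=lambda kv: kv[0].sort_key())
        ]
        return pd.DataFrame(
            rows, columns=["sample_id", "scope", "k", "motif_dna", "motif_rna", "count"]
        )

    def totals_frame(self) -> pd.DataFrame:
        rows = [(self.sample_id, self.scope, k, t) for k, t in sorted(self.totals.items())]
        df = pd.DataFrame(rows, columns=["sample_id", "scope", "k", "total"])
        df["n_reads_scanned"] = self.n_reads_scanned
        df["n_reads_retained"] = (
            -1 if self.n_reads_retained is None else self.n_reads_retained
        )
        return df

    def write_tsv(self, directory) -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        counts_path = directory / f"{self.sample_id}.{self.scope}.counts.tsv"
        totals_path = directory / f"{self.sample_id}.{self.scope}.totals.tsv"
        self.counts_frame().to_csv(counts_path, sep="\t", index=False)
        self.totals_frame().to_csv(totals_path, sep="\t", index=False)
        return counts_path, totals_path

    @classmethod
    def read_tsv(cls, counts_path, totals_path) -> "KmerCountTable":
        cf = pd.read_csv(counts_path, sep="\t")
        tf = pd.read_csv(totals_path, sep="\t")
        if cf.empty and tf.empty:
            raise TerraMotifError(f"empty count tables at {counts_path}")
        sample_id = str(tf["sample_id"].iloc[0]) if len(tf) else str(cf["sample_id"].iloc[0])
        scope = str(tf["scope"].iloc[0]) if len(tf) else str(cf["scope"].iloc[0])
        counts = {KmerClass(str(r.motif_dna)): int(r.count) for r in cf.itertuples()}
        totals = {int(r.k): int(r.total) for r in tf.itertuples()}
        scanned = int(tf["n_reads_scanned"].iloc[0]) if len(tf) else 0
        retained = int(tf["n_reads_retained"].iloc[0]) if len(tf) else -1
        return cls(
            sample_id=sample_id,
            scope=scope,
            counts=counts,
            totals=totals,
            n_reads_scanned=scanned,
            n_reads_retained=None if retained < 0 else retained,
        )


def count_kmer_classes(
    reads: Iterable,
    ks: Sequence[int] = DEFAULT_KS,
    canonicalize: bool = True,
    collapse_strands: bool = False,
    sample_id: str = "sample",
    scope: str = "filtered",
) -> KmerCountTable:
    """Count width-``k`` sliding windows (step 1) of all reads, per ``k``.

    Windows containing ``N`` are skipped; reads shorter than ``k``
    contribute nothing. With ``canonicalize`` each window is mapped to its
    rotation class (optionally strand-collapsed); without it raw k-mers are
    counted, as for the baseline scope. ``reads`` may be
    :class:`~terramotif.io.SequenceRead` objects or plain strings.
    """
    for k in ks:
        if not 1 <= k <= 8:
            raise ValueError(f"unsupported k={k}; expected small k (the study uses 5-7)")
    seqs = [_seq_of(r) for r in reads]
    joined = "N".join(seqs)
    if joined:
        arr = _CODE[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    else:
        arr = np.empty(0, dtype=np.uint8)
    counts: dict[KmerClass, int] = {}
    totals: dict[int, int] = {}
    for k in sorted(set(ks)):
        codes = _window_codes(arr, k)
        totals[k] = int(codes.size)
        if not codes.size:
            continue
        raw = np.bincount(codes, minlength=4**k)
        if canonicalize:
            table = _canonical_code_table(k, collapse_strands)
            agg = np.zeros(4**k, dtype=np.int64)
            np.add.at(agg, table, raw)
        else:
            agg = raw
        for code in np.nonzero(agg)[0]:
            counts[KmerClass(_decode_kmer(int(code), k))] = int(agg[code])
    return KmerCountTable(
        sample_id=sample_id,
        scope=scope,
        counts=counts,
        totals=totals,
        n_reads_scanned=len(seqs),
        n_reads_retained=len(seqs) if scope == "filtered" else None,
    )
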