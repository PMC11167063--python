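"""Normalized motif abundances, correlation ranking and z-scoring.

The abundance of a k-mer class in a sample is its count divided by the
total count of all k-mers of the same ``k`` in that sample (so, per sample
and per ``k``, abundances sum to 1 under the filtered denominator). Motif
variants are then ranked by the Pearson correlation of their abundance
profile across samples to the canonical TERRA motif's profile: variants of
the repeat co-vary with the canonical unit and serve as proxies for TERRA
content. Classes of all ``k`` are pooled into one ranking; note that counts
of shorter k-mers are partially contributed to by longer k-mers, a caveat
reported with the output rather than corrected for.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import TerraMotifError
from .kmers import CANONICAL_CLASS, KmerClass, KmerCountTable

__all__ = [
    "MotifAbundanceMatrix",
    "MotifCorrelation",
    "normalize_counts",
    "build_abundance_matrix",
    "correlate_to_canonical",
    "select_top_motifs",
    "zscore_rows",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifCorrelation:
    """Pearson correlation of one motif's abundance profile to the
    canonical motif's profile; ``r`` is NaN when undefined (zero variance)."""

    motif: KmerClass
    r: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


@dataclass
class MotifAbundanceMatrix:
    """Motifs x samples matrix of normalized abundances.

    ``values`` is indexed by canonical DNA strings (rows) and sample ids
    (columns); entries are unitless fractions in [0, 1]. Motifs of mixed
    ``k`` are pooled.
    """

    values: pd.DataFrame
    denominator_scope: str = "filtered"

    @property
    def motifs(self) -> list[KmerClass]:
        return [KmerClass(m) for m in self.values.index]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def row(self, motif: KmerClass) -> np.ndarray:
        return self.values.loc[motif.canonical].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = self.values.copy()
        df.insert(0, "k", [len(m) for m in df.index])
        df.index = pd.Index([m.replace("T", "U") for m in self.values.index], name="motif_rna")
        return df


def normalize_counts(
    table: KmerCountTable,
    denominator: str = "filtered",
    baseline_table: KmerCountTable | None = None,
) -> dict[KmerClass, float]:
    """Normalize a count table: each class's count divided by the chosen
    scope's per-``k`` total.

    ``denominator="filtered"`` uses the table's own totals; ``"baseline"``
    divides by the whole-dataset totals of ``baseline_table`` (same sample).
    A ``k`` whose total is zero yields no entries and a logged warning.
    """
    if denominator not in ("filtered", "baseline"):
        raise TerraMotifError(f"unknown denominator scope {denominator!r}")
    if denominator == "baseline":
        if baseline_table is None:
            raise TerraMotifError(
                "denominator='baseline' requires the sample's baseline count table"
            )
        totals = baseline_table.totals
    else:
        totals = table.totals
    out: dict[KmerClass, float] = {}
    warned: set[int] = set()
    for mc, c in table.counts.items():
        t = totals.get(mc.k, 0)
        if t <= 0:
            if mc.k not in warned:
                warned.add(mc.k)
                log.warning(
                    "sample %s: zero total for k=%d under %s denominator; "
                    "k=%d abundances omitted",
                    table.sample_id, mc.k, denominator, mc.k,
                )
            continue
        out[mc] = c / t
    return out


def build_abundance_matrix(
    tables: Sequence[KmerCountTable],
    denominator: str = "filtered",
    baseline_tables: Mapping[str, KmerCountTable] | None = None,
    sample_order: Sequence[str] | None = None,
) -> MotifAbundanceMatrix:
    """Assemble the motifs x samples abundance matrix from per-sample
    filtered count tables.

    The motif universe is the union of classes observed in any sample;
    unobserved cells are 0. Column order follows ``sample_order`` (e.g. the
    manifest) or, by default, the order of ``tables``; row order is
    deterministic (by ``k`` then canonical string), so the matrix does not
    depend on input table ordering.
    """
    if len(tables) < 2:
        raise TerraMotifError("need at least 2 samples to build an abundance matrix")
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise TerraMotifError(f"duplicate sample_id(s) across count tables: {dupes}")
    normalized: dict[str, dict[KmerClass, float]] = {}
    for t in tables:
        bt = baseline_tables.get(t.sample_id) if baseline_tables else None
        normalized[t.sample_id] = normalize_counts(t, denominator, bt)
    universe: set[KmerClass] = set()
    for d in normalized.values():
        universe.update(d)
    motifs = sorted(universe, key=lambda m: m.sort_key())
    columns = list(sample_order) if sample_order is not None else ids
    if set(columns) != set(ids):
        raise TerraMotifError("sample_order does not match the provided count tables")
    data = np.zeros((len(motifs), len(columns)))
    index = {m: i for i, m in enumerate(motifs)}
    for j, sid in enumerate(columns):
        for mc, v in normalized[sid].items():
            data[index[mc], j] = v
    values = pd.DataFrame(data, index=[m.canonical for m in motifs], columns=columns)
    return MotifAbundanceMatrix(values=values, denominator_scope=denominator)


def correlate_to_canonical(
    matrix: MotifAbundanceMatrix, canonical: KmerClass = CANONICAL_CLASS
) -> list[MotifCorrelation]:
    """Pearson r of every motif's abundance profile against the canonical
    motif's profile, across all samples jointly.

    Zero-variance profiles get NaN (undefined) and are excluded from
    ranking. The canonical motif's own entry is exactly 1.
    """
    if canonical.canonical not in matrix.values.index:
        raise TerraMotifError(
            f"canonical motif class {canonical.canonical} ({canonical.display}) absent "
            "from the abundance matrix; upstream filtering/counting is misconfigured"
        )
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise TerraMotifError("correlation requires at least 2 samples")
    c = matrix.row(canonical)
    Xc = X - X.mean(axis=1, keepdims=True)
    cc = c - c.mean()
    ss_x = (Xc**2).sum(axis=1)
    ss_c = float((cc**2).sum())
    denom = np.sqrt(ss_x * ss_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (Xc @ cc) / np.where(denom > 0, denom, 1.0), np.nan)
    r = np.clip(r, -1.0, 1.0)
    out = []
    for i, m in enumerate(matrix.values.index):
        mc = KmerClass(m)
        out.append(MotifCorrelation(mc, 1.0 if mc == canonical else float(r[i])))
    return out


def select_top_motifs(
    correlations: Iterable[MotifCorrelation],
    n: int = 10,
    canonical: KmerClass = CANONICAL_CLASS,
) -> list[KmerClass]:
    """The ``n`` motifs most correlated to the canonical motif, including
    the canonical motif itself, which always ranks first.

    Ties are broken lexicographically on the canonical DNA string;
    undefined (NaN) correlations are never selected. If fewer than ``n``
    motifs have a defined correlation, all of them are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    defined = [c for c in correlations if c.defined]
    ranked = sorted(defined, key=lambda c: (-c.r, c.motif.canonical))
    motifs = [c.motif for c in ranked]
    if canonical in motifs:
        motifs.remove(canonical)
        motifs.insert(0, canonical)
    if len(motifs) < n:
        log.info("only %d motifs with defined correlation available (requested %d)",
                 len(motifs), n)
    return motifs[:n]


def zscore_rows(
    matrix: MotifAbundanceMatrix, motifs: Sequence[KmerClass] | None = None
) -> pd.DataFrame:
    """Z-score abundances per motif row across all samples of the run.

    Uses the sample standard deviation (ddof=1); rows with zero standard
    deviation map to all zeros. Returns a motifs x samples DataFrame indexed
    like the abundance matrix (canonical DNA strings).
    """
    if motifs is None:
        sub = matrix.values
    else:
        missing = [m.canonical for m in motifs if m.canonical not in matrix.values.index]
        if missing:
            raise TerraMotifError(f"motifs not in matrix: {missing}")
        sub = matrix.values.loc[[m.canonical for m in motifs]]
    arr = sub.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True) if arr.shape[1] > 1 else np.zeros_like(mu)
    constant = (arr == arr[:, :1]).all(axis=1, keepdims=True)
    degenerate = constant | (sd == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, 0.0, (arr - mu) / np.where(sd > 0, sd, 1.0))
    return pd.DataFrame(z, index=sub.index, columns=sub.columns)
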