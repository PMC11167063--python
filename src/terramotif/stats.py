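"""Nonparametric group comparisons of motif abundances with FDR control.

Cohorts here are small (a handful of subjects and timepoints), so the
Mann-Whitney U test uses the exact null distribution whenever the combined
sample is small (n_a + n_b <= 12) and tie-free, and a tie-corrected normal
approximation with continuity correction otherwise. All p-values emitted by
one run are pooled into a single Benjamini-Hochberg family.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, TerraMotifError
from .io import SampleRecord
from .kmers import KmerClass

__all__ = [
    "MannWhitneyResult",
    "GroupDesign",
    "ComparisonResult",
    "mann_whitney_u",
    "benjamini_hochberg",
    "run_comparisons",
    "results_frame",
    "triangular_q_frame",
]

log = logging.getLogger(__name__)

_ALTERNATIVES = {
    "two_sided": "two-sided",
    "two-sided": "two-sided",
    "greater": "greater",
    "less": "less",
}

#: Exact enumeration is used up to this combined sample size (no ties).
EXACT_N_MAX = 12


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str  # "exact" or "normal_approx"


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> MannWhitneyResult:
    """Mann-Whitney U test; U counts pairs (x_i, y_j) with x_i > y_j plus
    half the tied pairs.

    ``method="auto"`` selects the exact null distribution when
    n_x + n_y <= 12 with no ties, otherwise the tie-corrected normal
    approximation with continuity correction. When every value in both
    groups is identical the test is uninformative and p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise TerraMotifError("mann_whitney_u requires non-empty groups")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    alt = _ALTERNATIVES[alternative]
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        log.warning("all values identical in both groups; p = 1 by convention")
        return MannWhitneyResult(u=x.size * y.size / 2.0, p=1.0, method="normal_approx")
    has_ties = np.unique(combined).size < combined.size
    if method == "auto":
        use = "exact" if (combined.size <= EXACT_N_MAX and not has_ties) else "asymptotic"
    elif method == "exact":
        use = "exact"
    elif method in ("normal_approx", "asymptotic"):
        use = "asymptotic"
    else:
        raise ValueError(f"unknown method {method!r}")
    res = sps.mannwhitneyu(x, y, alternative=alt, method=use, use_continuity=True)
    return MannWhitneyResult(
        u=float(res.statistic),
        p=float(res.pvalue),
        method="exact" if use == "exact" else "normal_approx",
    )


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, returned in input order.

    Sorted ascending, p_(i) * m / i, monotonicity enforced by a running
    minimum from the largest rank downward, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.asarray(sps.false_discovery_control(p, method="bh"), dtype=float)


@dataclass
class GroupDesign:
    """Assignment of samples to comparison groups.

    ``two_category`` mode compares a focal group against one combined
    background group (e.g. space_effect vs ground+recovery); in
    ``pairwise_groups`` mode every unordered pair of groups (e.g.
    per-timepoint groups) is compared.
    """

    mode: str
    group_assignments: dict[str, str]
    focal: str | None = None
    background_label: str | None = None

    def __post_init__(self):
        if self.mode not in ("two_category", "pairwise_groups"):
            raise DesignError(f"unknown design mode {self.mode!r}")
        labels = set(self.group_assignments.values())
        if self.mode == "two_category":
            if self.focal is None or self.background_label is None:
                raise DesignError("two_category mode requires focal and background labels")
            if labels != {self.focal, self.background_label}:
                raise DesignError(
                    f"two_category design must yield exactly the groups "
                    f"{{{self.focal!r}, {self.background_label!r}}}; got {sorted(labels)}"
                )
        elif len(labels) < 2:
            raise DesignError("pairwise_groups mode requires at least 2 groups")

    @classmethod
    def two_category(
        cls,
        samples: Iterable[SampleRecord],
        focal: str = "space_effect",
        background: Sequence[str] = ("ground", "recovery"),
        background_label: str | None = None,
    ) -> "GroupDesign":
        """Focal category vs the combined non-focal categories."""
        background = tuple(background)
        label = background_label or "+".join(background)
        assignments: dict[str, str] = {}
        for s in samples:
            if s.category == focal:
                assignments[s.sample_id] = focal
            elif s.category in background:
                assignments[s.sample_id] = label
        if not assignments:
            raise DesignError("no samples match the focal/background categories")
        return cls(
            mode="two_category",
            group_assignments=assignments,
            focal=focal,
            background_label=label,
        )

    @classmethod
    def pairwise_groups(
        cls, samples: Iterable[SampleRecord], by: str = "timepoint"
    ) -> "GroupDesign":
        """One group per distinct ``by`` label (timepoint or category)."""
        if by not in ("timepoint", "category"):
            raise DesignError("pairwise grouping must be by 'timepoint' or 'category'")
        assignments = {s.sample_id: getattr(s, by) for s in samples}
        return cls(mode="pairwise_groups", group_assignments=assignments)

    def groups(self, sample_order: Sequence[str]) -> dict[str, list[str]]:
        """Group label -> sample ids, restricted to ``sample_order`` and
        preserving that order within groups."""
        out: dict[str, list[str]] = {}
        for sid in sample_order:
            label = self.group_assignments.get(sid)
            if label is not None:
                out.setdefault(label, []).append(sid)
        return out


@dataclass
class ComparisonResult:
    """One motif x one group comparison with raw and BH-adjusted p-values."""

    motif: KmerClass
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_raw: float
    q_adjusted: float
    method: str


def run_comparisons(
    matrix,
    design: GroupDesign,
    motifs: Sequence[KmerClass],
    alternative: str = "two-sided",
    method: str = "auto",
) -> list[ComparisonResult]:
    """Mann-Whitney comparisons for each motif under the design, with all
    resulting p-values pooled into a single BH adjustment.

    ``two_category`` mode emits one test per motif (focal vs combined
    background); ``pairwise_groups`` mode emits one test per motif per
    unordered group pair.
    """
    if not motifs:
        raise DesignError("no motifs to test")
    groups = design.groups(matrix.samples)
    for label, ids in groups.items():
        if not ids:
            raise DesignError(f"group {label!r} has no samples")
        if len(ids) < 3:
            log.warning("group %r has only %d sample(s); test power is limited",
                        label, len(ids))
    if design.mode == "two_category":
        for label in (design.focal, design.background_label):
            if label not in groups:
                raise DesignError(f"group {label!r} has no samples in the matrix")
        pairs = [(design.focal, design.background_label)]
    else:
        pairs = list(itertools.combinations(sorted(groups), 2))
    col_index = {sid: j for j, sid in enumerate(matrix.samples)}
    X = matrix.values.to_numpy(dtype=float)
    row_index = {m: i for i, m in enumerate(matrix.values.index)}
    results: list[ComparisonResult] = []
    for group_a, group_b in pairs:
        ja = [col_index[s] for s in groups[group_a]]
        jb = [col_index[s] for s in groups[group_b]]
        for motif in motifs:
            row = X[row_index[motif.canonical]]
            mw = mann_whitney_u(row[ja], row[jb], alternative=alternative, method=method)
            results.append(
                ComparisonResult(
                    motif=motif,
                    group_a=group_a,
                    group_b=group_b,
                    n_a=len(ja),
                    n_b=len(jb),
                    u_statistic=mw.u,
                    p_raw=mw.p,
                    q_adjusted=float("nan"),
                    method=mw.method,
                )
            )
    q = benjamini_hochberg([r.p_raw for r in results])
    for r, qi in zip(results, q):
        r.q_adjusted = float(qi)
    return results


def results_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    rows = [
        (
            r.motif.display, r.motif.k, r.group_a, r.group_b, r.n_a, r.n_b,
            r.u_statistic, r.p_raw, r.q_adjusted, r.method,
        )
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "motif_rna", "k", "group_a", "group_b", "n_a", "n_b",
            "U", "p_raw", "q_adjusted", "method",
        ],
    )


def triangular_q_frame(results: Sequence[ComparisonResult], motif: KmerClass) -> pd.DataFrame:
    """Groups x groups triangular matrix of BH-adjusted p-values for one
    motif (pairwise design reporting)."""
    sub = [r for r in results if r.motif == motif]
    labels = sorted({r.group_a for r in sub} | {r.group_b for r in sub})
    df = pd.DataFrame(np.nan, index=labels, columns=labels)
    for r in sub:
        a, b = sorted((r.group_a, r.group_b))
        df.loc[b, a] = r.q_adjusted
    return df
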