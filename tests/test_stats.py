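import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from terramotif import (
    GroupDesign,
    KmerClass,
    SampleRecord,
    benjamini_hochberg,
    mann_whitney_u,
    run_comparisons,
)
from terramotif.abundance import MotifAbundanceMatrix
from terramotif.errors import DesignError, TerraMotifError
from terramotif.stats import results_frame, triangular_q_frame

from oracles import permutation_mannwhitney_p, stepup_bh, u_statistic


def _sample(sid, category, timepoint="T1"):
    from pathlib import Path

    return SampleRecord(sid, "S1", timepoint, category, Path("x.fa"))


def _matrix(data, samples):
    return MotifAbundanceMatrix(values=pd.DataFrame(data, index=samples).T)


# -- Mann-Whitney -----------------------------------------------------------

def test_mann_whitney_separated_groups():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.u == 0.0
    assert res.p == pytest.approx(0.1)  # 2 of 20 assignments as extreme
    assert res.method == "exact"


def test_mann_whitney_u_counts_favorable_pairs():
    res = mann_whitney_u([1, 3, 5], [2, 4, 6])
    assert res.u == 3.0  # 0 + 1 + 2


def test_mann_whitney_two_sided_symmetry():
    x, y = [0.3, 1.2, 0.8, 2.0], [0.9, 1.1, 0.2]
    assert mann_whitney_u(x, y).p == pytest.approx(mann_whitney_u(y, x).p)


def test_mann_whitney_all_identical_values():
    res = mann_whitney_u([1.0, 1.0], [1.0, 1.0, 1.0])
    assert res.p == 1.0
    assert res.u == 3.0  # all pairs tied, half of n_a*n_b


def test_mann_whitney_empty_group_rejected():
    with pytest.raises(TerraMotifError):
        mann_whitney_u([], [1.0])


@given(st.integers(0, 5000))
def test_u_statistics_sum_to_product_of_group_sizes(seed):
    rng = np.random.default_rng(seed)
    n_a, n_b = int(rng.integers(1, 8)), int(rng.integers(1, 8))
    # draws from a small integer set force ties, exercising the half-count
    x = rng.integers(0, 4, n_a).astype(float)
    y = rng.integers(0, 4, n_b).astype(float)
    method = "normal_approx" if np.unique(np.r_[x, y]).size > 1 else "auto"
    ux = mann_whitney_u(x, y, method=method).u
    uy = mann_whitney_u(y, x, method=method).u
    assert ux + uy == pytest.approx(n_a * n_b)
    assert ux == pytest.approx(u_statistic(x, y))


def test_exact_path_matches_permutation_oracle():
    rng = np.random.default_rng(7)
    for _ in range(25):
        n_a, n_b = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        x, y = rng.random(n_a), rng.random(n_b)
        res = mann_whitney_u(x, y)
        assert res.method == "exact"
        assert res.p == pytest.approx(permutation_mannwhitney_p(x, y), abs=1e-12)


def test_exact_and_normal_approx_agree_for_balanced_groups():
    rng = np.random.default_rng(11)
    for _ in range(50):
        x, y = rng.random(6), rng.random(6)
        p_exact = mann_whitney_u(x, y, method="exact").p
        p_norm = mann_whitney_u(x, y, method="normal_approx").p
        assert abs(p_exact - p_norm) < 0.05


# -- Benjamini-Hochberg -----------------------------------------------------

def test_bh_worked_examples():
    assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
        [0.04, 0.04, 0.04, 0.04]
    )
    assert benjamini_hochberg([0.005, 0.011, 0.02, 0.04]) == pytest.approx(
        [0.02, 0.022, 0.026667, 0.04], abs=1e-5
    )
    assert benjamini_hochberg([0.3]) == pytest.approx([0.3])


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.1, 1.2])
    with pytest.raises(ValueError):
        benjamini_hochberg([-0.1])


@given(st.integers(0, 5000))
def test_bh_matches_stepup_oracle_and_statsmodels(seed):
    rng = np.random.default_rng(seed)
    p = rng.random(int(rng.integers(1, 40)))
    q = benjamini_hochberg(p)
    assert q == pytest.approx(stepup_bh(list(p)), abs=1e-12)
    try:
        from statsmodels.stats.multitest import multipletests
    except ImportError:
        pass
    else:
        assert q == pytest.approx(multipletests(p, method="fdr_bh")[1], abs=1e-12)
    # never decreases any p; preserves order of distinct p-values
    assert (q >= p - 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


# -- grouped comparisons ----------------------------------------------------

CANON = KmerClass("AGGGTT")


def test_two_category_single_motif_q_equals_p():
    samples = [
        _sample("a1", "space_effect"), _sample("a2", "space_effect"),
        _sample("a3", "space_effect"), _sample("b1", "ground"),
        _sample("b2", "ground"), _sample("b3", "recovery"),
    ]
    m = _matrix({CANON.canonical: [0.9, 0.8, 0.85, 0.1, 0.2, 0.15]},
                [s.sample_id for s in samples])
    design = GroupDesign.two_category(samples)
    results = run_comparisons(m, design, [CANON])
    assert len(results) == 1
    r = results[0]
    assert r.q_adjusted == r.p_raw  # BH with m=1 is the identity
    assert r.group_a == "space_effect"
    assert (r.n_a, r.n_b) == (3, 3)
    assert 0 <= r.u_statistic <= r.n_a * r.n_b


def test_pairwise_design_emits_one_shared_bh_family():
    samples = []
    values = {}
    rng = np.random.default_rng(0)
    for t in ("T1", "T2", "T3", "T4"):
        for i in range(3):
            samples.append(_sample(f"{t}_{i}", "ground", timepoint=t))
    motifs = [KmerClass(f"A{b}GGGT") for b in "ACGT"] + [
        KmerClass(f"AC{b}GGT") for b in "ACGT"] + [KmerClass("AGGGTT"), KmerClass("AGGTTT")]
    ids = [s.sample_id for s in samples]
    data = {m.canonical: rng.random(len(ids)) for m in motifs}
    matrix = _matrix(data, ids)
    design = GroupDesign.pairwise_groups(samples, by="timepoint")
    results = run_comparisons(matrix, design, motifs)
    assert len(results) == 60  # 6 unordered pairs x 10 motifs
    # pooled family: adjustment applied across all 60 results at once
    assert benjamini_hochberg([r.p_raw for r in results]) == pytest.approx(
        [r.q_adjusted for r in results]
    )
    tri = triangular_q_frame(results, motifs[0])
    assert tri.shape == (4, 4)
    assert tri.notna().sum().sum() == 6


def test_design_rejects_empty_group():
    samples = [_sample("a", "ground"), _sample("b", "ground")]
    with pytest.raises(DesignError):
        GroupDesign.two_category(samples)  # no space_effect samples


def test_results_frame_columns():
    samples = [_sample(f"s{i}", "space_effect" if i < 3 else "ground") for i in range(6)]
    m = _matrix({CANON.canonical: [0.5, 0.6, 0.7, 0.1, 0.2, 0.3]},
                [s.sample_id for s in samples])
    results = run_comparisons(m, GroupDesign.two_category(samples), [CANON])
    df = results_frame(results)
    assert list(df.columns) == [
        "motif_rna", "k", "group_a", "group_b", "n_a", "n_b",
        "U", "p_raw", "q_adjusted", "method",
    ]
    assert df.loc[0, "motif_rna"] == "AGGGUU"
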