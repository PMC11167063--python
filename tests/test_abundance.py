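import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from terramotif import (
    CANONICAL_CLASS,
    KmerClass,
    KmerCountTable,
    build_abundance_matrix,
    correlate_to_canonical,
    normalize_counts,
    select_top_motifs,
    zscore_rows,
)
from terramotif.abundance import MotifAbundanceMatrix, MotifCorrelation
from terramotif.errors import TerraMotifError

A6, B6, C6 = KmerClass("AGGGTT"), KmerClass("AGGGGT"), KmerClass("AAGGGT")


def _table(sample_id, counts, scope="filtered"):
    totals = {}
    for m, c in counts.items():
        totals[m.k] = totals.get(m.k, 0) + c
    return KmerCountTable(sample_id=sample_id, scope=scope, counts=dict(counts),
                          totals=totals)


def _matrix(data, samples):
    """data: dict canonical -> list of per-sample values."""
    import pandas as pd

    return MotifAbundanceMatrix(
        values=pd.DataFrame(data, index=samples).T, denominator_scope="filtered"
    )


# -- normalization ----------------------------------------------------------

def test_normalize_divides_by_per_k_totals():
    t = _table("s", {A6: 3, B6: 1})
    assert normalize_counts(t) == {A6: 0.75, B6: 0.25}


def test_normalize_single_class_is_one():
    t = _table("s", {A6: 17})
    assert normalize_counts(t) == {A6: 1.0}


def test_normalize_three_classes():
    t = _table("s", {A6: 2, B6: 2, C6: 4})
    assert normalize_counts(t) == {A6: 0.25, B6: 0.25, C6: 0.5}


def test_normalize_baseline_requires_baseline_table():
    t = _table("s", {A6: 3})
    with pytest.raises(TerraMotifError):
        normalize_counts(t, denominator="baseline")
    base = _table("s", {KmerClass("TTAGGG"): 3, KmerClass("GGGGGG"): 9}, scope="baseline")
    assert normalize_counts(t, denominator="baseline", baseline_table=base) == {A6: 0.25}


def test_normalize_zero_total_yields_no_entries():
    t = KmerCountTable("s", "filtered", {}, {6: 0})
    assert normalize_counts(t) == {}


# -- matrix assembly --------------------------------------------------------

def test_matrix_union_fills_zeros_and_follows_manifest_order():
    t1 = _table("s1", {A6: 2, B6: 2, KmerClass("AGGTT"): 4})
    t2 = _table("s2", {C6: 1, KmerClass("AGGGT"): 1})
    m = build_abundance_matrix([t1, t2], sample_order=["s1", "s2"])
    assert m.values.shape == (5, 2)
    assert m.samples == ["s1", "s2"]
    assert (m.values.to_numpy() == 0).sum() == 5  # unobserved cells
    # permuting table order leaves the matrix unchanged
    m2 = build_abundance_matrix([t2, t1], sample_order=["s1", "s2"])
    assert m.values.equals(m2.values)


def test_matrix_per_k_columns_sum_to_one(small_cohort_config):
    from terramotif import count_kmer_classes, filter_terra_reads, orient_to_g_strand
    from terramotif.simulate import iter_cohort_samples

    tables = []
    for record, reads, _ in iter_cohort_samples(small_cohort_config):
        kept = [orient_to_g_strand(r) for r in filter_terra_reads(reads)]
        tables.append(count_kmer_classes(kept, sample_id=record.sample_id))
    m = build_abundance_matrix(tables)
    ks = np.array([len(i) for i in m.values.index])
    for k in (5, 6, 7):
        sums = m.values.to_numpy()[ks == k].sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)
    assert ((m.values.to_numpy() >= 0) & (m.values.to_numpy() <= 1)).all()


def test_matrix_scale_invariance():
    t1 = _table("s1", {A6: 2, B6: 6})
    t1_scaled = _table("s1", {A6: 20, B6: 60})
    t2 = _table("s2", {A6: 1, B6: 1})
    m = build_abundance_matrix([t1, t2])
    m_scaled = build_abundance_matrix([t1_scaled, t2])
    assert np.allclose(m.values.to_numpy(), m_scaled.values.to_numpy())


def test_matrix_rejects_duplicate_samples():
    with pytest.raises(TerraMotifError, match="duplicate"):
        build_abundance_matrix([_table("s", {A6: 1}), _table("s", {A6: 1})])


# -- correlation and selection ---------------------------------------------

def test_correlation_examples():
    canon = CANONICAL_CLASS.canonical
    m = _matrix(
        {
            canon: [0.1, 0.2, 0.4, 0.3],
            "AGGGGT": [0.2, 0.4, 0.8, 0.6],   # exactly 2x canonical -> r = 1
            "AAGGGT": [0.9, 0.8, 0.6, 0.7],   # c - canonical -> r = -1
            "AAAAAT": [0.5, 0.5, 0.5, 0.5],   # zero variance -> undefined
        },
        ["a", "b", "c", "d"],
    )
    rs = {c.motif.canonical: c.r for c in correlate_to_canonical(m)}
    assert rs[canon] == 1.0
    assert rs["AGGGGT"] == pytest.approx(1.0, abs=1e-12)
    assert rs["AAGGGT"] == pytest.approx(-1.0, abs=1e-12)
    assert math.isnan(rs["AAAAAT"])


def test_correlation_errors_when_canonical_absent():
    m = _matrix({"AGGGGT": [0.1, 0.2]}, ["a", "b"])
    with pytest.raises(TerraMotifError, match="canonical"):
        correlate_to_canonical(m)


@given(st.integers(0, 10_000))
def test_correlation_matches_scipy_pearsonr(seed):
    rng = np.random.default_rng(seed)
    n_motifs, n_samples = 6, 8
    data = rng.random((n_motifs, n_samples))
    names = [CANONICAL_CLASS.canonical, "AGGGGT", "AAGGGT", "AGGGTG", "AGGGTC", "ACGTAC"]
    m = _matrix({name: data[i] for i, name in enumerate(names)}, list("abcdefgh"))
    for c in correlate_to_canonical(m):
        if c.motif == CANONICAL_CLASS:
            continue
        expected = sps.pearsonr(data[names.index(c.motif.canonical)], data[0]).statistic
        assert c.r == pytest.approx(expected, abs=1e-12)


def test_select_top_motifs_rules():
    corrs = [
        MotifCorrelation(CANONICAL_CLASS, 1.0),
        MotifCorrelation(KmerClass("AGGGGT"), 0.9),
        MotifCorrelation(KmerClass("AAGGGT"), 0.9),
        MotifCorrelation(KmerClass("ACGTAC"), 0.5),
        MotifCorrelation(KmerClass("AAAAAT"), float("nan")),
    ]
    top = select_top_motifs(corrs, n=3)
    # canonical first; tie at 0.9 broken lexicographically
    assert top == [CANONICAL_CLASS, KmerClass("AAGGGT"), KmerClass("AGGGGT")]
    # undefined r never selected even when slots remain
    assert KmerClass("AAAAAT") not in select_top_motifs(corrs, n=10)
    # fewer motifs than n: all defined ones returned
    assert len(select_top_motifs(corrs, n=10)) == 4
    # invariant to input ordering
    assert select_top_motifs(list(reversed(corrs)), n=3) == top


# -- z-scores ---------------------------------------------------------------

def test_zscore_rows():
    m = _matrix(
        {CANONICAL_CLASS.canonical: [1.0, 2.0, 3.0], "AGGGGT": [0.4, 0.4, 0.4]},
        ["a", "b", "c"],
    )
    z = zscore_rows(m)
    assert np.allclose(z.loc[CANONICAL_CLASS.canonical], [-1.0, 0.0, 1.0])
    assert np.allclose(z.loc["AGGGGT"], 0.0)  # constant row -> zeros
    assert np.allclose(z.to_numpy().mean(axis=1), [0.0, 0.0], atol=1e-9)


def test_zscore_rejects_unknown_motif():
    m = _matrix({CANONICAL_CLASS.canonical: [1.0, 2.0]}, ["a", "b"])
    with pytest.raises(TerraMotifError):
        zscore_rows(m, [KmerClass("ACGTAC")])
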