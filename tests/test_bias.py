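"""Nearest-centroid expression-bias classification and its tabular workflow."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from homoeokit import (
    CATEGORIES,
    DEFAULT_CENTROIDS,
    ContractError,
    InputError,
    NearestCentroidBiasClassifier,
    aggregate_replicates,
    assign_bias,
    classify_triads,
    default_centroids,
    is_expressed,
    load_expression,
    normalize_triad,
    summarize_bias,
    ternary_xy,
    triad_tpm,
    xy_to_simplex,
)


def test_default_centroids_are_the_seven_ideal_points():
    cents = dict(default_centroids())
    assert list(cents) == list(CATEGORIES)
    assert cents["balanced"] == (1 / 3, 1 / 3, 1 / 3)
    assert cents["A_dominant"] == (1.0, 0.0, 0.0)
    assert cents["A_suppressed"] == (0.0, 0.5, 0.5)
    for point in cents.values():
        assert math.isclose(sum(point), 1.0)


@pytest.mark.parametrize(
    "p,expected",
    [
        ((1 / 3, 1 / 3, 1 / 3), "balanced"),
        ((0.8, 0.1, 0.1), "A_dominant"),
        ((0.45, 0.45, 0.10), "C_suppressed"),
        ((0.05, 0.5, 0.45), "A_suppressed"),
        ((0.0, 0.0, 1.0), "C_dominant"),
    ],
)
def test_assignment_worked_examples(p, expected):
    category, distances = assign_bias(p)
    assert category == expected
    # the winning distance is the global minimum recomputed by hand
    manual = {
        name: math.dist(p, point) for name, point in DEFAULT_CENTROIDS
    }
    assert distances == pytest.approx(manual)
    assert min(manual, key=manual.get) == expected


def test_balanced_point_has_zero_distance():
    _, distances = assign_bias((1 / 3, 1 / 3, 1 / 3))
    assert distances["balanced"] == pytest.approx(0.0, abs=1e-12)


def test_brute_force_oracle_agreement():
    """Vectorized assignment equals per-point brute-force minimization."""
    rng = np.random.default_rng(2024)
    P = rng.dirichlet(np.ones(3), size=20_000)
    clf = NearestCentroidBiasClassifier().fit()
    predicted = clf.predict(P)
    cents = default_centroids()
    for i in range(len(P)):
        best, best_d = None, np.inf
        for name, point in cents:
            d = math.dist(P[i], point)
            if d < best_d:  # strict: earlier centroid wins ties
                best, best_d = name, d
        assert predicted[i] == best


def test_tie_break_uses_centroid_order():
    # exact float tie between two custom centroids: the earlier one wins
    clf = NearestCentroidBiasClassifier(
        centroids=[("first", (1.0, 0.0, 0.0)), ("second", (0.0, 1.0, 0.0))]
    ).fit()
    assert clf.predict([(0.5, 0.5, 0.0)])[0] == "first"
    clf2 = NearestCentroidBiasClassifier(
        centroids=[("second", (0.0, 1.0, 0.0)), ("first", (1.0, 0.0, 0.0))]
    ).fit()
    assert clf2.predict([(0.5, 0.5, 0.0)])[0] == "second"


def test_label_permutation_equivariance():
    """Permuting the A/B/C axes permutes predicted categories consistently."""
    rng = np.random.default_rng(7)
    P = rng.dirichlet(np.ones(3), size=500)
    clf = NearestCentroidBiasClassifier().fit()
    base = clf.predict(P)
    subs = "ABC"
    for perm in ((1, 0, 2), (2, 1, 0), (0, 2, 1), (1, 2, 0), (2, 0, 1)):
        permuted = clf.predict(P[:, list(perm)])
        # axis j of the permuted input carries the original axis perm[j]
        rename = {subs[perm[j]]: subs[j] for j in range(3)}
        expected = [
            c if c == "balanced" else rename[c[0]] + c[1:] for c in base
        ]
        assert list(permuted) == expected


def test_off_simplex_input_rejected():
    clf = NearestCentroidBiasClassifier().fit()
    with pytest.raises(ContractError):
        clf.predict([(0.5, 0.4, 0.2)])
    with pytest.raises(ContractError):
        clf.predict([(1.2, -0.1, -0.1)])


def test_expression_threshold_is_strict():
    assert is_expressed(0.51)
    assert not is_expressed(0.5)
    assert not is_expressed(0.0)
    grid = np.linspace(0, 1.2, 241)
    assert np.array_equal(is_expressed(grid), grid > 0.5)


@given(st.lists(st.floats(0.01, 1e4), min_size=3, max_size=3))
def test_normalize_triad_sums_to_one(tpm):
    p = normalize_triad(tpm, threshold=0.0)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    assert ((0 <= p) & (p <= 1)).all()


def test_normalize_triad_examples_and_guard():
    assert normalize_triad((2, 1, 1)) == pytest.approx((0.5, 0.25, 0.25))
    assert normalize_triad((6, 0, 0)) == pytest.approx((1.0, 0.0, 0.0))
    with pytest.raises(ContractError):
        normalize_triad((0.1, 0.1, 0.1))  # total 0.3 <= 0.5


def test_load_expression_validates(tmp_path):
    good = tmp_path / "ok.tsv"
    good.write_text("gene_id\ts1\ts2\ng1\t1.0\t2.0\ng2\t0.0\t3.5\n")
    mat = load_expression(good)
    assert mat.loc["g2", "s2"] == 3.5
    bad = tmp_path / "neg.tsv"
    bad.write_text("gene_id\ts1\ng1\t-1.0\n")
    with pytest.raises(InputError, match="negative"):
        load_expression(bad)
    nn = tmp_path / "nn.tsv"
    nn.write_text("gene_id\ts1\ng1\tabc\n")
    with pytest.raises(InputError, match="non-numeric"):
        load_expression(nn)


def test_aggregate_replicates_matches_manual_mean():
    expr = pd.DataFrame(
        {"l1": [1.0, 4.0], "l2": [2.0, 5.0], "l3": [3.0, 6.0], "r1": [7.0, 8.0]},
        index=pd.Index(["g1", "g2"], name="gene_id"),
    )
    design = pd.DataFrame(
        {
            "sample_id": ["l1", "l2", "l3", "r1"],
            "tissue": ["leaf"] * 3 + ["root"],
            "replicate": [1, 2, 3, 1],
        }
    )
    agg = aggregate_replicates(expr, design)
    assert agg.loc["g1", "leaf"] == pytest.approx((1 + 2 + 3) / 3)
    assert agg.loc["g1", "root"] == 7.0  # single replicate is the identity
    med = aggregate_replicates(expr, design, stat="median")
    assert med.loc["g2", "leaf"] == 5.0
    with pytest.raises(InputError):
        aggregate_replicates(expr.drop(columns="r1"), design)


def _toy_triad_setup():
    triads = pd.DataFrame(
        {"triad_id": ["t1", "t2"], "gene_A": ["a1", "a2"],
         "gene_B": ["b1", "b2"], "gene_C": ["c1", "c2"]}
    )
    tissue = pd.DataFrame(
        {"leaf": [1.0, 2.0, 3.0, 0.1, 0.1, 0.1]},
        index=pd.Index(["a1", "b1", "c1", "a2", "b2", "c2"], name="gene_id"),
    )
    return triads, tissue


def test_triad_tpm_totals_and_missing_gene():
    triads, tissue = _toy_triad_setup()
    te = triad_tpm(triads, tissue)
    row = te[te["triad_id"] == "t1"].iloc[0]
    assert row["total"] == pytest.approx(6.0)
    assert row["total"] == pytest.approx(
        tissue.loc[["a1", "b1", "c1"], "leaf"].sum()
    )
    with pytest.raises(InputError, match="t1"):
        triad_tpm(triads, tissue.drop(index="a1"))


def test_classify_triads_filters_and_classifies():
    triads, tissue = _toy_triad_setup()
    out = classify_triads(triad_tpm(triads, tissue))
    t1 = out[out["triad_id"] == "t1"].iloc[0]
    t2 = out[out["triad_id"] == "t2"].iloc[0]
    assert t1["status"] == "expressed"
    assert t1["p_A"] == pytest.approx(1 / 6)
    assert t1["category"] == "balanced"
    assert t2["status"] == "not_expressed"  # total 0.3 <= 0.5
    assert t2["category"] == "" and np.isnan(t2["p_A"])


def test_summarize_bias_fractions():
    assignments = pd.DataFrame(
        {
            "tissue": ["leaf"] * 4 + ["root"],
            "status": ["expressed"] * 4 + ["not_expressed"],
            "category": ["balanced", "balanced", "A_dominant", "B_suppressed", ""],
        }
    )
    summary = summarize_bias(assignments)
    assert summary.pooled["balanced"] == pytest.approx(0.5)
    assert summary.pooled.sum() == pytest.approx(1.0, abs=1e-9)
    assert summary.grouped["dominant"] == pytest.approx(0.25)
    assert summary.grouped["suppressed"] == pytest.approx(0.25)
    assert summary.grouped.sum() == pytest.approx(1.0, abs=1e-9)
    assert summary.n_expressed["pooled"] == 4
    with pytest.raises(InputError):
        summarize_bias(assignments[assignments["status"] == "not_expressed"])


def test_ternary_vertices_and_roundtrip():
    assert ternary_xy((1, 0, 0)) == pytest.approx((0.0, 0.0))
    assert ternary_xy((0, 1, 0)) == pytest.approx((1.0, 0.0))
    assert ternary_xy((0, 0, 1)) == pytest.approx((0.5, math.sqrt(3) / 2))
    assert ternary_xy((1 / 3, 1 / 3, 1 / 3)) == pytest.approx((0.5, math.sqrt(3) / 6))
    rng = np.random.default_rng(99)
    P = rng.dirichlet(np.ones(3), size=1000)
    back = xy_to_simplex(ternary_xy(P))
    np.testing.assert_allclose(back, P, atol=1e-12)
    with pytest.raises(ContractError):
        ternary_xy((0.5, 0.5, 0.5))
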