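"""Fingerprints, PCA, PERMANOVA, LDA, ellipses and per-AA linear models."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aacsia.data import SampleMatrix
from aacsia.multivariate import (
    CorrelationPCA,
    LinearDiscriminant,
    Permanova,
    mean_normalize,
    sd_ellipse,
    two_factor_anova,
)


def _matrix(values, groups=None, element="C", aa_codes=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {"sample_id": sample_ids,
         "fraction": groups if groups is not None else ["host"] * n,
         "treatment": [None] * n}
    )
    return SampleMatrix(
        values=values,
        mask=np.zeros_like(values, dtype=bool),
        sample_ids=sample_ids,
        aa_codes=aa_codes or [f"A{j}" for j in range(p)],
        element=element,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# mean normalization
# ---------------------------------------------------------------------------

def test_mean_normalize_examples_and_idempotence():
    mat = _matrix([[-10, -20, -30], [-15, -15, -15]])
    fp = mean_normalize(mat)
    assert np.allclose(fp.values[0], [10, 0, -10])
    assert np.allclose(fp.values[1], [0, 0, 0])
    assert fp.normalized
    again = mean_normalize(fp)
    assert np.allclose(again.values, fp.values)


def test_mean_normalize_removes_per_sample_baseline(rng):
    """Fingerprints of x and x + c*1 are identical — the baseline-removal
    property that makes fingerprints comparable across sites."""
    X = rng.normal(-20, 3, size=(8, 6))
    shifts = rng.normal(0, 5, size=(8, 1))
    a = mean_normalize(_matrix(X))
    b = mean_normalize(_matrix(X + shifts))
    assert np.allclose(a.values, b.values, atol=1e-12)


def test_mean_normalize_rejects_masked_cells():
    mat = _matrix([[-10, -20, -30], [-15, -15, -15]])
    mat.mask[0, 1] = True
    with pytest.raises(ValueError, match="masked"):
        mean_normalize(mat)


# ---------------------------------------------------------------------------
# correlation PCA
# ---------------------------------------------------------------------------

def test_pca_rank_one_correlation():
    x = np.arange(10, dtype=float)
    mat = _matrix(np.column_stack([x, 2 * x + 1]))
    res = CorrelationPCA(mat).fit()
    assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_variance_fractions_and_reconstruction(rng):
    X = rng.normal(size=(12, 5))
    res = CorrelationPCA(_matrix(X)).fit()
    assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
    assert (res.variance_fraction >= 0).all()
    recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
    assert np.allclose(recon, res.scaled_data, atol=1e-8)


def test_pca_zero_variance_variable_named():
    X = np.column_stack([np.arange(6.0), np.full(6, 2.0)])
    with pytest.raises(ValueError, match="A1"):
        CorrelationPCA(_matrix(X)).fit()


def test_pca_correlation_vectors_flag_significance(rng):
    x = np.arange(20, dtype=float)
    noise = rng.normal(scale=30, size=20)
    mat = _matrix(np.column_stack([x, x + rng.normal(scale=0.1, size=20), noise]))
    res = CorrelationPCA(mat).fit()
    cv = res.correlation_vectors
    strong = cv[(cv["amino_acid"] == "A0") & (cv["component"] == "PC1")]
    assert bool(strong["significant"].iloc[0])
    assert set(cv.columns) >= {"amino_acid", "component", "r", "p", "significant"}


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def test_permanova_univariate_equals_classical_anova(rng):
    y = rng.normal(size=12) + np.repeat([0.0, 1.0], 6)
    groups = ["a"] * 6 + ["b"] * 6
    mat = _matrix(y[:, None], groups=groups)
    res = Permanova(mat, terms=["fraction"]).fit(n_perm=99, seed=0)
    f_classic = stats.f_oneway(y[:6], y[6:]).statistic
    assert res.table.loc[0, "pseudo_F"] == pytest.approx(f_classic, rel=1e-10)


def test_permanova_partition_exact_and_reorder_invariant(preset_dataset, rng):
    from aacsia.data import subset_matrix
    from aacsia.registry import MEASURED_13

    _, table, _ = preset_dataset
    mat = subset_matrix(table, "N", MEASURED_13, fractions=["host", "symbiont"])
    res = Permanova(
        mat, terms=["fraction", "treatment", "fraction:treatment"],
        transform="shift_nitrogen",
    ).fit(n_perm=49, seed=1)
    t = res.table.set_index("term")
    ss_sum = t.drop("Total")["SS"].sum()
    assert ss_sum == pytest.approx(t.loc["Total", "SS"], rel=1e-9)
    assert t.drop("Total")["R2"].sum() == pytest.approx(1.0, abs=1e-9)

    # reordering samples leaves the observed pseudo-F unchanged
    perm = rng.permutation(mat.shape[0])
    mat2 = SampleMatrix(
        values=mat.values[perm],
        mask=mat.mask[perm],
        sample_ids=[mat.sample_ids[i] for i in perm],
        aa_codes=mat.aa_codes,
        element=mat.element,
        metadata=mat.metadata,
    )
    res2 = Permanova(
        mat2, terms=["fraction", "treatment", "fraction:treatment"],
        transform="shift_nitrogen",
    ).fit(n_perm=49, seed=1)
    assert np.allclose(
        res.table["pseudo_F"].iloc[:3], res2.table["pseudo_F"].iloc[:3], rtol=1e-9
    )


def test_permanova_exact_enumeration_matches_brute_force(rng):
    """Full-permutation p-value equals an independent enumeration of the
    classical one-way ANOVA F over all 6! relabellings."""
    y = np.array([0.1, 0.9, 0.3, 2.2, 2.8, 2.0])
    groups = ["a", "a", "a", "b", "b", "b"]
    mat = _matrix(y[:, None], groups=groups)
    res = Permanova(mat, terms=["fraction"]).fit(n_perm="exact")

    f_obs = stats.f_oneway(y[:3], y[3:]).statistic
    count = total = 0
    for perm in itertools.permutations(range(6)):
        yp = y[list(perm)]
        f = stats.f_oneway(yp[:3], yp[3:]).statistic
        count += f >= f_obs - 1e-12
        total += 1
    assert res.table.loc[0, "p_perm"] == pytest.approx(count / total, abs=1e-12)


def test_permanova_nitrogen_shift_is_a_noop():
    """Euclidean distances are translation invariant, so the positive
    constant applied to nitrogen values cannot change any statistic."""
    rng = np.random.default_rng(5)
    X = rng.normal(5, 2, size=(10, 4))
    groups = ["a"] * 5 + ["b"] * 5
    r1 = Permanova(_matrix(X, groups), ["fraction"], transform="none").fit(99, seed=2)
    r2 = Permanova(_matrix(X, groups), ["fraction"], transform="shift_nitrogen").fit(99, seed=2)
    pd.testing.assert_frame_equal(r1.table, r2.table)


def test_permanova_abs_carbon_is_sign_flip_for_negative_data():
    rng = np.random.default_rng(6)
    X = -np.abs(rng.normal(20, 3, size=(8, 4)))  # all-negative d13C
    groups = ["a"] * 4 + ["b"] * 4
    r_abs = Permanova(_matrix(X, groups), ["fraction"], transform="abs_carbon").fit(49, seed=3)
    r_neg = Permanova(_matrix(-X, groups), ["fraction"], transform="none").fit(49, seed=3)
    pd.testing.assert_frame_equal(r_abs.table, r_neg.table)


def test_permanova_degenerate_and_singleton_errors():
    X = np.ones((6, 3))
    groups = ["a"] * 3 + ["b"] * 3
    with pytest.raises(ValueError, match="total sum of squares"):
        Permanova(_matrix(X, groups), ["fraction"]).fit(9, seed=0)
    with pytest.raises(ValueError, match="singleton"):
        Permanova(_matrix(np.random.default_rng(0).normal(size=(5, 3)),
                          ["a", "a", "a", "a", "b"]), ["fraction"])


def test_permanova_agrees_with_skbio_single_factor(rng):
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    X = rng.normal(size=(12, 5))
    X[6:] += 1.0
    groups = ["a"] * 6 + ["b"] * 6
    res = Permanova(_matrix(X, groups), ["fraction"]).fit(99, seed=4)
    dm = skbio_stats.DistanceMatrix(
        np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    )
    ref = skbio_stats.permanova(dm, grouping=groups, permutations=99)
    assert res.table.loc[0, "pseudo_F"] == pytest.approx(ref["test statistic"], rel=1e-6)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

def _two_class_data(rng, n=20, sep=10.0, p=2):
    a = rng.normal(0, 1, size=(n, p))
    b = rng.normal(0, 1, size=(n, p)) + sep
    X = np.vstack([a, b])
    y = ["a"] * n + ["b"] * n
    return X, y


def test_lda_two_classes_single_discriminant(rng):
    X, y = _two_class_data(rng)
    res = LinearDiscriminant(X, y).fit()
    assert res.scalings.shape[1] == 1
    assert res.proportion_of_trace[0] == pytest.approx(1.0)


def test_lda_scaling_convention_unit_within_variance(rng):
    """MASS convention: pooled within-class variance is 1 along each LD."""
    X, y = _two_class_data(rng, sep=4.0, p=3)
    res = LinearDiscriminant(X, y).fit()
    y_arr = np.asarray(y)
    W = np.zeros((3, 3))
    for c in ("a", "b"):
        Xc = X[y_arr == c] - X[y_arr == c].mean(axis=0)
        W += Xc.T @ Xc
    W /= len(X) - 2
    v = res.scalings.to_numpy()[:, 0]
    assert v @ W @ v == pytest.approx(1.0, rel=1e-8)


def test_lda_duplicated_column_singularity_error(rng):
    X, y = _two_class_data(rng)
    X = np.hstack([X, X[:, :1]])
    with pytest.raises(ValueError, match="singular"):
        LinearDiscriminant(X, y).fit()
    # explicit subspace tolerance solves it
    res = LinearDiscriminant(X, y, tol=1e-9).fit()
    assert res.scalings.shape[1] == 1


def test_lda_ridge_handles_singularity(rng):
    X, y = _two_class_data(rng)
    X = np.hstack([X, X[:, :1]])
    res = LinearDiscriminant(X, y, ridge=1e-6).fit()
    assert np.isfinite(res.scalings.to_numpy()).all()


def test_lda_class_with_one_member_rejected(rng):
    X = rng.normal(size=(5, 2))
    with pytest.raises(ValueError, match="< 2 samples"):
        LinearDiscriminant(X, ["a", "a", "a", "a", "b"]).fit()


def test_lda_posteriors_normalize_and_nearest_mean(rng):
    X, y = _two_class_data(rng, sep=5.0)
    res = LinearDiscriminant(X, y, priors="uniform").fit()
    pred = res.predict(res.class_means.to_numpy())
    post = pred[["a", "b"]].to_numpy()
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)
    assert list(pred["predicted"]) == ["a", "b"]
    assert post[0, 0] > 0.5 and post[1, 1] > 0.5


def test_lda_loocv_perfect_separation(rng):
    X, y = _two_class_data(rng, n=20, sep=10.0)
    cv = LinearDiscriminant(X, y).loocv()
    assert cv["overall"] == 1.0
    assert (cv["per_class"] == 1.0).all()


def test_lda_loocv_permuted_labels_near_chance(rng):
    X, y = _two_class_data(rng, n=20, sep=10.0)
    y_perm = list(rng.permutation(y))
    cv = LinearDiscriminant(X, y_perm).loocv()
    # binomial reference: chance is 0.5; 40 trials, keep generous bounds
    assert 0.15 <= cv["overall"] <= 0.8


def test_lda_matches_sklearn_predictions(rng):
    sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
    X, y = _two_class_data(rng, sep=2.0, p=3)
    res = LinearDiscriminant(X, y).fit()
    Xnew = rng.normal(1.0, 2.0, size=(30, 3))
    ours = res.predict(Xnew)["predicted"].to_numpy()
    ref = sklearn_da.LinearDiscriminantAnalysis().fit(X, y).predict(Xnew)
    assert (ours == ref).all()


def test_lda_predict_panel_mismatch_lists_missing(preset_dataset):
    from aacsia.data import subset_matrix
    from aacsia.registry import EAA5_PANEL, EAA6_PANEL

    _, table, _ = preset_dataset
    train = mean_normalize(
        subset_matrix(table, "C", EAA6_PANEL, fractions=["symbiont", "plankton"])
    )
    res = LinearDiscriminant(train).fit()
    hosts5 = mean_normalize(subset_matrix(table, "C", EAA5_PANEL, fractions=["host"]))
    with pytest.raises(ValueError, match="Lys"):
        res.predict(hosts5)


# ---------------------------------------------------------------------------
# ellipses
# ---------------------------------------------------------------------------

def test_ellipse_isotropic_cloud_near_circular(rng):
    pts = rng.normal(size=(4000, 2))
    ell = sd_ellipse(pts, level=0.90)
    assert ell.semi_axes[0] == pytest.approx(ell.semi_axes[1], rel=0.1)


def test_ellipse_collapses_as_level_vanishes(rng):
    pts = rng.normal(size=(50, 2))
    big = sd_ellipse(pts, level=0.9)
    tiny = sd_ellipse(pts, level=1e-6)
    assert tiny.semi_axes[0] < 1e-2 * big.semi_axes[0]
    assert tiny.center == big.center


def test_ellipse_monte_carlo_coverage(rng):
    pts = rng.multivariate_normal([0, 0], [[2.0, 0.7], [0.7, 1.0]], size=10**5)
    ell = sd_ellipse(pts, level=0.90)
    c, s = math.cos(ell.angle), math.sin(ell.angle)
    R = np.array([[c, s], [-s, c]])
    local = (pts - np.asarray(ell.center)) @ R.T
    inside = (local[:, 0] / ell.semi_axes[0]) ** 2 + (
        local[:, 1] / ell.semi_axes[1]
    ) ** 2 <= 1.0
    assert inside.mean() == pytest.approx(0.90, abs=0.01)


def test_ellipse_input_validation(rng):
    with pytest.raises(ValueError, match=">= 3"):
        sd_ellipse(np.zeros((2, 2)))
    with pytest.raises(ValueError, match="level"):
        sd_ellipse(rng.normal(size=(5, 2)), level=1.5)
    degen = np.column_stack([np.arange(5.0), np.arange(5.0)])
    assert sd_ellipse(degen).degenerate


# ---------------------------------------------------------------------------
# two-factor linear models
# ---------------------------------------------------------------------------

def test_two_factor_anova_null_configuration():
    """Equal cell means in a balanced design give F = 0, p = 1."""
    fraction = ["host", "host", "symbiont", "symbiont"] * 3
    treatment = sum(([t] * 4 for t in ["L-NF", "L-F", "D-F"]), [])
    values = [1.0, 2.0, 1.0, 2.0] * 3
    res = two_factor_anova(values, fraction, treatment)
    f_vals = res.anova_table["F"].dropna()
    p_vals = res.anova_table["PR(>F)"].dropna()
    assert (f_vals < 1e-10).all()
    assert (p_vals > 0.999).all()


def test_two_factor_anova_detects_strong_treatment_effect(rng):
    fraction = ["host", "symbiont"] * 9
    treatment = sum(([t] * 6 for t in ["L-NF", "L-F", "D-F"]), [])
    effect = {"L-NF": 0.0, "L-F": 0.0, "D-F": 3.0}
    values = rng.normal(0, 0.3, 18) + np.array([effect[t] for t in treatment])
    res = two_factor_anova(values, fraction, treatment)
    p_treat = res.anova_table.loc["C(treatment)", "PR(>F)"]
    assert p_treat < 0.001
    tk = res.tukey_treatment
    row = tk[(tk["group1"] == "D-F") & (tk["group2"] == "L-F")]
    assert bool(row["reject"].iloc[0])


def test_two_factor_anova_type_i_error_calibration():
    """Under the null, rejection rate at alpha = 0.05 is about 5%."""
    rng = np.random.default_rng(77)
    fraction = ["host", "symbiont"] * 6
    treatment = sum(([t] * 4 for t in ["L-NF", "L-F", "D-F"]), [])
    rejections = 0
    n_rep = 400
    for _ in range(n_rep):
        values = rng.normal(size=12)
        res = two_factor_anova(values, fraction, treatment, tukey=False)
        rejections += res.anova_table.loc["C(treatment)", "PR(>F)"] < 0.05
    assert 0.02 <= rejections / n_rep <= 0.08


def test_two_factor_anova_saturated_design_rejected():
    with pytest.raises(ValueError, match="saturated"):
        two_factor_anova([1.0, 2.0, 3.0], ["h", "s", "h"], ["a", "b", "c"])
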