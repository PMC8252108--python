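"""Multivariate machinery for amino-acid isotope fingerprints.

The estimators follow a Model/Results layout: construct the model from a
:class:`~aacsia.data.SampleMatrix` (or plain array) plus grouping
information, call ``fit()``, and read estimates, diagnostics and a
``summary()`` table off the returned results object.

* :class:`Permanova` — permutational multivariate ANOVA on Euclidean
  distances.  The Gower-centered distance matrix is partitioned by
  sequential (Type I) hat-matrix projections over the model terms
  (McArdle-Anderson), giving exact sums of squares; significance comes
  from free permutation of observations.
* :class:`CorrelationPCA` — principal components of the scaled, centered
  correlation matrix, with per-variable correlation vectors against the
  leading components.
* :class:`LinearDiscriminant` — Fisher discriminants with the classical
  R/MASS scaling convention (pooled within-class variance is unit along
  each discriminant), leave-one-out cross-validation, and Gaussian
  equal-covariance posterior prediction.

:func:`mean_normalize` produces the "isotope fingerprint": subtracting
each sample's own mean removes per-sample baseline isotope variation so
that only the *pattern* across amino acids remains.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import SampleMatrix

__all__ = [
    "FingerprintMatrix",
    "mean_normalize",
    "CorrelationPCA",
    "OrdinationResults",
    "Permanova",
    "PermanovaResults",
    "LinearDiscriminant",
    "LdaResults",
    "EllipseParams",
    "sd_ellipse",
    "two_factor_anova",
    "AnovaResult",
]


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

@dataclass
class FingerprintMatrix(SampleMatrix):
    """A :class:`SampleMatrix` carrying a mean-normalization flag and panel."""

    normalized: bool = False
    panel: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.panel:
            self.panel = list(self.aa_codes)
        if self.normalized:
            resid = np.abs(self.values.sum(axis=1))
            if resid.max() > 1e-9:
                raise ValueError("normalized rows must sum to 0 within 1e-9")


def mean_normalize(matrix: SampleMatrix) -> FingerprintMatrix:
    """Subtract each sample's own mean across the panel.

    Idempotent, and invariant to adding a per-sample constant to all
    amino acids — the baseline-removal property that makes fingerprints
    comparable across locations and times.
    """
    if matrix.mask.any():
        bad = [matrix.aa_codes[j] for j in np.unique(np.where(matrix.mask)[1])]
        raise ValueError(f"cannot normalize with masked cells in panel: {bad}")
    centered = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    return FingerprintMatrix(
        values=centered,
        mask=matrix.mask.copy(),
        sample_ids=list(matrix.sample_ids),
        aa_codes=list(matrix.aa_codes),
        element=matrix.element,
        metadata=matrix.metadata.copy(),
        normalized=True,
        panel=list(matrix.aa_codes),
    )


# ---------------------------------------------------------------------------
# PCA of the correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResults:
    """Scores, loadings and variance decomposition of a correlation PCA."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray
    eigenvalues: np.ndarray
    correlation_vectors: pd.DataFrame
    scaled_data: np.ndarray

    def summary(self) -> str:
        lines = ["Correlation-matrix PCA", "=" * 30]
        for i, vf in enumerate(self.variance_fraction[:4], start=1):
            lines.append(f"PC{i}: {vf:6.1%} of variance")
        k = min(2, len(self.variance_fraction))
        lines.append(f"first {k} PCs: {self.variance_fraction[:k].sum():.1%}")
        return "\n".join(lines)


class CorrelationPCA:
    """PCA of the scaled and centered correlation matrix of a sample matrix."""

    def __init__(self, matrix: SampleMatrix):
        if matrix.mask.any():
            raise ValueError("PCA requires a complete matrix (no masked cells)")
        if matrix.shape[0] < 2 or matrix.shape[1] < 2:
            raise ValueError("PCA requires >= 2 samples and >= 2 variables")
        self.matrix = matrix

    def fit(self, alpha: float = 0.05) -> OrdinationResults:
        X = self.matrix.values
        n, p = X.shape
        sd = X.std(axis=0, ddof=1)
        zero = [self.matrix.aa_codes[j] for j in np.where(sd == 0)[0]]
        if zero:
            raise ValueError(f"zero-variance variable(s): {zero}")
        Z = (X - X.mean(axis=0)) / sd
        R = np.corrcoef(Z, rowvar=False)
        evals, evecs = np.linalg.eigh(R)
        order = np.argsort(evals)[::-1]
        evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
        # deterministic sign: largest-magnitude loading positive
        for j in range(evecs.shape[1]):
            k = np.argmax(np.abs(evecs[:, j]))
            if evecs[k, j] < 0:
                evecs[:, j] *= -1
        n_comp = min(n - 1, p)
        pcs = [f"PC{i+1}" for i in range(p)]
        scores = Z @ evecs
        var_frac = evals / evals.sum()

        # Pearson correlation of each variable with the first two PCs
        rows = []
        for j, aa in enumerate(self.matrix.aa_codes):
            for c in range(min(2, n_comp)):
                r, pval = stats.pearsonr(X[:, j], scores[:, c])
                rows.append(
                    {"amino_acid": aa, "component": pcs[c], "r": r,
                     "p": pval, "significant": bool(pval < alpha)}
                )
        return OrdinationResults(
            scores=pd.DataFrame(scores, index=self.matrix.sample_ids, columns=pcs),
            loadings=pd.DataFrame(evecs, index=self.matrix.aa_codes, columns=pcs),
            variance_fraction=var_frac,
            eigenvalues=evals,
            correlation_vectors=pd.DataFrame(rows),
            scaled_data=Z,
        )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _transform(values: np.ndarray, transform: str) -> np.ndarray:
    """Pre-distance transform: absolute values for carbon (all-negative
    d13C in practice, so this mirrors the data), a positive constant
    shift for nitrogen (a no-op for Euclidean distances), or none."""
    if transform == "abs_carbon":
        return np.abs(values)
    if transform == "shift_nitrogen":
        return values - values.min() + 1.0
    if transform == "none":
        return values
    raise ValueError(f"unknown transform {transform!r}")


def _dummy_columns(series: pd.Series) -> np.ndarray:
    levels = sorted(pd.unique(series.astype(str)))
    return np.column_stack([(series.astype(str) == lv).to_numpy(float) for lv in levels[1:]])


def _term_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    parts = term.split(":")
    mats = [_dummy_columns(design[p]) for p in parts]
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(len(design), -1)
    return out


@dataclass
class PermanovaResults:
    """Sequential SS partition with pseudo-F and permutation p-values."""

    table: pd.DataFrame
    n_permutations: int | str
    seed: int | None
    transform: str

    def summary(self) -> str:
        lines = [
            f"PERMANOVA (Euclidean distance, transform={self.transform}, "
            f"permutations={self.n_permutations}, seed={self.seed})",
            self.table.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class Permanova:
    """Permutational MANOVA on Euclidean distances of a sample matrix.

    Parameters
    ----------
    matrix
        Complete sample matrix; rows are observations.
    design
        Frame of factor columns aligned to matrix rows (defaults to the
        matrix metadata in row order).
    terms
        Sequential model terms, e.g. ``["fraction", "treatment",
        "fraction:treatment"]``.  Interactions use ``:``.
    transform
        ``abs_carbon``, ``shift_nitrogen`` or ``none``.
    """

    def __init__(
        self,
        matrix: SampleMatrix,
        terms: Sequence[str],
        design: pd.DataFrame | None = None,
        transform: str = "none",
    ):
        if matrix.mask.any():
            raise ValueError("PERMANOVA requires a complete matrix")
        if design is None:
            meta = matrix.metadata.set_index("sample_id")
            cols = sorted({p for t in terms for p in t.split(":")})
            design = meta.loc[matrix.sample_ids, cols].reset_index(drop=True)
        if len(design) != matrix.shape[0]:
            raise ValueError("design length does not match sample count")
        for t in terms:
            for p in t.split(":"):
                counts = design[p].value_counts()
                if (counts < 2).any():
                    bad = counts[counts < 2].index.tolist()
                    raise ValueError(f"factor {p!r} has singleton level(s): {bad}")
        self.matrix = matrix
        self.design = design.reset_index(drop=True)
        self.terms = list(terms)
        self.transform = transform

    def _gower(self) -> np.ndarray:
        Y = _transform(self.matrix.values, self.transform)
        sq = (Y**2).sum(axis=1)
        D2 = sq[:, None] + sq[None, :] - 2.0 * Y @ Y.T
        np.clip(D2, 0.0, None, out=D2)
        A = -0.5 * D2
        n = len(A)
        J = np.eye(n) - np.ones((n, n)) / n
        return J @ A @ J

    def _hats(self) -> tuple[list[np.ndarray], list[int]]:
        """Cumulative hat matrices and term df under sequential fitting."""
        n = self.matrix.shape[0]
        X = np.ones((n, 1))
        hats, dfs = [], []
        prev_rank = 1
        for term in self.terms:
            X = np.hstack([X, _term_columns(self.design, term)])
            rank = np.linalg.matrix_rank(X)
            H = X @ np.linalg.pinv(X)
            hats.append(H)
            dfs.append(rank - prev_rank)
            prev_rank = rank
        return hats, dfs

    def fit(
        self,
        n_perm: int | str = 999,
        seed: int | None = None,
    ) -> PermanovaResults:
        """Partition the distance matrix and compute permutation p-values.

        ``n_perm="exact"`` enumerates all n! row permutations (n <= 8)
        and reports ``p = #{F_perm >= F_obs} / n!``; otherwise ``n_perm``
        random permutations give ``p = (#{F_perm >= F_obs} + 1) /
        (n_perm + 1)``.
        """
        G = self._gower()
        n = len(G)
        ss_total = float(np.trace(G))
        if ss_total <= 1e-12:
            raise ValueError("degenerate input: total sum of squares is zero")
        hats, dfs = self._hats()
        H_full = hats[-1]
        rank_full = int(round(np.trace(H_full)))
        df_res = n - rank_full
        if df_res <= 0:
            raise ValueError("model is saturated: zero residual degrees of freedom")
        if any(d == 0 for d in dfs):
            bad = [t for t, d in zip(self.terms, dfs) if d == 0]
            raise ValueError(f"term(s) with zero degrees of freedom: {bad}")

        def partition(Gp: np.ndarray) -> tuple[np.ndarray, float]:
            cum = np.array([float(np.sum(H * Gp)) for H in hats])
            ss_terms = np.diff(np.concatenate([[0.0], cum]))
            ss_res = float(np.trace(Gp)) - cum[-1]
            return ss_terms, ss_res

        ss_terms, ss_res = partition(G)
        ms_res = ss_res / df_res
        f_obs = (ss_terms / np.asarray(dfs)) / ms_res

        if n_perm == "exact":
            if n > 8:
                raise ValueError("exact enumeration limited to n <= 8 samples")
            count = np.zeros(len(self.terms))
            total = 0
            for perm in itertools.permutations(range(n)):
                idx = np.asarray(perm)
                Gp = G[np.ix_(idx, idx)]
                ss_t, ss_r = partition(Gp)
                f_p = (ss_t / np.asarray(dfs)) / (ss_r / df_res)
                count += f_p >= f_obs - 1e-12
                total += 1
            pvals = count / total
            n_perm_out: int | str = "exact"
        else:
            rng = np.random.default_rng(seed)
            count = np.zeros(len(self.terms))
            for _ in range(int(n_perm)):
                idx = rng.permutation(n)
                Gp = G[np.ix_(idx, idx)]
                ss_t, ss_r = partition(Gp)
                f_p = (ss_t / np.asarray(dfs)) / (ss_r / df_res)
                count += f_p >= f_obs - 1e-12
            pvals = (count + 1.0) / (int(n_perm) + 1.0)
            n_perm_out = int(n_perm)

        rows = []
        for t, d, ss, f, p in zip(self.terms, dfs, ss_terms, f_obs, pvals):
            rows.append({"term": t, "df": d, "SS": ss, "R2": ss / ss_total,
                         "pseudo_F": f, "p_perm": p})
        rows.append({"term": "Residual", "df": df_res, "SS": ss_res,
                     "R2": ss_res / ss_total, "pseudo_F": np.nan, "p_perm": np.nan})
        rows.append({"term": "Total", "df": n - 1, "SS": ss_total,
                     "R2": 1.0, "pseudo_F": np.nan, "p_perm": np.nan})
        return PermanovaResults(
            table=pd.DataFrame(rows),
            n_permutations=n_perm_out,
            seed=seed,
            transform=self.transform,
        )


# ---------------------------------------------------------------------------
# Linear discriminant analysis
# ---------------------------------------------------------------------------

@dataclass
class LdaResults:
    """Fitted discriminant model (MASS scaling convention)."""

    classes: list[str]
    priors: pd.Series
    class_means: pd.DataFrame          # classes x variables, original space
    scalings: pd.DataFrame             # variables x discriminants
    proportion_of_trace: np.ndarray
    pooled_cov: np.ndarray
    variables: list[str]
    _model: "LinearDiscriminant" = field(repr=False, default=None)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project observations onto the discriminant axes."""
        grand = (self.priors.to_numpy()[:, None] * self.class_means.to_numpy()).sum(axis=0)
        return (np.asarray(X, float) - grand) @ self.scalings.to_numpy()

    def predict(self, matrix: "SampleMatrix | np.ndarray",
                coarse_groups: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Gaussian equal-covariance posteriors and hard labels.

        ``coarse_groups`` optionally maps fine class labels to coarse
        nutrition groups (e.g. symbiont -> autotrophy, plankton/POM ->
        heterotrophy); the mapped label is added as ``coarse_group``.
        """
        if isinstance(matrix, SampleMatrix):
            missing = [v for v in self.variables if v not in matrix.aa_codes]
            if missing:
                raise ValueError(f"panel mismatch; model variables missing: {missing}")
            idx = [matrix.aa_codes.index(v) for v in self.variables]
            X = matrix.values[:, idx]
            index = list(matrix.sample_ids)
        else:
            X = np.asarray(matrix, dtype=float)
            if X.shape[1] != len(self.variables):
                raise ValueError(
                    f"expected {len(self.variables)} variables, got {X.shape[1]}"
                )
            index = list(range(len(X)))
        Sigma_inv = np.linalg.pinv(self.pooled_cov)
        M = self.class_means.to_numpy()
        disc = X @ Sigma_inv @ M.T - 0.5 * np.einsum(
            "kj,jl,kl->k", M, Sigma_inv, M
        ) + np.log(self.priors.to_numpy())
        disc -= disc.max(axis=1, keepdims=True)
        post = np.exp(disc)
        post /= post.sum(axis=1, keepdims=True)
        out = pd.DataFrame(post, index=index, columns=self.classes)
        out.insert(0, "predicted", [self.classes[k] for k in post.argmax(axis=1)])
        if coarse_groups is not None:
            out["coarse_group"] = [coarse_groups.get(c, c) for c in out["predicted"]]
        return out

    def summary(self) -> str:
        lines = ["Linear discriminant analysis", "=" * 32,
                 f"classes: {self.classes}",
                 "priors: " + ", ".join(f"{c}={p:.3f}" for c, p in self.priors.items())]
        for i, pot in enumerate(self.proportion_of_trace, start=1):
            lines.append(f"LD{i} proportion of trace: {pot:.4f}")
        lines.append("scalings:")
        lines.append(self.scalings.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


class LinearDiscriminant:
    """Fisher linear discriminants of a labelled fingerprint matrix.

    Scalings solve the generalized eigenproblem ``B v = l W v`` with
    ``W`` the pooled (unbiased) within-class covariance and ``B`` the
    between-class covariance, normalized so within-class variance is
    unit along each discriminant — the classical R/MASS convention.
    Directions are defined only up to sign.
    """

    def __init__(
        self,
        matrix: SampleMatrix | np.ndarray,
        labels: Sequence[str] | None = None,
        priors: str | Mapping[str, float] = "proportional",
        ridge: float = 0.0,
        tol: float | None = None,
    ):
        if isinstance(matrix, SampleMatrix):
            if matrix.mask.any():
                raise ValueError("LDA requires a complete matrix")
            X = matrix.values
            self.variables = list(matrix.aa_codes)
            if labels is None:
                labels = matrix.groups("fraction").tolist()
        else:
            X = np.asarray(matrix, dtype=float)
            self.variables = [f"x{j}" for j in range(X.shape[1])]
            if labels is None:
                raise ValueError("labels required for a plain array")
        self.X = X
        self.labels = np.asarray([str(l) for l in labels])
        if len(self.labels) != len(X):
            raise ValueError("labels length does not match sample count")
        self.priors = priors
        self.ridge = float(ridge)
        # Mean-normalized fingerprints carry an exact sum-to-zero
        # constraint per row, so their pooled covariance is singular by
        # construction; solve in the non-null eigen-subspace.
        if tol is None and isinstance(matrix, FingerprintMatrix) and matrix.normalized:
            tol = 1e-9
        self.tol = tol

    def fit(self) -> LdaResults:
        X, y = self.X, self.labels
        classes = sorted(pd.unique(y))
        if len(classes) < 2:
            raise ValueError("LDA needs >= 2 classes")
        n, p = X.shape
        counts = {c: int((y == c).sum()) for c in classes}
        small = [c for c, k in counts.items() if k < 2]
        if small:
            raise ValueError(f"class(es) with < 2 samples: {small}")

        means = np.vstack([X[y == c].mean(axis=0) for c in classes])
        W = np.zeros((p, p))
        for c, m in zip(classes, means):
            Xc = X[y == c] - m
            W += Xc.T @ Xc
        W /= n - len(classes)
        if self.ridge > 0:
            W = W + self.ridge * np.trace(W) / p * np.eye(p)

        nk = np.array([counts[c] for c in classes], dtype=float)
        grand = (nk[:, None] * means).sum(axis=0) / n
        B = (nk[:, None, None] * np.einsum(
            "kj,kl->kjl", means - grand, means - grand
        )).sum(axis=0) / (len(classes) - 1)

        # whitening-based generalized eigensolve: W = U S U', project onto
        # the subspace where S is numerically nonzero, then eigh there.
        S, U = np.linalg.eigh(W)
        smax = float(S.max()) if S.size else 0.0
        if smax <= 0:
            raise ValueError("pooled within-class covariance is zero")
        rank_tol = max(self.tol or 0.0, 1e-14) * smax
        keep = S > rank_tol
        if not keep.all() and self.tol is None:
            raise ValueError(
                "singular pooled within-class covariance (collinear variables); "
                "pass a ridge or an explicit tol to solve in the reduced subspace"
            )
        T = U[:, keep] / np.sqrt(S[keep])  # p x r whitener: T' W T = I
        Bt = T.T @ B @ T
        evals_r, a = np.linalg.eigh(Bt)
        order = np.argsort(evals_r)[::-1]
        d = min(len(classes) - 1, int(keep.sum()))
        evals = np.clip(evals_r[order][:d], 0.0, None)
        evecs = T @ a[:, order][:, :d]
        for j in range(d):
            k = np.argmax(np.abs(evecs[:, j]))
            if evecs[k, j] < 0:
                evecs[:, j] *= -1
        pot = evals / evals.sum() if evals.sum() > 0 else np.full(d, 1.0 / d)

        if self.priors == "proportional":
            pri = pd.Series({c: counts[c] / n for c in classes})
        elif self.priors == "uniform":
            pri = pd.Series({c: 1.0 / len(classes) for c in classes})
        else:
            pri = pd.Series({c: float(self.priors[c]) for c in classes})
            pri /= pri.sum()

        return LdaResults(
            classes=classes,
            priors=pri,
            class_means=pd.DataFrame(means, index=classes, columns=self.variables),
            scalings=pd.DataFrame(
                evecs, index=self.variables,
                columns=[f"LD{i+1}" for i in range(d)],
            ),
            proportion_of_trace=pot,
            pooled_cov=W,
            variables=list(self.variables),
            _model=self,
        )

    def loocv(self) -> dict:
        """Leave-one-out cross-validated classification.

        Returns a dict with ``confusion`` (true x predicted counts),
        ``per_class`` success rates and the ``overall`` rate.
        """
        n = len(self.X)
        preds = []
        for i in range(n):
            keep = np.arange(n) != i
            y_train = self.labels[keep]
            if len(pd.unique(y_train)) < len(pd.unique(self.labels)):
                raise ValueError(f"fold {i}: a class vanishes from the training set")
            sub = LinearDiscriminant(
                self.X[keep], y_train, priors=self.priors, ridge=self.ridge,
                tol=self.tol,
            )
            res = sub.fit()
            preds.append(res.predict(self.X[i : i + 1])["predicted"].iloc[0])
        preds = np.asarray(preds)
        classes = sorted(pd.unique(self.labels))
        confusion = pd.crosstab(
            pd.Series(self.labels, name="true"),
            pd.Series(preds, name="predicted"),
        ).reindex(index=classes, columns=classes, fill_value=0)
        per_class = pd.Series(
            {c: confusion.loc[c, c] / confusion.loc[c].sum() for c in classes}
        )
        overall = float(np.mean(preds == self.labels))
        return {"confusion": confusion, "per_class": per_class, "overall": overall}


# ---------------------------------------------------------------------------
# SD / confidence ellipses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipseParams:
    """Data ellipse of a 2-D point cloud at a chi-square(2) coverage level."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float  # radians, orientation of the major axis
    level: float
    degenerate: bool = False


def sd_ellipse(points: np.ndarray, level: float = 0.90) -> EllipseParams:
    """Covariance ellipse of one group's 2-D ordination scores.

    Semi-axes are ``sqrt(eigenvalue * chi2.ppf(level, 2))`` along the
    covariance eigenvectors, so a bivariate-normal cloud falls inside
    the ellipse with probability ``level``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 3:
        raise ValueError("need >= 3 points for a covariance ellipse")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    r = math.sqrt(stats.chi2.ppf(level, df=2))
    semi = np.sqrt(evals)[::-1] * r  # major first
    major = evecs[:, -1]
    angle = math.atan2(major[1], major[0])
    return EllipseParams(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        angle=float(angle),
        level=float(level),
        degenerate=bool(evals.min() <= 1e-15),
    )


# ---------------------------------------------------------------------------
# per-AA two-factor linear models
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Two-factor fixed-effects ANOVA with Tukey HSD treatment contrasts."""

    anova_table: pd.DataFrame
    tukey_treatment: pd.DataFrame | None

    def summary(self) -> str:
        parts = [self.anova_table.to_string(float_format=lambda v: f"{v:.4f}")]
        if self.tukey_treatment is not None:
            parts += ["", "Tukey HSD (treatment):", self.tukey_treatment.to_string()]
        return "\n".join(parts)


def two_factor_anova(
    values: Sequence[float],
    fraction: Sequence[str],
    treatment: Sequence[str],
    tukey: bool = True,
) -> AnovaResult:
    """Fixed-effects linear model ``value ~ fraction + treatment``.

    No interaction term (matching the reported per-AA model structure);
    pairwise treatment contrasts by Tukey HSD.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame(
        {"value": np.asarray(values, float),
         "fraction": list(fraction), "treatment": list(treatment)}
    )
    n_params = 1 + (df["fraction"].nunique() - 1) + (df["treatment"].nunique() - 1)
    if len(df) - n_params < 1:
        raise ValueError("saturated design: no residual degrees of freedom")
    model = smf.ols("value ~ C(fraction) + C(treatment)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    tukey_df = None
    if tukey and df["treatment"].nunique() >= 2:
        res = pairwise_tukeyhsd(df["value"], df["treatment"])
        tukey_df = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return AnovaResult(anova_table=table, tukey_treatment=tukey_df)
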