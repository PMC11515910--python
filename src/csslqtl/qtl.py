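"""Joint multi-locus additive/dominance QTL mapping with LRT LOD scores.

The model for a quantitative trait measured on ``n`` introgression lines
genotyped at ``m`` segment markers is

    y_i = mu + sum_j w_ij a_j + sum_j v_ij d_j + e_i

where ``a_j`` and ``d_j`` are the additive and dominance effects of marker
``j`` and the indicator coding is ``w = 1/0/-1`` and ``v = 0/1/0`` for the
donor-homozygous (AA), heterozygous (Aa) and recipient-homozygous (aa)
classes.  All ``2m`` effects are estimated jointly by minimising

    (1/2n) * sum_i (y_i - mu - W a - V d)_i^2  +  lambda * sum_j (|a_j| + |d_j|)

(the intercept is never penalised).  Each marker with a non-zero estimated
effect is then scored with a likelihood-ratio test on its *conditional
residual* — the phenotype with every fitted term removed except the one
under test — comparing a single normal distribution against per-genotype-
class means with a pooled variance.  The LOD score has the closed form
``(n/2) * log10(sigma0^2 / sigma^2)`` with maximum-likelihood (1/n) variance
estimates; significance defaults to LOD >= 2.5 for phenotypic QTLs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_is_fitted

# genotype codes used throughout the package
AA = 2   # donor homozygote
Aa = 1   # heterozygote
aa = 0   # recipient homozygote

__all__ = [
    "AA", "Aa", "aa",
    "DesignMatrices", "LassoConfig", "LRTResult",
    "MultiLocusQTLMapper",
    "encode_design", "fit_multilocus", "conditional_residual", "lod_score",
    "scan_trait",
]


@dataclass
class DesignMatrices:
    """Additive (W) and dominance (V) indicator matrices for one population."""

    W: np.ndarray
    V: np.ndarray

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def m(self) -> int:
        return self.W.shape[1]


@dataclass
class LassoConfig:
    """Settings of the penalized fit.

    ``lambda_`` may be a nonnegative float or ``"auto"`` (k-fold
    cross-validated lambda at minimum CV error).  ``standardize`` reproduces
    glmnet's default: predictors are scaled to unit variance before
    penalization and coefficients are reported on the original scale.
    """

    lambda_: float | str = "auto"
    cv_folds: int = 10
    standardize: bool = True
    seed: int | None = None
    n_alphas: int = 100
    alpha_min_ratio: float = 0.01
    tol: float = 1e-4
    max_iter: int = 5000


@dataclass
class LRTResult:
    """One likelihood-ratio LOD test at one marker."""

    marker: int
    effect_kind: str                 # "additive" or "dominance"
    y_cond: np.ndarray
    n1: int                          # AA lines
    n2: int                          # Aa lines
    n3: int                          # aa lines
    mu0: float
    sigma0_sq: float
    class_means: dict = field(default_factory=dict)
    sigma_sq: float = np.nan
    L0: float = np.nan
    LA: float = np.nan
    lod: float = 0.0
    flag: str | None = None          # "single_class", "separable", "no_heterozygotes"


def encode_design(genotypes) -> DesignMatrices:
    """Translate {0,1,2} (aa/Aa/AA) genotype codes into W, V indicators.

    NaN entries propagate as NaN in both matrices; any other value raises.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (lines x markers)")
    valid = np.isnan(G) | np.isin(G, (0.0, 1.0, 2.0))
    if not valid.all():
        bad = np.argwhere(~valid)[0]
        raise ValueError(
            f"unknown genotype code {G[tuple(bad)]!r} at line {bad[0]}, "
            f"marker {bad[1]}; expected 0 (aa), 1 (Aa), 2 (AA) or NaN"
        )
    W = np.where(G == AA, 1.0, np.where(G == aa, -1.0, 0.0))
    V = np.where(G == Aa, 1.0, 0.0)
    nan = np.isnan(G)
    W[nan] = np.nan
    V[nan] = np.nan
    return DesignMatrices(W=W, V=V)


def _loglik_normal(x: np.ndarray, mu: float, sigma_sq: float) -> float:
    """Sum of natural-log normal densities; used in the LRT."""
    n = x.size
    return -0.5 * n * np.log(2 * np.pi * sigma_sq) - np.sum((x - mu) ** 2) / (2 * sigma_sq)


def lod_score(y_cond, genotype_column, *, marker: int = -1,
              effect_kind: str = "additive", max_lod: float = 300.0) -> LRTResult:
    """Likelihood-ratio LOD for one marker on its conditional residual.

    The null fits one normal ``N(mu0, sigma0^2)`` to all lines; the
    alternative gives each observed genotype class (AA/Aa/aa) its own mean
    with one pooled MLE variance.  Classes absent from the data contribute
    no terms.  ``lod = (L_A - L_0) / ln 10 = (n/2) log10(sigma0^2/sigma^2)``.

    Lines with a missing genotype are dropped.  Degenerate cases: a single
    genotype class returns lod 0 with flag ``"single_class"``; zero pooled
    variance with nonzero null variance returns ``max_lod`` with flag
    ``"separable"``.
    """
    y = np.asarray(y_cond, dtype=float)
    g = np.asarray(genotype_column, dtype=float)
    if y.shape != g.shape:
        raise ValueError("y_cond and genotype column have different lengths")
    keep = ~np.isnan(g) & ~np.isnan(y)
    y, g = y[keep], g[keep]
    n = y.size

    groups = {code: y[g == code] for code in (AA, Aa, aa) if np.any(g == code)}
    n1 = groups.get(AA, np.empty(0)).size
    n2 = groups.get(Aa, np.empty(0)).size
    n3 = groups.get(aa, np.empty(0)).size

    res = LRTResult(marker=marker, effect_kind=effect_kind, y_cond=y,
                    n1=n1, n2=n2, n3=n3, mu0=np.nan, sigma0_sq=np.nan)
    if n < 3 or len(groups) < 2:
        res.flag = "single_class"
        return res

    mu0 = float(y.mean())
    sigma0_sq = float(np.mean((y - mu0) ** 2))
    res.mu0, res.sigma0_sq = mu0, sigma0_sq

    means = {c: float(v.mean()) for c, v in groups.items()}
    sse = sum(float(np.sum((v - means[c]) ** 2)) for c, v in groups.items())
    sigma_sq = sse / n
    res.class_means = means
    res.sigma_sq = sigma_sq

    if sigma0_sq <= 0.0:
        res.lod = 0.0            # constant everywhere: null and alternative tie
        return res
    if sigma_sq <= 0.0:
        res.lod = max_lod
        res.flag = "separable"
        return res

    res.L0 = _loglik_normal(y, mu0, sigma0_sq)
    res.LA = sum(_loglik_normal(v, means[c], sigma_sq) for c, v in groups.items())
    res.lod = max(0.0, (n / 2.0) * np.log10(sigma0_sq / sigma_sq))
    if res.lod > max_lod:
        res.lod = max_lod
        res.flag = "capped"
    return res


class MultiLocusQTLMapper(RegressorMixin, BaseEstimator):
    """L1-penalized additive+dominance mapper with per-locus LRT LOD scores.

    Parameters
    ----------
    lambda_ : float or "auto"
        Penalty weight; "auto" selects it by ``cv_folds``-fold
        cross-validation at minimum CV error over a geometric path of
        ``n_alphas`` values down to ``alpha_min_ratio`` times the smallest
        penalty that zeroes every effect.  ``lambda_ = 0`` is solved exactly
        by least squares (the unpenalized limit).
    cv_folds : int
        Folds for the cross-validated penalty (shuffled, seeded).
    standardize : bool
        Scale predictors to unit variance before penalization (glmnet's
        default); coefficients are always reported on the original scale.
    lod_threshold : float
        Significance threshold on max(additive LOD, dominance LOD).
    max_lod : float
        Cap used when the alternative model fits perfectly.
    random_state : int or None
        Seeds CV fold shuffling; the fit is deterministic given it.

    Attributes
    ----------
    mu_ : float
        Fitted intercept (population mean on the recipient scale).
    additive_effects_, dominance_effects_ : ndarray of shape (m,)
        Fitted ``a_j`` and ``d_j``; exactly 0 outside ``nonzero_loci_``.
    lambda_used_ : float
        Penalty actually used.
    nonzero_loci_ : ndarray of int
        Markers with a non-zero additive or dominance effect.
    lod_additive_, lod_dominance_ : ndarray of shape (m,)
        LOD scores (0 at zero-effect loci).
    lrt_flags_ : dict mapping (marker, kind) -> flag string
    imputed_markers_ : ndarray of int
        Markers where missing genotypes were mean-imputed for the fit.
    """

    def __init__(self, lambda_="auto", cv_folds=10, standardize=True,
                 lod_threshold=2.5, max_lod=300.0, n_alphas=100,
                 alpha_min_ratio=0.01, tol=1e-4, max_iter=5000,
                 random_state=None):
        self.lambda_ = lambda_
        self.cv_folds = cv_folds
        self.standardize = standardize
        self.lod_threshold = lod_threshold
        self.max_lod = max_lod
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        """Fit the joint model and score every selected locus.

        X : (n, m) genotype codes in {0, 1, 2} (aa/Aa/AA), NaN = missing.
        y : (n,) trait values.
        """
        G = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if G.ndim != 2 or G.shape[0] != y.size:
            raise ValueError("X must be (n_lines, n_markers) matching y")
        if not np.all(np.isfinite(y)):
            raise ValueError("trait values must be finite")
        if isinstance(self.lambda_, (int, float)) and self.lambda_ < 0:
            raise ValueError("lambda_ must be nonnegative")

        design = encode_design(G)
        W, V = design.W, design.V
        n, m = design.n, design.m

        # mean-impute missing design entries for the global fit only;
        # the per-marker LRT drops those lines instead.
        nanmask = np.isnan(G)
        self.imputed_markers_ = np.flatnonzero(nanmask.any(axis=0))
        Wf, Vf = W.copy(), V.copy()
        if self.imputed_markers_.size:
            for j in self.imputed_markers_:
                rows = nanmask[:, j]
                Wf[rows, j] = np.nanmean(W[:, j]) if not np.all(rows) else 0.0
                Vf[rows, j] = np.nanmean(V[:, j]) if not np.all(rows) else 0.0

        self.n_features_in_ = m
        self._G, self._W, self._V, self._y = G, Wf, Vf, y

        if np.var(y) == 0.0:
            warnings.warn("trait has zero variance; all effects set to 0")
            self._set_null_fit(float(y[0]) if n else 0.0, m)
            self._score_loci()
            return self

        a, d, mu, lam = self._solve_lasso(Wf, Vf, y)
        self.mu_ = mu
        self.additive_effects_ = a
        self.dominance_effects_ = d
        self.lambda_used_ = lam
        self.nonzero_loci_ = np.flatnonzero((a != 0.0) | (d != 0.0))
        self._score_loci()
        return self

    def _set_null_fit(self, mu, m):
        self.mu_ = mu
        self.additive_effects_ = np.zeros(m)
        self.dominance_effects_ = np.zeros(m)
        self.lambda_used_ = np.inf
        self.nonzero_loci_ = np.array([], dtype=int)

    def _solve_lasso(self, W, V, y):
        n, m = W.shape
        if self.lambda_ == 0:
            # unpenalized limit: exact least squares
            Xd = np.hstack([np.ones((n, 1)), W, V])
            beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            mu, a, d = beta[0], beta[1:m + 1], beta[m + 1:]
            a = np.where(np.abs(a) < 1e-12, 0.0, a)
            d = np.where(np.abs(d) < 1e-12, 0.0, d)
            return a, d, float(mu), 0.0

        # Shifted sparse coding: C = W + 1 (allele dosage of the donor) has
        # the same column variances as W and keeps the matrix sparse; the
        # shift is absorbed by the unpenalized intercept and undone below.
        C = sp.csc_matrix(W + 1.0)
        Vs = sp.csc_matrix(V)
        if self.standardize:
            sw = W.std(axis=0)
            sv = V.std(axis=0)
            sw[sw == 0.0] = 1.0
            sv[sv == 0.0] = 1.0
        else:
            sw = np.ones(m)
            sv = np.ones(m)
        Xs = sp.hstack([C.multiply(1.0 / sw), Vs.multiply(1.0 / sv)], format="csc")

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            if self.lambda_ in ("auto", "cv_1se", "cv_min"):
                cv = KFold(self.cv_folds, shuffle=True,
                           random_state=self.random_state)
                est = LassoCV(alphas=self.n_alphas, eps=self.alpha_min_ratio,
                              cv=cv, tol=self.tol, max_iter=self.max_iter,
                              random_state=self.random_state).fit(Xs, y)
                if self.lambda_ in ("auto", "cv_min"):
                    lam = float(est.alpha_)
                else:
                    # one-standard-error rule (glmnet's default for
                    # coefficient extraction): largest penalty whose mean CV
                    # error is within one SE of the minimum
                    mean_mse = est.mse_path_.mean(axis=1)
                    k = int(np.argmin(mean_mse))
                    se = est.mse_path_[k].std(ddof=1) / np.sqrt(
                        est.mse_path_.shape[1])
                    ok = mean_mse <= mean_mse[k] + se
                    lam = float(est.alphas_[ok].max())
                    if lam != est.alpha_:
                        est = Lasso(alpha=lam, tol=self.tol,
                                    max_iter=self.max_iter).fit(Xs, y)
            else:
                est = Lasso(alpha=float(self.lambda_), tol=self.tol,
                            max_iter=self.max_iter).fit(Xs, y)
                lam = float(self.lambda_)

        coef = np.where(np.abs(est.coef_) < 1e-10, 0.0, est.coef_)
        a = coef[:m] / sw
        d = coef[m:] / sv
        mu = float(est.intercept_) + float(a.sum())  # undo the +1 shift of C
        return a, d, mu, lam

    # ------------------------------------------------------- LRT per locus

    def _score_loci(self):
        m = self.n_features_in_
        self.lod_additive_ = np.zeros(m)
        self.lod_dominance_ = np.zeros(m)
        self.lrt_flags_ = {}
        a, d = self.additive_effects_, self.dominance_effects_
        r_full = self._y - self.predict(self._G, _use_cached=True)
        for k in self.nonzero_loci_:
            gcol = self._G[:, k]
            y_cond_a = r_full + self._W[:, k] * a[k]
            res_a = lod_score(y_cond_a, gcol, marker=k, effect_kind="additive",
                              max_lod=self.max_lod)
            self.lod_additive_[k] = res_a.lod
            if res_a.flag:
                self.lrt_flags_[(int(k), "additive")] = res_a.flag
            n_het = int(np.sum(gcol == Aa))
            if n_het >= 2:
                y_cond_d = r_full + self._V[:, k] * d[k]
                res_d = lod_score(y_cond_d, gcol, marker=k,
                                  effect_kind="dominance", max_lod=self.max_lod)
                self.lod_dominance_[k] = res_d.lod
                if res_d.flag:
                    self.lrt_flags_[(int(k), "dominance")] = res_d.flag
            else:
                self.lrt_flags_[(int(k), "dominance")] = "no_heterozygotes"

    # ---------------------------------------------------------------- misc

    def predict(self, X, _use_cached=False):
        check_is_fitted(self, "mu_")
        if _use_cached:
            W, V = self._W, self._V
        else:
            design = encode_design(np.asarray(X, dtype=float))
            W = np.nan_to_num(design.W)
            V = np.nan_to_num(design.V)
        return (self.mu_ + W @ self.additive_effects_
                + V @ self.dominance_effects_)

    def conditional_residual(self, marker: int, effect_kind: str) -> np.ndarray:
        """Phenotype with every fitted term removed except the one tested."""
        check_is_fitted(self, "mu_")
        if marker not in self.nonzero_loci_:
            raise ValueError(f"marker {marker} has no non-zero fitted effect")
        r_full = self._y - self.predict(self._G, _use_cached=True)
        if effect_kind == "additive":
            return r_full + self._W[:, marker] * self.additive_effects_[marker]
        if effect_kind == "dominance":
            return r_full + self._V[:, marker] * self.dominance_effects_[marker]
        raise ValueError("effect_kind must be 'additive' or 'dominance'")

    def scan_table(self, trait_id: str = "trait", marker_ids=None):
        """Per-marker results as a tidy DataFrame."""
        import pandas as pd

        check_is_fitted(self, "mu_")
        m = self.n_features_in_
        ids = list(marker_ids) if marker_ids is not None else [f"M{j+1}" for j in range(m)]
        lod_max = np.maximum(self.lod_additive_, self.lod_dominance_)
        return pd.DataFrame({
            "trait": trait_id,
            "marker": ids,
            "a_hat": self.additive_effects_,
            "d_hat": self.dominance_effects_,
            "lod_a": self.lod_additive_,
            "lod_d": self.lod_dominance_,
            "significant": lod_max >= self.lod_threshold,
        })


# ------------------------------------------------------- functional wrappers

def _mapper_from_config(cfg: LassoConfig | None, **overrides) -> MultiLocusQTLMapper:
    cfg = cfg or LassoConfig()
    return MultiLocusQTLMapper(
        lambda_=cfg.lambda_, cv_folds=cfg.cv_folds, standardize=cfg.standardize,
        n_alphas=cfg.n_alphas, alpha_min_ratio=cfg.alpha_min_ratio,
        tol=cfg.tol, max_iter=cfg.max_iter, random_state=cfg.seed, **overrides)


def fit_multilocus(genotypes, y, cfg: LassoConfig | None = None) -> MultiLocusQTLMapper:
    """Fit the joint additive+dominance model; returns the fitted mapper."""
    return _mapper_from_config(cfg).fit(genotypes, y)


def conditional_residual(fit: MultiLocusQTLMapper, marker: int,
                         effect_kind: str) -> np.ndarray:
    return fit.conditional_residual(marker, effect_kind)


def scan_trait(genotypes, y, cfg: LassoConfig | None = None,
               lod_threshold: float = 2.5, trait_id: str = "trait",
               marker_ids=None):
    """Fit once, LOD-score every selected locus, return the scan table."""
    mapper = _mapper_from_config(cfg, lod_threshold=lod_threshold)
    mapper.fit(genotypes, y)
    return mapper.scan_table(trait_id=trait_id, marker_ids=marker_ids)
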