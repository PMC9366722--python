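"""RR-BLUP genomic prediction.

Markers are random effects with a common variance: for centered marker
scores X (n families x m markers),

    y = mu + X b + e,    b ~ N(0, sigma_u^2 I),   e ~ N(0, sigma_e^2 I).

Variance components are estimated by REML through the spectral
decomposition of K = X X', marker effects follow as the ridge solution

    MV = X' (K + lambda I)^-1 (y - mu),   lambda = sigma_e^2 / sigma_u^2,

and breeding values are GEBV = X x MV.  Prediction accuracy is assessed by
leave-one-out cross-validation (theoretical accuracy) or by correlating
training GEBVs with phenotypes of derived later-generation lines
(empirical, realized accuracy); both report the Pearson r_g.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    DataError,
    DimensionError,
    DomainError,
    InvalidParameterError,
)

logger = logging.getLogger(__name__)

__all__ = ["RidgeBLUP", "RidgeBLUPResults", "AccuracyReport", "loo_cv", "empirical_accuracy"]

_LOG10_LAMBDA_BOUNDS = (-8.0, 8.0)


class RidgeBLUP:
    """Ridge-regression BLUP of marker effects for one trait.

    Parameters
    ----------
    y : phenotype per family (Series indexed by family id, or 1-D array).
    X : donor-dosage matrix, families x markers (DataFrame or array).
        Columns are centered by their training means before fitting; no
        variance standardization is applied.  Monomorphic markers are
        dropped (logged) — their effects are reported as 0.
    """

    def __init__(self, y, X, center: bool = True):
        if isinstance(X, pd.DataFrame):
            self.marker_ids = [str(c) for c in X.columns]
            Xv = X.to_numpy(dtype=float)
            fam = [str(i) for i in X.index]
        else:
            Xv = np.asarray(X, dtype=float)
            self.marker_ids = [f"m{j}" for j in range(Xv.shape[1])]
            fam = [str(i) for i in range(Xv.shape[0])]
        if isinstance(y, pd.Series):
            ys = y.copy()
            ys.index = ys.index.astype(str)
            if len(set(fam)) == len(fam):
                missing = [f for f in fam if f not in ys.index]
                if missing:
                    raise DimensionError(
                        f"phenotype missing for families: {missing[:5]}"
                    )
                yv = ys.loc[fam].to_numpy(dtype=float)
            else:
                yv = ys.to_numpy(dtype=float)
        else:
            yv = np.asarray(y, dtype=float)
        if yv.shape != (Xv.shape[0],):
            raise DimensionError("y length must equal the number of rows of X")
        if Xv.shape[0] < 3 or Xv.shape[1] < 1:
            raise InvalidParameterError("need n >= 3 families and m >= 1 markers")
        if not np.all(np.isfinite(yv)):
            raise DataError("y contains non-finite values")
        self.family_ids = fam
        self.y = yv
        self._X_raw = Xv
        poly = Xv.std(axis=0) > 0
        if not poly.all():
            dropped = [m for m, keep in zip(self.marker_ids, poly) if not keep]
            logger.info("dropping %d monomorphic markers: %s", len(dropped), dropped[:10])
        self._poly = poly
        self.center = center
        self.col_means = Xv[:, poly].mean(axis=0) if center else np.zeros(int(poly.sum()))
        self.Xc = Xv[:, poly] - self.col_means

    # -- REML --------------------------------------------------------------
    def _profile_negloglik(self, log10_lam: float, d: np.ndarray, y2: np.ndarray) -> float:
        lam = 10.0 ** log10_lam
        dn = d + lam
        nm = len(d)
        s2 = float(np.sum(y2 / dn)) / nm
        return 0.5 * (nm * np.log(max(s2, 1e-300)) + float(np.sum(np.log(dn))) + nm)

    def fit(self, lamb: float | None = None) -> "RidgeBLUPResults":
        """Estimate (sigma_u^2, sigma_e^2) by spectral REML, or solve the
        ridge system at a fixed ``lamb`` if one is supplied."""
        n = len(self.y)
        m_poly = self.Xc.shape[1]
        if m_poly == 0 or not np.any(self.Xc):
            logger.warning("no polymorphic marker signal; all effects set to 0")
            mu = float(self.y.mean())
            mv = pd.Series(0.0, index=self.marker_ids)
            return RidgeBLUPResults(
                model=self, mu=mu, marker_effects=mv,
                sigma2_u=0.0, sigma2_e=float(np.var(self.y, ddof=1)),
                lamb=np.inf, loglik=np.nan,
            )
        K = self.Xc @ self.Xc.T
        d_all, U = np.linalg.eigh(K)
        # project out the intercept: work in the n-1 dim contrast space
        ones = np.ones(n) / np.sqrt(n)
        # eigenvectors of K restricted to the orthogonal complement of 1:
        # deflate via projection of the rotated response
        P = np.eye(n) - np.outer(ones, ones)
        Kc = P @ K @ P
        d, V = np.linalg.eigh(Kc)
        keep = slice(1, n)  # drop the (near-)zero eigenvalue of the 1-direction
        d = np.clip(d[keep], 0.0, None)
        yt = V[:, keep].T @ (self.y - self.y.mean())
        y2 = yt * yt

        if lamb is None:
            if np.allclose(d, 0):
                lamb = np.inf
            else:
                res = optimize.minimize_scalar(
                    self._profile_negloglik,
                    bounds=_LOG10_LAMBDA_BOUNDS,
                    args=(d, y2),
                    method="bounded",
                    options={"xatol": 1e-10},
                )
                lamb = float(10.0 ** res.x)
                if res.x >= _LOG10_LAMBDA_BOUNDS[1] - 1e-6:
                    logger.warning(
                        "REML drove lambda to its upper bound (no detectable "
                        "genetic signal); marker effects shrink to ~0"
                    )
        if not np.isfinite(lamb):
            mu = float(self.y.mean())
            mv = pd.Series(0.0, index=self.marker_ids)
            return RidgeBLUPResults(
                model=self, mu=mu, marker_effects=mv, sigma2_u=0.0,
                sigma2_e=float(np.var(self.y, ddof=1)), lamb=np.inf, loglik=np.nan,
            )

        nm = len(d)
        sigma2_u = float(np.sum(y2 / (d + lamb))) / nm
        sigma2_e = lamb * sigma2_u
        # GLS intercept in the eigenbasis of K (eigenvalues clipped at 0)
        w = 1.0 / (np.clip(d_all, 0.0, None) + lamb)
        yt_full = U.T @ self.y
        ot_full = U.T @ np.ones(n)
        mu = float(np.sum(w * ot_full * yt_full) / np.sum(w * ot_full * ot_full))
        # primal ridge normal equations: numerically stable for small lambda
        mv_poly = np.linalg.solve(
            self.Xc.T @ self.Xc + lamb * np.eye(m_poly),
            self.Xc.T @ (self.y - mu),
        )
        mv = np.zeros(len(self.marker_ids))
        mv[self._poly] = mv_poly
        loglik = -self._profile_negloglik(np.log10(lamb), d, y2)
        return RidgeBLUPResults(
            model=self,
            mu=mu,
            marker_effects=pd.Series(mv, index=self.marker_ids),
            sigma2_u=sigma2_u,
            sigma2_e=sigma2_e,
            lamb=float(lamb),
            loglik=float(loglik),
        )


@dataclass
class RidgeBLUPResults:
    """Fitted marker effects and variance components."""

    model: RidgeBLUP
    mu: float
    marker_effects: pd.Series  # trait units per unit donor dosage
    sigma2_u: float
    sigma2_e: float
    lamb: float
    loglik: float

    def predict(self, X_new) -> pd.Series:
        """GEBV = X x MV for new families, centered with training means."""
        if isinstance(X_new, pd.DataFrame):
            ids = [str(i) for i in X_new.index]
            Xv = X_new.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X_new, dtype=float)
            ids = [str(i) for i in range(Xv.shape[0])]
        if Xv.shape[1] != len(self.marker_effects):
            raise DimensionError(
                f"X_new has {Xv.shape[1]} columns; model has "
                f"{len(self.marker_effects)} markers"
            )
        Xc = Xv[:, self.model._poly] - self.model.col_means
        gebv = Xc @ self.marker_effects.to_numpy()[self.model._poly]
        return pd.Series(gebv, index=ids, name="gebv")

    def gebv(self) -> pd.Series:
        """Training-set GEBVs (zero mean by construction of the centering)."""
        g = self.model.Xc @ self.marker_effects.to_numpy()[self.model._poly]
        return pd.Series(g, index=self.model.family_ids, name="gebv")

    @property
    def heritability(self) -> float:
        """Genomic heritability implied by the fit: var(g) / var(y)."""
        g = self.gebv().to_numpy()
        vy = np.var(self.model.y, ddof=1)
        return float(np.var(g, ddof=1) / vy) if vy > 0 else np.nan

    def summary(self) -> str:
        return "\n".join(
            [
                "RR-BLUP (spectral REML)",
                f"  n = {len(self.model.y)} families, "
                f"m = {len(self.marker_effects)} markers "
                f"({int(self.model._poly.sum())} polymorphic)",
                f"  mu = {self.mu:.4f}",
                f"  sigma2_marker = {self.sigma2_u:.6g}   "
                f"sigma2_resid = {self.sigma2_e:.6g}   lambda = {self.lamb:.6g}",
                f"  restricted log-likelihood: {self.loglik:.4f}",
            ]
        )


@dataclass
class AccuracyReport:
    """Prediction accuracy r_g (Pearson) with its two-sided p-value."""

    r_g: float
    p_value: float
    kind: str  # "cross_validation" or "empirical"
    n: int

    def summary(self) -> str:
        return f"{self.kind}: r_g = {self.r_g:.3f} (p = {self.p_value:.3g}, n = {self.n})"


def loo_cv(y, X) -> AccuracyReport:
    """Leave-one-out cross-validation accuracy.

    Each family's GEBV is predicted from a model refit (including variance
    components) on the other n - 1 families; r_g is the Pearson correlation
    between the held-out GEBVs (X x MV, no intercept) and the observed
    phenotypes.  The per-fold intercept is deliberately excluded from the
    correlation: it differs across folds only through the held-out
    observation, and that leakage alone drives the correlation toward -1
    whenever the marker model carries no signal.
    """
    if isinstance(X, pd.DataFrame):
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
    yv = y.to_numpy(dtype=float) if isinstance(y, pd.Series) else np.asarray(y, float)
    n = Xv.shape[0]
    if n < 10:
        raise InvalidParameterError("leave-one-out CV needs n >= 10")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fit = RidgeBLUP(yv[mask], Xv[mask]).fit()
        preds[i] = fit.predict(Xv[i:i + 1]).iloc[0]
    if np.std(preds) == 0 or np.std(yv) == 0:
        raise DomainError(
            "constant predictions or phenotypes: correlation undefined "
            f"(pred sd = {np.std(preds):.3g}, y sd = {np.std(yv):.3g})"
        )
    r, p = stats.pearsonr(preds, yv)
    return AccuracyReport(r_g=float(r), p_value=float(p), kind="cross_validation", n=n)


def empirical_accuracy(gebv: pd.Series, pheno: pd.Series) -> AccuracyReport:
    """Realized accuracy: correlation of training GEBVs with phenotypic
    BLUPs of derived (e.g. further-inbred) lines, over matching ids."""
    gebv = gebv.copy()
    pheno = pheno.copy()
    gebv.index = gebv.index.astype(str)
    pheno.index = pheno.index.astype(str)
    common = [i for i in gebv.index if i in pheno.index]
    if len(common) < 3:
        raise InvalidParameterError(
            f"need >= 3 matched family ids; found {len(common)}"
        )
    r, p = stats.pearsonr(gebv.loc[common], pheno.loc[common])
    return AccuracyReport(r_g=float(r), p_value=float(p), kind="empirical", n=len(common))
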