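"""Trial models: spatially adjusted BLUPs, variance components, group tests.

The workhorse is the random-effects model for augmented greenhouse trials,

    Y = mu + genotype + Row + Column + error,

with genotype, row and column all random.  Variance components are
estimated by EM-REML on Henderson's mixed-model equations and genotype
BLUPs are the spatially adjusted trait values carried forward to QTL
mapping and selection.  Row and column levels are nested within
environment when the data span several environments.

Also here: variance partitioning (percent of total per term), likelihood
ratio tests with BIC for dropping single terms, the fixed-effects model
with Tukey HSD letters for group comparisons, and simple trait-vs-trait
regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .errors import (
    ConvergenceError,
    DomainError,
    InvalidParameterError,
    LookupError_,
    RankError,
)

__all__ = [
    "TrialModel",
    "TrialResults",
    "ModelComparison",
    "TukeyResult",
    "RegressionResult",
    "variance_partition",
    "average_blups",
    "lrt_drop_term",
    "fit_fixed_tukey",
    "trait_regression",
]

VAR_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# the random-effects trial model
# ---------------------------------------------------------------------------
class TrialModel:
    """Random-effects model for one response in a (possibly augmented) trial.

    Parameters
    ----------
    data : DataFrame with columns ``line_id``, ``row``, ``column`` and the
        response; an ``environment`` column, if present with > 1 level,
        nests row/column effects within environment.
    response : name of the response column (ordinal scores are treated as
        numeric).
    random_terms : subset of ("genotype", "row", "column").
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        random_terms=("genotype", "row", "column"),
        genotype_col: str = "line_id",
    ):
        if response not in data.columns:
            raise InvalidParameterError(f"response column {response!r} not in data")
        allowed = ("genotype", "row", "column")
        bad = [t for t in random_terms if t not in allowed]
        if bad:
            raise InvalidParameterError(f"unknown random terms {bad}; allowed {allowed}")
        self.data = data.reset_index(drop=True)
        self.response = response
        self.random_terms = tuple(random_terms)
        self.genotype_col = genotype_col
        self.y = self.data[response].to_numpy(dtype=float)
        if np.any(~np.isfinite(self.y)):
            raise InvalidParameterError("response contains non-finite values")
        self._build_design()

    def _term_labels(self, term: str) -> pd.Series:
        d = self.data
        if term == "genotype":
            return d[self.genotype_col].astype(str)
        col = d[term].astype(str)
        if "environment" in d.columns and d["environment"].nunique() > 1:
            return d["environment"].astype(str) + ":" + col
        return col

    def _build_design(self):
        n = len(self.data)
        self.X = np.ones((n, 1))
        self.Z: dict[str, np.ndarray] = {}
        self.levels: dict[str, list[str]] = {}
        for term in self.random_terms:
            lab = self._term_labels(term)
            levels = sorted(lab.unique())
            if len(levels) < 2:
                raise RankError(f"random term {term!r} needs >= 2 levels")
            idx = lab.map({l: i for i, l in enumerate(levels)}).to_numpy()
            Z = np.zeros((n, len(levels)))
            Z[np.arange(n), idx] = 1.0
            self.Z[term] = Z
            self.levels[term] = levels

    # -- REML machinery ----------------------------------------------------
    def _loglik(self, sigma2: dict[str, float], sigma2_e: float) -> float:
        """Restricted log-likelihood at the given variance components."""
        n = len(self.y)
        V = sigma2_e * np.eye(n)
        for term, Z in self.Z.items():
            if sigma2[term] > 0:
                V += sigma2[term] * (Z @ Z.T)
        try:
            L = cho_factor(V, lower=True)
        except np.linalg.LinAlgError as exc:
            raise RankError(f"V not positive definite: {exc}") from exc
        logdetV = 2.0 * np.sum(np.log(np.diag(L[0])))
        Vi_y = cho_solve(L, self.y)
        Vi_X = cho_solve(L, self.X)
        XtViX = self.X.T @ Vi_X
        sign, logdetXVX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise RankError("X'V^-1X singular")
        beta = np.linalg.solve(XtViX, self.X.T @ Vi_y)
        r = self.y - self.X @ beta
        quad = float(r @ cho_solve(L, r))
        p = self.X.shape[1]
        return -0.5 * (logdetV + logdetXVX + quad + (n - p) * np.log(2 * np.pi))

    def _polish(self, sigma2: dict, sigma2_e: float, v_y: float):
        """Bounded Nelder-Mead on log10 variances, warm-started from EM."""
        from scipy.optimize import minimize

        terms = list(self.random_terms)
        lo, hi = -12.0, np.log10(4.0 * v_y)
        x0 = np.log10(np.clip([sigma2[t] for t in terms] + [sigma2_e], 10.0**lo, None))

        def neg(x):
            s = {t: 10.0 ** xi for t, xi in zip(terms, x[:-1])}
            try:
                return -self._loglik(s, 10.0 ** x[-1])
            except RankError:
                return np.inf

        res = minimize(
            neg, np.clip(x0, lo, hi), method="Nelder-Mead",
            bounds=[(lo, hi)] * len(x0),
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if not np.isfinite(res.fun):
            return sigma2, sigma2_e, np.nan, False
        out = {t: max(10.0 ** xi, VAR_FLOOR) for t, xi in zip(terms, res.x[:-1])}
        out = {t: (VAR_FLOOR if v <= 10.0 ** (lo + 1) else v) for t, v in out.items()}
        return out, float(10.0 ** res.x[-1]), float(-res.fun), True

    def fit(self, tol: float = 1e-8, maxiter: int = 500, start=None) -> "TrialResults":
        """EM-REML on Henderson's mixed-model equations.

        Convergence is declared when the relative change of the restricted
        log-likelihood falls below ``tol`` and the variance components have
        stopped moving (scaled by the phenotypic variance); estimates are
        floored at 1e-10.  EM crawls when a component approaches the zero
        boundary, so a stalled fit is finished by a bounded simplex search
        on the restricted likelihood; ConvergenceError (carrying the
        iteration trace) is raised only if that also fails.
        """
        y, X = self.y, self.X
        n, p = X.shape[0], X.shape[1]
        terms = list(self.random_terms)
        q = {t: self.Z[t].shape[1] for t in terms}

        if np.var(y) == 0.0:  # degenerate: constant response
            vc = {t: 0.0 for t in terms}
            blups = {t: pd.Series(0.0, index=self.levels[t]) for t in terms}
            return TrialResults(
                model=self,
                variance_components=vc,
                resid_variance=0.0,
                loglik=0.0,
                n_iter=0,
                converged=True,
                intercept=float(y[0]),
                blups_by_term=blups,
            )

        W = np.hstack([X] + [self.Z[t] for t in terms])
        WtW = W.T @ W
        Wty = W.T @ y
        yty = float(y @ y)
        slices, start_col = {}, p
        for t in terms:
            slices[t] = slice(start_col, start_col + q[t])
            start_col += q[t]

        v_y = float(np.var(y, ddof=1))
        default = v_y / (len(terms) + 1)
        start = start or {}
        sigma2 = {t: float(start.get(t, default)) for t in terms}
        sigma2_e = float(start.get("residual", default))

        ll_old = -np.inf
        par_old = np.array([sigma2[t] for t in terms] + [sigma2_e])
        trace = []
        theta = None
        converged = False
        n_slow = 0
        for it in range(1, maxiter + 1):
            M = WtW.copy()
            for t in terms:
                lam = sigma2_e / max(sigma2[t], VAR_FLOOR)
                sl = slices[t]
                M[sl, sl] += lam * np.eye(q[t])
            try:
                Lm = cho_factor(M, lower=True)
            except np.linalg.LinAlgError as exc:
                raise RankError(f"singular mixed-model equations: {exc}") from exc
            theta = cho_solve(Lm, Wty)
            Minv = cho_solve(Lm, np.eye(M.shape[0]))
            sigma2_e = max((yty - float(theta @ Wty)) / (n - p), VAR_FLOOR)
            for t in terms:
                sl = slices[t]
                u = theta[sl]
                tr = float(np.trace(Minv[sl, sl]))
                sigma2[t] = max((float(u @ u) + sigma2_e * tr) / q[t], VAR_FLOOR)
            ll = self._loglik(sigma2, sigma2_e)
            trace.append({"iter": it, "loglik": ll, **sigma2, "residual": sigma2_e})
            par = np.array([sigma2[t] for t in terms] + [sigma2_e])
            # parameter movement scaled by the total phenotypic variance:
            # a component decaying to the boundary has a vanishing absolute
            # step, so this criterion terminates there too
            par_change = float(np.max(np.abs(par - par_old))) / v_y
            ll_slow = abs(ll - ll_old) / (abs(ll) + 1.0) < tol
            if ll_slow and par_change < 100.0 * tol:
                converged = True
                break
            # EM crawls when a component heads for the zero boundary; hand
            # a stalled fit to a direct simplex search on the restricted
            # likelihood instead of burning the remaining iterations
            n_slow = n_slow + 1 if ll_slow else 0
            if n_slow >= 30:
                break
            ll_old = ll
            par_old = par

        if not converged:
            sigma2, sigma2_e, ll, ok = self._polish(sigma2, sigma2_e, v_y)
            if not ok:
                raise ConvergenceError(
                    f"EM-REML did not converge in {maxiter} iterations and the "
                    "simplex polish failed", trace=trace,
                )
            # final BLUP solve at the polished variance components
            M = WtW.copy()
            for t in terms:
                lam = sigma2_e / max(sigma2[t], VAR_FLOOR)
                sl = slices[t]
                M[sl, sl] += lam * np.eye(q[t])
            theta = cho_solve(cho_factor(M, lower=True), Wty)
            trace.append({"iter": it, "loglik": ll, **sigma2, "residual": sigma2_e,
                          "polished": True})

        blups = {
            t: pd.Series(theta[slices[t]], index=self.levels[t]) for t in terms
        }
        vc = {t: (0.0 if sigma2[t] <= 2 * VAR_FLOOR else sigma2[t]) for t in terms}
        return TrialResults(
            model=self,
            variance_components=vc,
            resid_variance=sigma2_e,
            loglik=ll,
            n_iter=it,
            converged=True,
            intercept=float(theta[0]),
            blups_by_term=blups,
        )


@dataclass
class TrialResults:
    """REML fit of a :class:`TrialModel`."""

    model: TrialModel
    variance_components: dict
    resid_variance: float
    loglik: float
    n_iter: int
    converged: bool
    intercept: float
    blups_by_term: dict = field(repr=False)

    @property
    def blups(self) -> pd.Series:
        """Genotype BLUPs (deviations from the intercept)."""
        if "genotype" not in self.blups_by_term:
            raise LookupError_("genotype is not a random term of this model")
        return self.blups_by_term["genotype"]

    @property
    def n_params(self) -> int:
        # variance components (incl. residual) + fixed effects
        return len(self.variance_components) + 1 + self.model.X.shape[1]

    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(len(self.model.y))

    def variance_partition(self) -> pd.Series:
        comps = dict(self.variance_components)
        comps["residual"] = self.resid_variance
        return variance_partition(comps)

    def summary(self) -> str:
        lines = [
            "Random-effects trial model (EM-REML)",
            f"  response: {self.model.response}   n = {len(self.model.y)}",
            f"  REML log-likelihood: {self.loglik:.4f}  "
            f"(iterations: {self.n_iter}, BIC: {self.bic():.2f})",
            f"  intercept (mu): {self.intercept:.4f}",
            "  variance components (percent of total):",
        ]
        pct = self.variance_partition()
        for term, v in {**self.variance_components, "residual": self.resid_variance}.items():
            lines.append(f"    {term:<10} {v:>12.6f}   {pct[term]:6.2f} %")
        return "\n".join(lines)


def variance_partition(components: dict) -> pd.Series:
    """Each component as a percentage of the total; sums to 100."""
    total = float(sum(components.values()))
    if total <= 0:
        raise DomainError("total variance must be > 0 to partition")
    return pd.Series({k: 100.0 * v / total for k, v in components.items()})


def average_blups(blups_by_environment: dict) -> pd.Series:
    """Unweighted mean of per-environment genotype BLUPs.

    Genotypes missing from some environments are averaged over the
    environments where they appear; a genotype absent everywhere raises.
    """
    if not blups_by_environment:
        raise InvalidParameterError("no environments supplied")
    df = pd.DataFrame(blups_by_environment)
    if df.isna().all(axis=1).any():
        missing = df.index[df.isna().all(axis=1)].tolist()
        raise LookupError_(f"genotypes absent from every environment: {missing}")
    return df.mean(axis=1)


@dataclass
class ModelComparison:
    """Likelihood ratio test of dropping one term, with BIC for both fits."""

    term: str
    statistic: float
    df: int
    p_value: float
    bic_full: float
    bic_reduced: float
    loglik_full: float
    loglik_reduced: float


def lrt_drop_term(
    data: pd.DataFrame,
    response: str,
    term: str,
    random_terms=("genotype", "row", "column"),
    genotype_col: str = "line_id",
    **fit_kwargs,
) -> ModelComparison:
    """LRT of the full random model against the model with ``term`` dropped.

    statistic = 2 (logLik_full - logLik_reduced), referred to chi-square
    with 1 df (no boundary mixture correction; conservative for a variance
    component tested at its boundary).
    """
    if term not in random_terms:
        raise InvalidParameterError(f"term {term!r} not in the model {random_terms}")
    reduced_terms = tuple(t for t in random_terms if t != term)
    if not reduced_terms:
        raise InvalidParameterError("cannot drop the only random term")
    full = TrialModel(data, response, random_terms, genotype_col).fit(**fit_kwargs)
    red = TrialModel(data, response, reduced_terms, genotype_col).fit(**fit_kwargs)
    stat = max(0.0, 2.0 * (full.loglik - red.loglik))
    return ModelComparison(
        term=term,
        statistic=stat,
        df=1,
        p_value=float(stats.chi2.sf(stat, df=1)),
        bic_full=full.bic(),
        bic_reduced=red.bic(),
        loglik_full=full.loglik,
        loglik_reduced=red.loglik,
    )


# ---------------------------------------------------------------------------
# fixed model + Tukey HSD
# ---------------------------------------------------------------------------
@dataclass
class TukeyResult:
    group_means: pd.Series       # block-adjusted least-squares means
    hsd: float                   # minimum significant difference
    letters: pd.Series           # compact letter display
    mse: float
    df_error: int
    alpha: float

    def summary(self) -> str:
        lines = [
            f"Tukey HSD (alpha = {self.alpha}); minimum significant "
            f"difference = {self.hsd:.4f}",
        ]
        for g in self.group_means.sort_values(ascending=False).index:
            lines.append(f"  {g:<14} {self.group_means[g]:>10.4f}  {self.letters[g]}")
        return "\n".join(lines)


def _compact_letters(means: pd.Series, hsd: float) -> pd.Series:
    """Insert-and-absorb compact letter display.

    Groups whose means differ by more than ``hsd`` share no letter; ties in
    mean are broken by ascending mean then label.
    """
    order = means.sort_values(ascending=False, kind="mergesort").index.tolist()
    columns = [set(order)]  # start: everyone shares one letter
    for i, gi in enumerate(order):
        for gj in order[i + 1:]:
            if abs(means[gi] - means[gj]) > hsd:  # significant pair: insert
                for col in [c for c in columns if gi in c and gj in c]:
                    columns.remove(col)
                    columns.append(col - {gi})
                    columns.append(col - {gj})
                # absorb: drop columns contained in another
                keep = []
                for c in columns:
                    if not any(c < other for other in columns if other is not c):
                        if c not in keep:
                            keep.append(c)
                columns = keep
    # letter order follows the best mean in each column
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in means.index}
    for letter, col in zip(alphabet, columns):
        for g in col:
            out[g] += letter
    return pd.Series({g: "".join(sorted(out[g])) for g in means.index})


def fit_fixed_tukey(
    data: pd.DataFrame,
    response: str,
    group_term: str,
    block_term: str | None = None,
    alpha: float = 0.05,
) -> TukeyResult:
    """Fixed-effects model with Tukey's honest significant difference.

    Fits  response ~ group (+ block)  by OLS, computes block-adjusted
    least-squares group means, HSD = q(alpha, k, df_e) * sqrt(MSE / n_h)
    with n_h the harmonic mean group size, and assigns compact letters.
    """
    import statsmodels.formula.api as smf

    counts = data.groupby(group_term)[response].count()
    if len(counts) < 2:
        raise InvalidParameterError("need >= 2 groups")
    if (counts < 2).any():
        raise InvalidParameterError("every group needs >= 2 observations")
    formula = f"Q('{response}') ~ C(Q('{group_term}'))"
    if block_term is not None:
        formula += f" + C(Q('{block_term}'))"
    ols = smf.ols(formula, data=data).fit()
    if ols.df_resid < 1:
        raise InvalidParameterError("no residual degrees of freedom")

    groups = sorted(data[group_term].unique())
    # LS means: average prediction over the observed block levels
    if block_term is not None:
        blocks = sorted(data[block_term].unique())
        grid = pd.DataFrame(
            [(g, b) for g in groups for b in blocks], columns=[group_term, block_term]
        )
    else:
        grid = pd.DataFrame({group_term: groups})
    grid["__pred"] = ols.predict(grid)
    means = grid.groupby(group_term)["__pred"].mean()

    k = len(groups)
    df_e = int(ols.df_resid)
    mse = float(ols.mse_resid)
    n_h = k / float((1.0 / counts).sum())
    qcrit = float(stats.studentized_range.ppf(1.0 - alpha, k, df_e))
    hsd = qcrit * np.sqrt(mse / n_h)
    letters = _compact_letters(means, hsd)
    return TukeyResult(
        group_means=means, hsd=hsd, letters=letters, mse=mse, df_error=df_e, alpha=alpha
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def trait_regression(x, y) -> RegressionResult:
    """Ordinary least-squares regression of one trait on another."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise InvalidParameterError("need n >= 3")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise InvalidParameterError("non-finite values")
    if np.var(x) == 0:
        raise DomainError("zero variance in x: degenerate regression")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(x),
    )
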