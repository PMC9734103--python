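"""Multilevel binomial models for county-week mask-posting panels.

The estimand is the association between mask-mandate exposure and the
county-week proportion of image-posting users who posted a mask image,
allowing the mandate effect to vary with county GOP vote share. The model
is a binomial GLMM on (successes = mask users, trials = image users):

    logit p_jt = x_jt' beta + u_county(j) + u_state(j) + u_week(t),
    u_f ~ Normal(0, sigma_f^2), independent across the three factors,

with crossed Gaussian random intercepts for county, state (which absorbs
the county-in-state nesting), and week. Estimation maximizes the
Laplace-approximated marginal likelihood: an inner penalized Newton solve
(PIRLS) finds the joint mode of the fixed effects and random effects given
the variance components, and an outer quasi-Newton search maximizes the
Laplace objective over the three log-standard-deviations. Fixed-effect
standard errors come from the joint-mode Hessian, the standard conditional
approximation for Laplace fits.

Covariates enter untransformed on their reporting scales (percentage
points, deaths per 10k, visits per hundred, weekly counter), so printed
coefficients are per raw unit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse, special, stats

from .synthetic_data import GeneratorParams, simulate_panel

__all__ = [
    "FIXED_TERMS",
    "DesignBundle",
    "build_design",
    "MaskMandateGLMM",
    "GLMMResults",
    "effect_per_sd",
    "MarginalEffectCurve",
    "marginal_effect_curve",
    "compare_models",
    "RecoveryReport",
    "recovery_study",
]

#: Fixed-effect terms in reporting order, with the panel column each reads.
FIXED_TERMS: dict[str, str | None] = {
    "intercept": None,
    "mandate": "mandate_active",
    "gop": "gop_vote_2016",
    "mandate_gop": None,  # elementwise product of the two above
    "deaths": "deaths_per_10k_lag",
    "urban": "urban_pct",
    "density": "density",
    "news": "covid_news",
    "retail": "retail_per_100",
    "week": "week_counter",
}

GROUPING_FACTORS = ("county", "state", "week")


@dataclass
class DesignBundle:
    """Response pairs, fixed-effect matrix, and grouping indices."""

    y: np.ndarray  # successes
    n: np.ndarray  # trials
    X: np.ndarray
    exog_names: list[str]
    groups: dict[str, np.ndarray]  # factor -> integer codes per row
    group_levels: dict[str, np.ndarray]  # factor -> level labels


def build_design(panel: pd.DataFrame, interaction: bool = True) -> DesignBundle:
    """Build the model design from a complete county-week panel.

    Rows whose trial count is missing must be excluded beforehand; rows
    with zero trials raise (exclude them — they carry no information and
    the binomial likelihood is undefined on an empty denominator).
    """
    n = panel["n_image_users"]
    if n.isna().any():
        raise ValueError(
            "panel has county-weeks with missing user counts; exclude them before fitting"
        )
    if (n == 0).any():
        raise ValueError(
            "panel has county-weeks with zero image-posting users; exclude them before fitting"
        )

    names = [t for t in FIXED_TERMS if interaction or t != "mandate_gop"]
    cols = []
    for term in names:
        if term == "intercept":
            cols.append(np.ones(len(panel)))
        elif term == "mandate_gop":
            cols.append(
                panel["mandate_active"].astype(float).values * panel["gop_vote_2016"].values
            )
        else:
            cols.append(panel[FIXED_TERMS[term]].astype(float).values)
    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate values in the design")

    groups, levels = {}, {}
    for factor, col in (("county", "fips"), ("state", "state"), ("week", "week_index")):
        codes, lev = pd.factorize(panel[col], sort=True)
        groups[factor] = codes.astype(np.int64)
        levels[factor] = np.asarray(lev)
    return DesignBundle(
        y=panel["n_mask_users"].astype(float).values,
        n=n.astype(float).values,
        X=X,
        exog_names=names,
        groups=groups,
        group_levels=levels,
    )


def _binom_const(y: np.ndarray, n: np.ndarray) -> float:
    return float(
        np.sum(special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1))
    )


class MaskMandateGLMM:
    """Binomial GLMM with crossed random intercepts, statsmodels-style.

    Construct from arrays or with :meth:`from_panel`, then call
    :meth:`fit`. With no grouping factors (or all variance components fixed
    at zero) the model collapses to an ordinary binomial GLM.
    """

    def __init__(
        self,
        endog_success: np.ndarray,
        endog_trials: np.ndarray,
        exog: np.ndarray,
        exog_names: list[str] | None = None,
        groups: dict[str, np.ndarray] | None = None,
        group_levels: dict[str, np.ndarray] | None = None,
    ) -> None:
        self.y = np.asarray(endog_success, dtype=float)
        self.n = np.asarray(endog_trials, dtype=float)
        self.X = np.asarray(exog, dtype=float)
        if self.X.ndim != 2 or len(self.y) != len(self.n) != self.X.shape[0]:
            raise ValueError("inconsistent design dimensions")
        if np.any(self.y > self.n) or np.any(self.y < 0):
            raise ValueError("successes must lie in [0, trials]")
        self.exog_names = list(exog_names) if exog_names else [
            f"x{i}" for i in range(self.X.shape[1])
        ]
        self.groups = {k: np.asarray(v, dtype=np.int64) for k, v in (groups or {}).items()}
        self.group_levels = group_levels or {
            k: np.arange(v.max() + 1) for k, v in self.groups.items()
        }
        for factor, codes in self.groups.items():
            if len(np.unique(codes)) < 2:
                raise ValueError(f"grouping factor {factor!r} needs >= 2 levels")
        self.factor_names = list(self.groups)
        self.n_levels = [len(self.group_levels[f]) for f in self.factor_names]
        self._Z = self._build_z()
        self._A = (
            sparse.hstack([sparse.csr_matrix(self.X), self._Z]).tocsr()
            if self._Z is not None
            else None
        )
        self._const = _binom_const(self.y, self.n)

    @classmethod
    def from_panel(
        cls, panel: pd.DataFrame, interaction: bool = True, drop_missing: bool = True
    ) -> "MaskMandateGLMM":
        if drop_missing:
            panel = panel.loc[panel["n_image_users"].notna()]
        d = build_design(panel, interaction=interaction)
        return cls(d.y, d.n, d.X, d.exog_names, d.groups, d.group_levels)

    # ------------------------------------------------------------------
    @property
    def nobs(self) -> int:
        return len(self.y)

    @property
    def n_groups(self) -> dict[str, int]:
        return dict(zip(self.factor_names, self.n_levels))

    def _build_z(self) -> sparse.csr_matrix | None:
        if not self.groups:
            return None
        blocks = []
        for factor, n_lev in zip(self.factor_names, self.n_levels):
            codes = self.groups[factor]
            blocks.append(
                sparse.csr_matrix(
                    (np.ones(len(codes)), (np.arange(len(codes)), codes)),
                    shape=(len(codes), n_lev),
                )
            )
        return sparse.hstack(blocks).tocsr()

    # ------------------------------------------------------------------
    def _penalty_vector(self, sigma2: np.ndarray) -> np.ndarray:
        return np.repeat(1.0 / sigma2, self.n_levels)

    def _pirls(
        self, sigma2: np.ndarray, phi0: np.ndarray | None, maxiter: int = 80, tol: float = 1e-9
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
        """Penalized Newton solve for the joint (beta, u) mode.

        Iterates to (near) machine precision — the outer optimizer
        differentiates this profiled objective numerically, so a sloppy
        inner solve would poison the outer gradient. Convergence is judged
        on the Newton decrement, which bounds the remaining objective gap.

        Returns (phi, w, H_dense, penalized loglik, converged).
        """
        A = self._A
        p = self.X.shape[1]
        q = A.shape[1] - p
        pen = np.concatenate([np.zeros(p), self._penalty_vector(sigma2)])
        phi = phi0.copy() if phi0 is not None else self._start_phi(p, q)

        def obj(phi_):
            eta = A @ phi_
            ll = float(np.sum(self.y * eta - self.n * np.logaddexp(0.0, eta)))
            return ll - 0.5 * float(np.sum(pen * phi_**2))

        f = obj(phi)
        H = None
        ok = False
        for _ in range(maxiter):
            eta = A @ phi
            mu = special.expit(eta)
            w = self.n * mu * (1.0 - mu)
            grad = A.T @ (self.y - self.n * mu) - pen * phi
            WA = A.multiply(w[:, None]).tocsr()
            H = (A.T @ WA).toarray()
            H[np.diag_indices_from(H)] += pen
            try:
                cf = linalg.cho_factor(H, lower=True)
            except linalg.LinAlgError:
                H[np.diag_indices_from(H)] += 1e-8
                cf = linalg.cho_factor(H, lower=True)
            step = linalg.cho_solve(cf, grad)
            decrement = float(grad @ step)  # ~ 2x the remaining objective gap
            if decrement < tol:
                ok = True
                break
            # step-halving line search on the penalized loglik
            t = 1.0
            for _ in range(30):
                f_new = obj(phi + t * step)
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            phi = phi + t * step
            f = f_new
        eta = A @ phi
        mu = special.expit(eta)
        w = self.n * mu * (1.0 - mu)
        return phi, w, H, f, ok

    def _start_phi(self, p: int, q: int) -> np.ndarray:
        # least-squares on the empirical logit for beta; random effects at 0
        prop = (self.y + 0.5) / (self.n + 1.0)
        eta0 = np.log(prop / (1.0 - prop))
        beta0, *_ = np.linalg.lstsq(self.X, eta0, rcond=None)
        return np.concatenate([beta0, np.zeros(q)])

    def _laplace_loglik(self, sigma2: np.ndarray, phi0: np.ndarray | None):
        phi, w, H, f_pen, ok = self._pirls(sigma2, phi0)
        p = self.X.shape[1]
        # log det (I + S^{1/2} Z'WZ S^{1/2}); Z'WZ is the u-block of H minus the penalty
        s = np.sqrt(np.repeat(sigma2, self.n_levels))
        ZtWZ = H[p:, p:].copy()
        ZtWZ[np.diag_indices_from(ZtWZ)] -= self._penalty_vector(sigma2)
        M = (s[:, None] * ZtWZ) * s[None, :]
        M[np.diag_indices_from(M)] += 1.0
        _, logdet = np.linalg.slogdet(M)
        ll = f_pen + self._const - 0.5 * logdet
        return ll, phi, H, ok

    # ------------------------------------------------------------------
    def fit(
        self,
        start_var_components: dict[str, float] | None = None,
        fix_var_components: dict[str, float] | None = None,
        maxiter: int = 200,
    ) -> "GLMMResults":
        """Fit by Laplace-approximated maximum likelihood.

        ``fix_var_components`` pins every variance component (a factor
        fixed at 0 drops its random intercept); otherwise the variances
        are estimated. Non-convergence is flagged on the result, never
        silent.
        """
        if not self.groups or (
            fix_var_components is not None
            and all(fix_var_components.get(f, 0.0) == 0.0 for f in self.factor_names)
        ):
            return self._fit_plain_glm()

        if fix_var_components is not None:
            missing = set(self.factor_names) - set(fix_var_components)
            if missing:
                raise ValueError(f"fix_var_components must cover all factors, missing {missing}")
            if any(v < 0 for v in fix_var_components.values()):
                raise ValueError("variance components must be nonnegative")
            if any(v == 0.0 for v in fix_var_components.values()):
                raise NotImplementedError("mixing fixed-zero and positive components is unsupported")
            sigma2 = np.array([fix_var_components[f] for f in self.factor_names])
            ll, phi, H, ok = self._laplace_loglik(sigma2, None)
            return self._package(sigma2, ll, phi, H, converged=ok, estimated_vc=False)

        start = start_var_components or {f: 0.04 for f in self.factor_names}
        theta0 = np.log(np.sqrt([max(start.get(f, 0.04), 1e-4) for f in self.factor_names]))
        state = {"phi": None}

        def negll(theta):
            sigma2 = np.exp(2.0 * theta)
            ll, phi, _, _ = self._laplace_loglik(sigma2, state["phi"])
            state["phi"] = phi
            return -ll

        res = optimize.minimize(
            negll,
            theta0,
            method="L-BFGS-B",
            bounds=[(-6.0, 2.5)] * len(self.factor_names),
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7, "eps": 1e-5},
        )
        sigma2 = np.exp(2.0 * res.x)
        ll, phi, H, ok = self._laplace_loglik(sigma2, state["phi"])
        return self._package(sigma2, ll, phi, H, converged=bool(res.success) and ok)

    def _fit_plain_glm(self) -> "GLMMResults":
        """Ordinary binomial GLM: the zero-variance reduction of the model."""
        X = self.X
        p = X.shape[1]
        beta = self._start_phi(p, 0)[:p]
        ll_old = -np.inf
        ok = False
        H = None
        for _ in range(100):
            eta = X @ beta
            mu = special.expit(eta)
            w = self.n * mu * (1.0 - mu)
            grad = X.T @ (self.y - self.n * mu)
            H = (X * w[:, None]).T @ X
            beta = beta + np.linalg.solve(H, grad)
            ll = float(np.sum(self.y * eta - self.n * np.logaddexp(0.0, eta)))
            if abs(ll - ll_old) < 1e-11 * (1.0 + abs(ll)):
                ok = True
                break
            ll_old = ll
        eta = X @ beta
        ll = float(np.sum(self.y * eta - self.n * np.logaddexp(0.0, eta))) + self._const
        return self._package(
            np.zeros(len(self.factor_names)), ll, beta, H, converged=ok, estimated_vc=False
        )

    def _package(self, sigma2, ll, phi, H, converged, estimated_vc=True) -> "GLMMResults":
        p = self.X.shape[1]
        cov_joint = linalg.inv(H)
        cov_beta = cov_joint[:p, :p]
        k = p + (len(self.factor_names) if estimated_vc else 0)
        ranef = {}
        if len(phi) > p:
            offset = p
            for factor, n_lev in zip(self.factor_names, self.n_levels):
                ranef[factor] = pd.Series(
                    phi[offset : offset + n_lev], index=self.group_levels[factor]
                )
                offset += n_lev
        return GLMMResults(
            model=self,
            params=pd.Series(phi[:p], index=self.exog_names),
            bse=pd.Series(np.sqrt(np.diag(cov_beta)), index=self.exog_names),
            cov_beta=pd.DataFrame(cov_beta, index=self.exog_names, columns=self.exog_names),
            var_components=dict(zip(self.factor_names, sigma2)),
            llf=ll,
            k_params=k,
            converged=converged,
            random_effects=ranef,
        )


@dataclass
class GLMMResults:
    """Estimates, uncertainties, and fit diagnostics of a fitted model."""

    model: MaskMandateGLMM
    params: pd.Series
    bse: pd.Series
    cov_beta: pd.DataFrame
    var_components: dict[str, float]
    llf: float
    k_params: int
    converged: bool
    random_effects: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def n_groups(self) -> dict[str, int]:
        return self.model.n_groups

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf

    @property
    def bic(self) -> float:
        return self.k_params * np.log(self.nobs) - 2.0 * self.llf

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.tvalues.values)), index=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {"low": self.params - z * self.bse, "high": self.params + z * self.bse}
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Binomial GLMM (logit link), Laplace-approximated ML",
            f"county-weeks: {self.nobs}    converged: {self.converged}",
            "groups: " + ", ".join(f"{k}={v}" for k, v in self.n_groups.items()),
            f"log-likelihood: {self.llf:.3f}   AIC: {self.aic:.3f}   BIC: {self.bic:.3f}",
            "",
            f"{'term':<14}{'estimate':>10}{'SE':>9}{'z':>8}{'p':>9}{'[0.025':>9}{'0.975]':>9}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<14}{self.params[name]:>10.4f}{self.bse[name]:>9.4f}"
                f"{self.tvalues[name]:>8.2f}{self.pvalues[name]:>9.4f}"
                f"{ci.loc[name, 'low']:>9.4f}{ci.loc[name, 'high']:>9.4f}"
            )
        lines.append("")
        lines.append("random-intercept variances:")
        for k, v in self.var_components.items():
            lines.append(f"  {k:<10}{v:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "var_components": {k: float(v) for k, v in self.var_components.items()},
            "llf": self.llf,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.nobs,
            "n_groups": self.n_groups,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# effect translations and marginal effects


def effect_per_sd(coefficient: float, delta: float) -> float:
    """Percent change in the outcome for a ``delta``-unit covariate rise.

    ``100 * (exp(coefficient * delta) - 1)``: the odds-scale percent
    change, which approximates the prevalence change for a rare outcome.
    """
    return 100.0 * (np.exp(coefficient * delta) - 1.0)


@dataclass
class MarginalEffectCurve:
    """Mandate-on minus mandate-off predicted proportion across GOP share."""

    gop_grid: np.ndarray
    effect: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gop_vote_2016": self.gop_grid,
                "effect": self.effect,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def marginal_effect_curve(
    results: GLMMResults, gop_grid, ci_level: float = 0.95
) -> MarginalEffectCurve:
    """Response-scale mandate effect at each GOP vote share on the grid.

    Other covariates are held at their fitted-sample means and random
    effects at zero; the confidence band comes from the delta method on
    the difference of the two predicted proportions.
    """
    names = list(results.params.index)
    if "mandate_gop" not in names:
        raise ValueError("marginal_effect_curve requires the interaction model")
    if not results.converged:
        raise ValueError("fit did not converge; marginal effects unavailable")
    means = results.model.X.mean(axis=0)
    beta = results.params.values
    cov = results.cov_beta.values
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    i_m, i_g, i_mg = names.index("mandate"), names.index("gop"), names.index("mandate_gop")

    grid = np.asarray(gop_grid, dtype=float)
    eff = np.empty_like(grid)
    lo = np.empty_like(grid)
    hi = np.empty_like(grid)
    for j, g in enumerate(grid):
        x0, x1 = means.copy(), means.copy()
        x0[[i_m, i_mg]] = 0.0
        x1[i_m] = 1.0
        x0[i_g] = x1[i_g] = g
        x1[i_mg] = g
        p0, p1 = special.expit(x0 @ beta), special.expit(x1 @ beta)
        eff[j] = p1 - p0
        grad = p1 * (1 - p1) * x1 - p0 * (1 - p0) * x0
        se = np.sqrt(grad @ cov @ grad)
        lo[j], hi[j] = eff[j] - z * se, eff[j] + z * se
    return MarginalEffectCurve(gop_grid=grid, effect=eff, ci_low=lo, ci_high=hi)


def compare_models(fits: dict[str, GLMMResults]) -> pd.DataFrame:
    """AIC/BIC/log-likelihood comparison of fits on the same data."""
    n_obs = {name: f.nobs for name, f in fits.items()}
    if len(set(n_obs.values())) > 1:
        raise ValueError(f"fits are not on identical data: n_obs = {n_obs}")
    table = pd.DataFrame(
        {
            "k": {n: f.k_params for n, f in fits.items()},
            "loglik": {n: f.llf for n, f in fits.items()},
            "aic": {n: f.aic for n, f in fits.items()},
            "bic": {n: f.bic for n, f in fits.items()},
        }
    )
    table["preferred"] = table["aic"] == table["aic"].min()
    return table


# ---------------------------------------------------------------------------
# parameter-recovery simulation study


@dataclass
class RecoveryReport:
    """Bias, spread, and CI coverage of refitted generator coefficients."""

    table: pd.DataFrame  # per-coefficient summary
    estimates: pd.DataFrame  # replicate × coefficient point estimates
    std_errors: pd.DataFrame
    var_component_means: dict[str, float]
    n_replicates: int
    n_nonconverged: int

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="index"),
            "var_component_means": self.var_component_means,
            "n_replicates": self.n_replicates,
            "n_nonconverged": self.n_nonconverged,
        }


def recovery_study(
    generator_params: GeneratorParams,
    n_replicates: int,
    seed: int,
    interaction: bool = True,
    ci_level: float = 0.95,
) -> RecoveryReport:
    """Simulate panels, refit the GLMM, and summarize estimator behavior.

    Per replicate: draw a fresh county-week panel from the generator's
    logit-linear model, fit the interaction (or main-effects) GLMM, and
    record estimates and standard errors. The report gives, per
    coefficient: the generating value, mean estimate, bias, empirical SE,
    mean model SE, and the fraction of nominal-level Wald intervals
    covering the truth. Non-convergent replicates are counted and excluded
    from the summaries.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)

    est_rows, se_rows, vc_rows = [], [], []
    n_bad = 0
    for s in rep_seeds:
        params = replace(generator_params, seed=int(s))
        panel = simulate_panel(params)
        model = MaskMandateGLMM.from_panel(panel, interaction=interaction)
        res = model.fit()
        if not res.converged:
            n_bad += 1
            continue
        est_rows.append(res.params)
        se_rows.append(res.bse)
        vc_rows.append(pd.Series(res.var_components))

    estimates = pd.DataFrame(est_rows).reset_index(drop=True)
    std_errors = pd.DataFrame(se_rows).reset_index(drop=True)
    truth = pd.Series(
        {k: v for k, v in generator_params.betas.items() if k in estimates.columns}
    )[estimates.columns]
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    covered = (estimates - z * std_errors <= truth) & (truth <= estimates + z * std_errors)
    table = pd.DataFrame(
        {
            "true": truth,
            "mean_estimate": estimates.mean(),
            "bias": estimates.mean() - truth,
            "empirical_se": estimates.std(ddof=1),
            "mean_model_se": std_errors.mean(),
            "coverage": covered.mean(),
        }
    )
    return RecoveryReport(
        table=table,
        estimates=estimates,
        std_errors=std_errors,
        var_component_means=pd.DataFrame(vc_rows).mean().to_dict(),
        n_replicates=n_replicates,
        n_nonconverged=n_bad,
    )
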