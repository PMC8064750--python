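"""Inference layer: random-slope linear mixed models, least-square-means
post hocs with Holm-Bonferroni adjustment, and a normality-gated test
chooser.

The central model, for a response Y measured repeatedly within animals,
with laser state L ∈ {0,1} and genotype/virus group G ∈ {0,1}:

    Y_i = b0 + R0a + (b1 + R1a)·L + b2·G [+ b3·L·G] + e_i

where (R0a, R1a) are animal-specific random corrections to intercept and
laser slope, jointly normal with zero mean, and e_i is i.i.d. Gaussian
noise.  Repeated, unbalanced sampling within animals is what motivates the
mixed model over ordinary regression.  The group-by-laser interaction term
is included by default (it carries the question "does the laser do more in
the opsin-expressing group?"); ``interaction=False`` gives the additive
model.

Fitting is by REML through :class:`statsmodels` MixedLM.  Degrees of
freedom for t/F tests use the Satterthwaite approximation, implemented
here on top of the fitted variance parameters (statsmodels does not
provide it): the df of a contrast c is

    nu = 2·[c' C(θ̂) c]² / (g' A g),

with C(θ) the fixed-effects covariance as a function of the variance
parameters θ, g its gradient in θ, and A the asymptotic covariance of θ̂
from the numerical Hessian of the REML criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelSpec",
    "ModelFit",
    "PosthocResult",
    "fit_lmm",
    "posthoc_lsmeans",
    "laser_within_group_contrasts",
    "choose_test",
    "dunn_posthoc",
    "holm_adjust",
    "colabel_proportion",
]


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response column, transform, and model structure."""

    response: str
    transform: Literal["identity", "log"] = "identity"
    interaction: bool = True
    random_slope: bool = True
    laser_col: str = "laser"
    group_col: str = "group"
    animal_col: str = "animal"


@dataclass
class ModelFit:
    spec: ModelSpec
    param_names: list[str]
    beta: np.ndarray
    cov_beta: np.ndarray
    random_sd: dict[str, float]
    sigma: float
    satterthwaite_df: dict[str, float]
    tests: dict[str, dict]  # per fixed effect: F, df_num, df_den, p
    converged: bool
    singular: bool
    n_obs: int
    n_animals: int
    notes: list[str] = field(default_factory=list)
    _design: dict = field(default_factory=dict, repr=False)

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_beta))
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": se,
                "df": [self.satterthwaite_df[p] for p in self.param_names],
                "t": self.beta / se,
                "p": [self.tests[p]["p"] for p in self.param_names],
            },
            index=self.param_names,
        )

    def confint(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Wald CI with Satterthwaite df for one fixed effect."""
        j = self.param_names.index(name)
        se = float(np.sqrt(self.cov_beta[j, j]))
        tcrit = sps.t.ppf(0.5 + level / 2, self.satterthwaite_df[name])
        return self.beta[j] - tcrit * se, self.beta[j] + tcrit * se

    def residual_diagnostics(self) -> dict:
        """Linear-model assumption checks on the residuals.

        Returns the residual mean, the Pearson correlation with fitted
        values, and a Breusch-Pagan heteroscedasticity p-value (residual
        variance regressed on fitted values).  A failing check (strong
        heteroscedasticity, p < 0.05) on an identity-scale fit of a
        multiplicative response is the signal to switch to the log model.
        """
        resid = self._design["resid"]
        fitted = self._design["fitted"]
        r = float(np.corrcoef(resid, fitted)[0, 1]) if resid.std() > 0 else 0.0
        from statsmodels.stats.diagnostic import het_breuschpagan

        bp = het_breuschpagan(resid, np.column_stack([np.ones_like(fitted), fitted]))
        return {
            "resid_mean": float(resid.mean()),
            "corr_with_fitted": r,
            "breusch_pagan_p": float(bp[1]),
        }


@dataclass
class PosthocResult:
    contrast: str
    estimate: float
    se: float
    t: float
    df: float
    p_raw: float
    p_adjusted: float


def _build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    y = np.asarray(data[spec.response], dtype=float)
    if spec.transform == "log":
        if np.any(y <= 0):
            raise ValueError(
                "log transform requires strictly positive responses; add an "
                "offset to zero rates or use the identity model"
            )
        y = np.log(y)
    L = np.asarray(data[spec.laser_col], dtype=float)
    G = np.asarray(data[spec.group_col], dtype=float)
    if set(np.unique(L)) - {0.0, 1.0} or set(np.unique(G)) - {0.0, 1.0}:
        raise ValueError("laser and group must be coded 0/1")
    names = ["Intercept", "laser"]
    cols = [np.ones_like(y), L]
    notes: list[str] = []
    if np.unique(G).size > 1:
        names.append("group")
        cols.append(G)
        if spec.interaction:
            names.append("laser:group")
            cols.append(L * G)
    else:
        notes.append("group constant; group and interaction terms dropped")
    X = np.column_stack(cols)
    groups = np.asarray(data[spec.animal_col])
    return y, X, L, groups, names, notes


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """REML fit of the random-intercept(+slope) model.

    Requires at least two animals, and two observations per animal for
    slope estimation.  A laser column with a single level makes the laser
    effect inestimable and raises.  Near-zero random-effect variance is
    reported through the ``singular`` flag rather than silently refitting
    a simpler model.
    """
    y, X, L, groups, names, notes = _build_design(data, spec)
    if np.unique(L).size < 2:
        raise ValueError("laser takes a single level; its effect is inestimable")
    uniq = pd.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least 2 animals")

    exog_re = np.column_stack([np.ones_like(L), L]) if spec.random_slope else None
    model = MixedLM(y, X, groups=groups, exog_re=exog_re)
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(reml=True, method=["lbfgs", "bfgs"], maxiter=200)
    boundary_warned = any(
        "boundary" in str(w.message) or "Hessian" in str(w.message) for w in caught
    )

    G_hat = np.atleast_2d(np.asarray(res.cov_re))
    sigma2 = float(res.scale)
    beta = np.asarray(res.fe_params, dtype=float)

    # Boundary fits (vanishing variance or |correlation| -> 1) leave the
    # REML surface flat along some direction, which invalidates the
    # Satterthwaite curvature; flag them and fall back to between-animal
    # df instead of reporting a spuriously tiny df.
    eigs = np.linalg.eigvalsh(G_hat)
    singular = boundary_warned or bool(eigs.min() < 1e-4 * max(eigs.max(), sigma2))
    if G_hat.shape[0] == 2 and G_hat[0, 0] > 0 and G_hat[1, 1] > 0:
        corr = G_hat[0, 1] / np.sqrt(G_hat[0, 0] * G_hat[1, 1])
        singular = singular or abs(corr) > 0.95

    per_group = _split_groups(y, X, exog_re, groups)
    theta = _pack_theta(sigma2, G_hat)
    resid_df = max(y.size - X.shape[1] - (uniq.size - 1), 2)
    fallback_df = float(max(uniq.size - 2, 1)) if singular else float(resid_df)
    try:
        # Degenerate (zero-variance) fits make V singular; fall back to
        # the statsmodels covariance and between-animal df below.
        C, _ = _beta_cov(theta, per_group, G_hat.shape[0])
        A = _theta_cov(theta, per_group, G_hat.shape[0]) if not singular else None
    except np.linalg.LinAlgError:
        C = np.asarray(res.cov_params())[: len(names), : len(names)]
        A = None

    sat_df: dict[str, float] = {}
    tests: dict[str, dict] = {}
    for j, name in enumerate(names):
        c = np.zeros(len(names))
        c[j] = 1.0
        if A is None:
            df = fallback_df
        else:
            df = _satterthwaite_df(c, theta, per_group, G_hat.shape[0], A)
        if not np.isfinite(df) or df <= 0:
            df = fallback_df
        sat_df[name] = df
        tstat = beta[j] / np.sqrt(C[j, j])
        tests[name] = {
            "F": float(tstat**2),
            "df_num": 1,
            "df_den": df,
            "p": float(2 * sps.t.sf(abs(tstat), df)),
        }

    random_sd = {"animal(Intercept)": float(np.sqrt(max(G_hat[0, 0], 0.0)))}
    if spec.random_slope:
        random_sd["animal(laser)"] = float(np.sqrt(max(G_hat[1, 1], 0.0)))

    return ModelFit(
        spec=spec,
        param_names=names,
        beta=beta,
        cov_beta=C,
        random_sd=random_sd,
        sigma=float(np.sqrt(sigma2)),
        satterthwaite_df=sat_df,
        tests=tests,
        converged=bool(res.converged),
        singular=singular,
        n_obs=int(y.size),
        n_animals=int(uniq.size),
        notes=notes,
        _design={
            "per_group": per_group,
            "theta": theta,
            "k_re": G_hat.shape[0],
            "A": A,
            "fallback_df": fallback_df,
            "fitted": np.asarray(res.fittedvalues, dtype=float),
            "resid": np.asarray(res.resid, dtype=float),
        },
    )


# ---------------------------------------------------------------------------
# Satterthwaite machinery: REML criterion, covariance in theta, df.


def _split_groups(y, X, exog_re, groups):
    out = []
    for g in pd.unique(groups):
        idx = groups == g
        Z = exog_re[idx] if exog_re is not None else np.ones((idx.sum(), 1))
        out.append((y[idx], X[idx], Z))
    return out


def _pack_theta(sigma2: float, G: np.ndarray) -> np.ndarray:
    k = G.shape[0]
    vech = [G[i, j] for i in range(k) for j in range(i + 1)]
    return np.array([sigma2] + vech)


def _unpack_theta(theta: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    sigma2 = theta[0]
    G = np.zeros((k, k))
    pos = 1
    for i in range(k):
        for j in range(i + 1):
            G[i, j] = G[j, i] = theta[pos]
            pos += 1
    return float(sigma2), G


def _beta_cov(theta, per_group, k) -> tuple[np.ndarray, list]:
    sigma2, G = _unpack_theta(theta, k)
    p = per_group[0][1].shape[1]
    XtVinvX = np.zeros((p, p))
    solves = []
    for yg, Xg, Zg in per_group:
        V = sigma2 * np.eye(len(yg)) + Zg @ G @ Zg.T
        Vinv_X = np.linalg.solve(V, Xg)
        XtVinvX += Xg.T @ Vinv_X
        solves.append((V, Vinv_X))
    return np.linalg.inv(XtVinvX), solves


def _reml_loglike(theta, per_group, k) -> float:
    sigma2, G = _unpack_theta(theta, k)
    if sigma2 <= 0:
        return -np.inf
    eigs = np.linalg.eigvalsh(G)
    if eigs.min() < -1e-10:
        return -np.inf
    p = per_group[0][1].shape[1]
    XtVinvX = np.zeros((p, p))
    XtVinvy = np.zeros(p)
    logdet = 0.0
    pieces = []
    for yg, Xg, Zg in per_group:
        V = sigma2 * np.eye(len(yg)) + Zg @ G @ Zg.T
        sign, ld = np.linalg.slogdet(V)
        if sign <= 0:
            return -np.inf
        logdet += ld
        Vinv_X = np.linalg.solve(V, Xg)
        Vinv_y = np.linalg.solve(V, yg)
        XtVinvX += Xg.T @ Vinv_X
        XtVinvy += Xg.T @ Vinv_y
        pieces.append((yg, Xg, Vinv_y, Vinv_X))
    beta = np.linalg.solve(XtVinvX, XtVinvy)
    quad = 0.0
    for yg, Xg, Vinv_y, Vinv_X in pieces:
        r = yg - Xg @ beta
        quad += r @ (Vinv_y - Vinv_X @ beta)
    sign, ld_fe = np.linalg.slogdet(XtVinvX)
    return -0.5 * (logdet + quad + ld_fe)


def _theta_cov(theta, per_group, k) -> np.ndarray:
    """Asymptotic covariance of the variance parameters: inverse negative
    Hessian of the REML criterion, by central finite differences."""
    m = theta.size
    h = np.maximum(1e-4 * np.abs(theta), 1e-8)
    H = np.zeros((m, m))
    f0 = _reml_loglike(theta, per_group, k)

    def f(t):
        v = _reml_loglike(t, per_group, k)
        return v if np.isfinite(v) else f0

    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m)
            ej = np.zeros(m)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej)
                    - f(theta + ei - ej)
                    - f(theta - ei + ej)
                    + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        return np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(-H)


def _satterthwaite_df(c, theta, per_group, k, A) -> float:
    def fvar(t):
        try:
            C, _ = _beta_cov(t, per_group, k)
        except np.linalg.LinAlgError:
            return np.nan
        return float(c @ C @ c)

    f0 = fvar(theta)
    if not np.isfinite(f0):
        return np.inf
    m = theta.size
    g = np.zeros(m)
    h = np.maximum(1e-4 * np.abs(theta), 1e-8)
    for i in range(m):
        e = np.zeros(m)
        e[i] = h[i]
        g[i] = (fvar(theta + e) - fvar(theta - e)) / (2 * h[i])
    denom = float(g @ A @ g)
    if not np.isfinite(denom) or denom <= 0:
        return np.inf
    return 2.0 * f0**2 / denom


# ---------------------------------------------------------------------------
# Post hoc least-square means.


def laser_within_group_contrasts(fit: ModelFit) -> dict[str, np.ndarray]:
    """Laser-on minus laser-off least-square-mean contrast per group."""
    names = fit.param_names

    def row(laser, group):
        r = np.zeros(len(names))
        for j, nm in enumerate(names):
            r[j] = {
                "Intercept": 1.0,
                "laser": laser,
                "group": group,
                "laser:group": laser * group,
            }[nm]
        return r

    out = {"laser within group=0": row(1, 0) - row(0, 0)}
    if "group" in names:
        out["laser within group=1"] = row(1, 1) - row(0, 1)
    return out


def posthoc_lsmeans(
    fit: ModelFit, contrasts: dict[str, np.ndarray] | None = None
) -> list[PosthocResult]:
    """Least-square-mean differences with Satterthwaite df, Holm-adjusted.

    ``contrasts`` maps a label to a coefficient vector on the fixed-effect
    design; by default the laser effect is tested within each group.  The
    Holm family is the supplied set of contrasts.
    """
    if contrasts is None:
        contrasts = laser_within_group_contrasts(fit)
    p = len(fit.param_names)
    results = []
    for label, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        if c.size != p:
            raise ValueError(
                f"contrast {label!r} has {c.size} elements for {p} coefficients"
            )
        est = float(c @ fit.beta)
        se = float(np.sqrt(c @ fit.cov_beta @ c))
        if fit._design.get("A") is None:
            df = fit._design.get("fallback_df", float(fit.n_obs - p))
        else:
            df = _satterthwaite_df(
                c,
                fit._design["theta"],
                fit._design["per_group"],
                fit._design["k_re"],
                fit._design["A"],
            )
        if not np.isfinite(df) or df <= 0:
            df = fit._design.get("fallback_df", float(fit.n_obs - p))
        t = est / se
        results.append(
            PosthocResult(label, est, se, t, df, float(2 * sps.t.sf(abs(t), df)), np.nan)
        )
    adj = holm_adjust([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
    return results


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]


# ---------------------------------------------------------------------------
# Normality-gated simple tests.


def choose_test(
    samples: Sequence[np.ndarray], paired: bool = False, alpha_normality: float = 0.05
) -> dict:
    """Shapiro-Wilk-gated dispatch between parametric and rank tests.

    Every group must pass Shapiro-Wilk at p > ``alpha_normality`` for the
    parametric branch (t-test / one-way ANOVA); otherwise the rank branch
    (Wilcoxon or Mann-Whitney for two groups, Kruskal-Wallis for more,
    followed by a Dunn post hoc with Holm-Bonferroni correction).
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) < 3 for s in samples):
        raise ValueError("need at least 3 observations per group")
    if paired and len({len(s) for s in samples}) != 1:
        raise ValueError("paired groups must have equal sizes")

    if paired and len(samples) == 2:
        shapiro_targets = [samples[0] - samples[1]]
    else:
        shapiro_targets = samples
    shapiro_p = [float(sps.shapiro(s).pvalue) for s in shapiro_targets]
    normal = all(p > alpha_normality for p in shapiro_p)

    out = {"shapiro_p": shapiro_p, "normal": normal, "posthoc": None}
    if normal:
        if len(samples) == 2:
            if paired:
                stat, p = sps.ttest_rel(samples[0], samples[1])
                out["test"] = "paired t-test"
            else:
                stat, p = sps.ttest_ind(samples[0], samples[1])
                out["test"] = "t-test"
        else:
            stat, p = sps.f_oneway(*samples)
            out["test"] = "one-way ANOVA"
    else:
        if len(samples) == 2:
            if paired:
                stat, p = sps.wilcoxon(samples[0], samples[1])
                out["test"] = "Wilcoxon signed-rank"
            else:
                stat, p = sps.mannwhitneyu(samples[0], samples[1])
                out["test"] = "Mann-Whitney U"
        else:
            stat, p = sps.kruskal(*samples)
            out["test"] = "Kruskal-Wallis (ANOVA on ranks)"
            if p < 0.05:
                out["posthoc"] = dunn_posthoc(samples)
    out["statistic"] = float(stat)
    out["p"] = float(p)
    return out


def dunn_posthoc(samples: Sequence[np.ndarray]) -> list[PosthocResult]:
    """Dunn's rank-based pairwise test after Kruskal-Wallis, Holm-adjusted."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    n_tot = pooled.size
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12 * (n_tot - 1))
    var_unit = n_tot * (n_tot + 1) / 12.0 - tie_term
    mean_ranks = []
    pos = 0
    for s in samples:
        mean_ranks.append(ranks[pos : pos + s.size].mean())
        pos += s.size
    results = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            se = np.sqrt(var_unit * (1 / samples[i].size + 1 / samples[j].size))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            results.append(
                PosthocResult(
                    f"group{i} vs group{j}",
                    float(mean_ranks[i] - mean_ranks[j]),
                    float(se),
                    float(z),
                    np.inf,
                    float(2 * sps.norm.sf(abs(z))),
                    np.nan,
                )
            )
    adj = holm_adjust([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
    return results


def colabel_proportion(n_double: int, n_total: int) -> tuple[int, float]:
    """Immunostaining co-labeling proportion, e.g. YFP+ among ChAT+ cells.

    Returns ``(percent rounded to integer, raw percent)``.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_double <= n_total:
        raise ValueError("need 0 <= n_double <= n_total")
    raw = 100.0 * n_double / n_total
    return int(round(raw)), raw
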