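"""Multilevel moderated mediation of sickness effects on skill outcomes.

The causal question: does simulator-sickness severity (X, total SSQ score)
depress the physical-examination score (Y) partly *through* an autonomic
response — the very-low-frequency HRV power in the late learning epoch
(M, VLF 6–10 min) — and does frustration (W) modulate that transmitted
effect?

All legs are Gaussian linear mixed models estimated by maximum likelihood
(not REML, so deviance differences between nested fits form valid
likelihood-ratio statistics):

    total    Y ~ X            (+ random intercept by cluster)
    a-path   M ~ X
    b-path   Y ~ X + M        (X coefficient here is the direct effect c')
    moderation  Y ~ X + M + W (+ M:W when estimable)

Mediation inference is by joint significance of the a and b paths at
two-sided p < .05; a cluster-resampling bootstrap for the indirect effect
a*b is available as an optional extra.  Variance components are summarised
by ICC(1,1) = var_between / (var_between + var_within), and nested model
comparisons by the deviance difference against a chi-squared(1) reference
(5 % point 3.84).  A 50:50 chi-squared mixture is the modern recommendation
for a variance-component test on the boundary; the plain chi-squared(1)
reference is kept as the default convention here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss
import statsmodels.api as sm

from .errors import InvalidParameterError, ZeroVarianceError

MULTILEVEL_ALPHA = 0.05


def normalize(x) -> np.ndarray:
    """z-score a column: (x - mean) / SD with the n-1 sample SD."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise InvalidParameterError("normalize needs n >= 2")
    sd = np.std(x, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ZeroVarianceError("cannot normalize a zero-variance column")
    return (x - np.mean(x)) / sd


def icc_1_1(var_between: float, var_within: float) -> float:
    """ICC(1,1): share of total variance attributable to clusters."""
    if var_between < 0 or var_within < 0:
        raise InvalidParameterError("variance components must be non-negative")
    total = var_between + var_within
    if total == 0:
        raise InvalidParameterError("variance components sum to zero")
    return var_between / total


@dataclass
class LRTResult:
    lr_statistic: float
    df: int
    critical_value_05: float
    p: float
    clamped: bool = False


def lrt(deviance_null: float, deviance_alt: float, df: int = 1) -> LRTResult:
    """Likelihood-ratio test from the deviances of two nested ML fits."""
    if not (np.isfinite(deviance_null) and np.isfinite(deviance_alt)):
        raise InvalidParameterError("deviances must be finite")
    stat = deviance_null - deviance_alt
    clamped = stat < 0
    stat = max(stat, 0.0)
    return LRTResult(lr_statistic=stat, df=df,
                     critical_value_05=float(ss.chi2.ppf(0.95, df)),
                     p=float(ss.chi2.sf(stat, df)), clamped=clamped)


@dataclass
class MixedModelFit:
    """Results of one maximum-likelihood linear mixed-model fit."""

    outcome: str
    fixed_effects: dict[str, tuple[float, float, float]]  # name -> (est, se, p)
    var_between: float
    var_within: float
    deviance: float
    model_kind: str  # random_intercept | random_slope
    converged: bool
    boundary: bool = False
    n_obs: int = 0
    n_clusters: int = 0

    @property
    def icc(self) -> float:
        return icc_1_1(self.var_between, self.var_within)

    def coef(self, name: str) -> tuple[float, float, float]:
        return self.fixed_effects[name]

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "fixed_effects": {k: {"estimate": v[0], "se": v[1], "p": v[2]}
                              for k, v in self.fixed_effects.items()},
            "var_between": self.var_between,
            "var_within": self.var_within,
            "icc": self.icc,
            "deviance": self.deviance,
            "model_kind": self.model_kind,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
        }


def _marginal_loglik(endog: np.ndarray, exog: np.ndarray, codes: np.ndarray,
                     exog_re: np.ndarray, beta: np.ndarray,
                     cov_re: np.ndarray, scale: float) -> float:
    """Gaussian LMM marginal log-likelihood at given parameters.

    Per cluster g: y_g ~ N(X_g beta, Z_g G Z_g' + scale I).
    """
    ll = 0.0
    for g in np.unique(codes):
        idx = codes == g
        r = endog[idx] - exog[idx] @ beta
        Z = exog_re[idx]
        V = Z @ cov_re @ Z.T + scale * np.eye(idx.sum())
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            return -np.inf
        ll += -0.5 * (idx.sum() * np.log(2 * np.pi) + logdet
                      + r @ np.linalg.solve(V, r))
    return float(ll)


def _gls_cov_beta(exog: np.ndarray, codes: np.ndarray, exog_re: np.ndarray,
                  cov_re: np.ndarray, scale: float) -> np.ndarray:
    """Fixed-effect covariance (X' V^-1 X)^-1 at given variance components."""
    A = np.zeros((exog.shape[1], exog.shape[1]))
    for g in np.unique(codes):
        idx = codes == g
        Z = exog_re[idx]
        V = Z @ cov_re @ Z.T + scale * np.eye(idx.sum())
        A += exog[idx].T @ np.linalg.solve(V, exog[idx])
    return np.linalg.inv(A)


def fit_mixed(data: pd.DataFrame, outcome: str, fixed_terms: list[str],
              grouping: str, random_slope: str | None = None) -> MixedModelFit:
    """Fit a random-intercept (or random-slope) linear mixed model by ML.

    ``fixed_terms`` are column names entering the fixed part with an
    intercept always included.  ``random_slope`` names a column whose slope
    varies by cluster in addition to the intercept.  The residual variance is
    reported as ``var_within`` and the random-intercept variance as
    ``var_between``; a near-zero ``var_between`` sets the ``boundary`` flag.
    """
    cols = [outcome, grouping, *fixed_terms]
    if random_slope is not None:
        cols.append(random_slope)
    df = data[list(dict.fromkeys(cols))].dropna()
    groups = df[grouping]
    if groups.nunique() < 2:
        raise InvalidParameterError("need at least 2 clusters")
    endog = df[outcome].to_numpy(dtype=float)
    exog = sm.add_constant(df[list(fixed_terms)].to_numpy(dtype=float)
                           if fixed_terms else np.empty((len(df), 0)))
    names = ["const", *fixed_terms]
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise InvalidParameterError("fixed-effect design is rank deficient")
    if random_slope is None:
        exog_re = np.ones((len(df), 1))
        kind = "random_intercept"
    else:
        exog_re = np.column_stack([np.ones(len(df)),
                                   df[random_slope].to_numpy(dtype=float)])
        kind = "random_slope"
    codes = pd.factorize(groups)[0]
    model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
    candidates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "cg", "powell"):
            try:
                res = model.fit(reml=False, method=method, maxiter=500)
            except Exception:
                continue
            b = np.asarray(res.fe_params, dtype=float)
            G = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
            s = float(res.scale)
            if (np.all(np.isfinite(b)) and np.all(np.isfinite(G))
                    and np.isfinite(s) and s > 0):
                candidates.append((b, G, s, bool(res.converged)))
    # boundary candidate: zero random effects, ML ordinary least squares —
    # also serves as the tie-break when the split is unidentified (e.g. one
    # observation per cluster, where only var_between + var_within matters)
    b_ols, *_ = np.linalg.lstsq(exog, endog, rcond=None)
    resid = endog - exog @ b_ols
    candidates.append((b_ols, np.zeros((exog_re.shape[1], exog_re.shape[1])),
                       float(resid @ resid / len(endog)), True))
    # pick by closed-form marginal log-likelihood (robust where the
    # optimiser's Hessian is singular on the variance boundary); prefer the
    # smaller random-intercept variance on likelihood ties
    lls = [_marginal_loglik(endog, exog, codes, exog_re, b, G, s)
           for b, G, s, _ in candidates]
    best_ll = max(lls)
    tied = [i for i, ll in enumerate(lls) if ll >= best_ll - 1e-6]
    idx = min(tied, key=lambda i: float(candidates[i][1][0, 0]))
    beta, cov_re, scale, converged = candidates[idx]
    ll = _marginal_loglik(endog, exog, codes, exog_re, beta, cov_re, scale)
    cov_beta = _gls_cov_beta(exog, codes, exog_re, cov_re, scale)
    se = np.sqrt(np.diag(cov_beta))
    pvals = 2.0 * ss.norm.sf(np.abs(beta) / np.where(se > 0, se, np.inf))
    fe = {name: (float(beta[i]), float(se[i]), float(pvals[i]))
          for i, name in enumerate(names)}
    var_between = float(cov_re[0, 0])
    var_within = float(scale)
    boundary = var_between < 1e-6 * max(var_within, 1e-12)
    return MixedModelFit(outcome=outcome, fixed_effects=fe,
                         var_between=var_between, var_within=var_within,
                         deviance=float(-2.0 * ll), model_kind=kind,
                         converged=converged, boundary=boundary,
                         n_obs=len(df), n_clusters=int(groups.nunique()))


@dataclass
class PathEstimate:
    name: str
    estimate: float
    se: float
    p: float
    alpha: float = MULTILEVEL_ALPHA

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    @property
    def sign(self) -> str:
        return "positive" if self.estimate >= 0 else "inverse"

    def as_dict(self) -> dict:
        return {"estimate": self.estimate, "se": self.se, "p": self.p,
                "significant": self.significant, "sign": self.sign}


class ModeratedMediation:
    """Multilevel moderated-mediation model.

    Parameters
    ----------
    data : DataFrame with one row per observation.
    x, m, y : column names for the exposure, mediator and outcome.
    w : optional moderator column acting on the mediator->outcome leg.
    groups : column defining the clustering (nesting) structure.  For a
        participant-level table where each row is one participant the
        two-level fallback is grouping by sickness status.
    random_slope : if True the X slope varies by cluster in the outcome legs.
    standardize : z-score x, m, y (and w) before fitting (default True).
    """

    def __init__(self, data: pd.DataFrame, x: str, m: str, y: str,
                 w: str | None = None, groups: str = "ss_status",
                 random_slope: bool = False, standardize: bool = True,
                 alpha: float = MULTILEVEL_ALPHA):
        for col in filter(None, (x, m, y, w, groups)):
            if col not in data.columns:
                raise InvalidParameterError(f"column {col!r} not in data")
        self.x, self.m, self.y, self.w, self.groups = x, m, y, w, groups
        self.random_slope = random_slope
        self.alpha = alpha
        df = data[[c for c in dict.fromkeys(filter(None, (x, m, y, w, groups)))]].dropna().copy()
        if standardize:
            for col in filter(None, (x, m, y, w)):
                df[col] = normalize(df[col])
        self.data = df
        # interaction column for the moderated leg
        if w is not None:
            self.data["_m_x_w"] = self.data[m] * self.data[w]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "ModeratedMediation":
        return cls(data, **kwargs)

    def fit(self) -> "ModeratedMediationResults":
        slope = self.x if self.random_slope else None
        legs: dict[str, MixedModelFit] = {}
        flags: dict[str, str] = {}

        def _fit(name, outcome, terms, random_slope=None):
            try:
                legs[name] = fit_mixed(self.data, outcome, terms, self.groups,
                                       random_slope=random_slope)
            except Exception as exc:  # record per-leg failure, keep going
                flags[name] = f"{type(exc).__name__}: {exc}"

        _fit("total", self.y, [self.x], random_slope=slope)
        _fit("mediator", self.m, [self.x])
        _fit("outcome", self.y, [self.x, self.m], random_slope=slope)
        if self.w is not None:
            _fit("moderated", self.y, [self.x, self.m, self.w, "_m_x_w"],
                 random_slope=slope)
            if "moderated" in flags:  # interaction not estimable: drop it
                flags["moderated"] += " (refit without interaction)"
                _fit("moderated", self.y, [self.x, self.m, self.w],
                     random_slope=slope)
        return ModeratedMediationResults(self, legs, flags)


class ModeratedMediationResults:
    """Fitted paths, variance components and the mediation diagram."""

    def __init__(self, model: ModeratedMediation,
                 legs: dict[str, MixedModelFit], flags: dict[str, str]):
        self.model = model
        self.legs = legs
        self.flags = flags
        a = model.alpha
        self.paths: dict[str, PathEstimate] = {}
        if "total" in legs:
            self.paths["c"] = PathEstimate("c", *legs["total"].coef(model.x), a)
        if "mediator" in legs:
            self.paths["a"] = PathEstimate("a", *legs["mediator"].coef(model.x), a)
        if "outcome" in legs:
            self.paths["b"] = PathEstimate("b", *legs["outcome"].coef(model.m), a)
            self.paths["c_prime"] = PathEstimate(
                "c_prime", *legs["outcome"].coef(model.x), a)
        if "moderated" in legs:
            mod = legs["moderated"]
            self.paths["w"] = PathEstimate("w", *mod.coef(model.w), a)
            if "_m_x_w" in mod.fixed_effects:
                self.paths["m_x_w"] = PathEstimate("m_x_w", *mod.coef("_m_x_w"), a)

    @property
    def indirect_effect(self) -> float | None:
        if "a" in self.paths and "b" in self.paths:
            return self.paths["a"].estimate * self.paths["b"].estimate
        return None

    @property
    def mediated(self) -> bool:
        """Joint-significance test: both a and b legs significant."""
        return ("a" in self.paths and "b" in self.paths
                and self.paths["a"].significant and self.paths["b"].significant)

    @property
    def moderated(self) -> bool:
        return "m_x_w" in self.paths and self.paths["m_x_w"].significant

    def lrt_mediator(self) -> LRTResult | None:
        """Deviance test of adding the mediator to the X-only outcome model."""
        if "total" in self.legs and "outcome" in self.legs:
            return lrt(self.legs["total"].deviance, self.legs["outcome"].deviance, df=1)
        return None

    def diagram_edges(self) -> list[dict]:
        m = self.model
        name = {"c": (m.x, m.y), "c_prime": (m.x, m.y), "a": (m.x, m.m),
                "b": (m.m, m.y), "w": (m.w, m.y), "m_x_w": (f"{m.m}:{m.w}", m.y)}
        edges = []
        for key, pe in self.paths.items():
            src, dst = name[key]
            edges.append({"path": key, "from": src, "to": dst,
                          **pe.as_dict()})
        return edges

    def bootstrap_indirect(self, n_boot: int = 1000, seed: int = 0,
                           ci: float = 0.95) -> dict:
        """Cluster-resampling bootstrap CI for the indirect effect a*b.

        Clusters are resampled with replacement and the a and b legs refitted
        by ordinary least squares within each resample (the point estimates
        of the fixed effects, which is what the product uses, agree with the
        mixed fit up to cluster weighting); this keeps the bootstrap tractable.
        """
        rng = np.random.default_rng(seed)
        df = self.model.data
        clusters = df[self.model.groups].unique()
        vals = []
        for _ in range(n_boot):
            chosen = rng.choice(clusters, size=len(clusters), replace=True)
            boot = pd.concat([df[df[self.model.groups] == c] for c in chosen])
            xa = sm.add_constant(boot[[self.model.x]].to_numpy())
            a_hat = np.linalg.lstsq(xa, boot[self.model.m].to_numpy(), rcond=None)[0][1]
            xb = sm.add_constant(boot[[self.model.x, self.model.m]].to_numpy())
            b_hat = np.linalg.lstsq(xb, boot[self.model.y].to_numpy(), rcond=None)[0][2]
            vals.append(a_hat * b_hat)
        lo, hi = np.quantile(vals, [(1 - ci) / 2, 1 - (1 - ci) / 2])
        return {"indirect": self.indirect_effect, "ci_low": float(lo),
                "ci_high": float(hi), "n_boot": n_boot}

    def summary(self) -> str:
        m = self.model
        lines = [
            "Multilevel moderated mediation (ML linear mixed models)",
            f"  X={m.x}  M={m.m}  Y={m.y}  W={m.w}  groups={m.groups}",
            f"  n_obs={len(m.data)}  clusters={m.data[m.groups].nunique()}",
            "",
            f"  {'path':<10}{'estimate':>10}{'SE':>9}{'p':>9}",
        ]
        for key, pe in self.paths.items():
            star = "*" if pe.significant else ""
            lines.append(f"  {key:<10}{pe.estimate:>10.3f}{pe.se:>9.3f}"
                         f"{pe.p:>9.3f}{star}")
        ind = self.indirect_effect
        if ind is not None:
            lines.append(f"  indirect (a*b) = {ind:.3f}  "
                         f"mediated={self.mediated}  moderated={self.moderated}")
        for name, leg in self.legs.items():
            lines.append(f"  [{name}] deviance={leg.deviance:.3f} "
                         f"ICC={leg.icc:.3f} kind={leg.model_kind}")
        lr = self.lrt_mediator()
        if lr is not None:
            lines.append(f"  LRT mediator: {lr.lr_statistic:.3f} vs "
                         f"chi2(1) 5% point {lr.critical_value_05:.2f} (p={lr.p:.3f})")
        for name, msg in self.flags.items():
            lines.append(f"  ! {name}: {msg}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        out = {
            "paths": {k: v.as_dict() for k, v in self.paths.items()},
            "indirect_effect": self.indirect_effect,
            "mediated": self.mediated,
            "moderated": self.moderated,
            "legs": {k: v.as_dict() for k, v in self.legs.items()},
            "flags": self.flags,
            "edges": self.diagram_edges(),
        }
        lr = self.lrt_mediator()
        if lr is not None:
            out["lrt_mediator"] = {
                "lr_statistic": lr.lr_statistic, "df": lr.df,
                "critical_value_05": lr.critical_value_05, "p": lr.p,
            }
        return out

    def plot_diagram(self, ax=None):
        """Draw the X/M/Y/W path diagram with signed, significance-styled edges."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        m = self.model
        pos = {m.x: (0.05, 0.35), m.m: (0.5, 0.8), m.y: (0.95, 0.35)}
        if m.w:
            pos[m.w] = (0.72, 0.8)
        for label, (px, py) in pos.items():
            ax.annotate(label, (px, py), ha="center", va="center",
                        bbox=dict(boxstyle="round", fc="white"))
        arrows = {"a": (m.x, m.m), "b": (m.m, m.y), "c_prime": (m.x, m.y)}
        if m.w and "w" in self.paths:
            arrows["w"] = (m.w, m.y)
        for key, (src, dst) in arrows.items():
            if key not in self.paths:
                continue
            pe = self.paths[key]
            ax.annotate(
                "", xy=pos[dst], xytext=pos[src],
                arrowprops=dict(arrowstyle="->",
                                color="red" if pe.estimate >= 0 else "black",
                                linestyle="-" if pe.significant else "--"))
            mid = ((pos[src][0] + pos[dst][0]) / 2, (pos[src][1] + pos[dst][1]) / 2)
            ax.annotate(f"{pe.estimate:.2f}", mid, fontsize=8, color="gray")
        ax.set_axis_off()
        return ax


def moderated_mediation(cohort: pd.DataFrame, x: str, m: str, y: str,
                        w: str | None = None, grouping: str = "ss_status",
                        random_slope: bool = False) -> ModeratedMediationResults:
    """Convenience wrapper: build and fit a :class:`ModeratedMediation`."""
    return ModeratedMediation(cohort, x=x, m=m, y=y, w=w, groups=grouping,
                              random_slope=random_slope).fit()


def simulate_mediation_data(n_clusters: int, obs_per_cluster: int,
                            a: float, b: float, c_prime: float = 0.0,
                            w_effect: float = 0.0, interaction: float = 0.0,
                            var_between: float = 0.5, var_within: float = 1.0,
                            seed: int = 0) -> pd.DataFrame:
    """Generate clustered data with known mediation path coefficients.

    X and W are standard-normal; M = a*X + u_m; Y = c'*X + b*M + w_effect*W
    + interaction*M*W + cluster intercept + residual, with the cluster
    intercept variance ``var_between`` and residual variance ``var_within``.
    """
    rng = np.random.default_rng(seed)
    n = n_clusters * obs_per_cluster
    cluster = np.repeat(np.arange(n_clusters), obs_per_cluster)
    u_y = rng.normal(0, np.sqrt(var_between), n_clusters)[cluster]
    u_m = rng.normal(0, np.sqrt(var_between), n_clusters)[cluster]
    x = rng.normal(size=n)
    w = rng.normal(size=n)
    m = a * x + u_m + rng.normal(0, np.sqrt(var_within), n)
    y = (c_prime * x + b * m + w_effect * w + interaction * m * w
         + u_y + rng.normal(0, np.sqrt(var_within), n))
    return pd.DataFrame({"cluster": cluster, "x": x, "m": m, "y": y, "w": w})
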