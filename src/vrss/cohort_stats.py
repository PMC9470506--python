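"""Normality-gated descriptive and inferential statistics for the cohort.

The battery mirrors common practice in small clinical-education cohorts:

* D'Agostino–Pearson omnibus test decides "normal" vs "skewed" per sample.
* Group comparisons route to t tests for normal data and to Mann–Whitney U
  (unpaired) or Wilcoxon signed-rank (paired) otherwise.
* One-sample comparisons against a reference value (the NASA-TLX midpoint
  of 10) follow the same gating.
* Associations use Spearman rank correlation, or point-biserial when exactly
  one variable is dichotomous.
* Categorical 2x2 contrasts use Fisher's exact test.

All p-values are two-sided.  The correlation screen records significance at
p < .01 (a deliberately strict threshold in lieu of a formal multiplicity
correction); the multilevel stage uses .05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss

from .errors import InvalidParameterError, ValidationError, ZeroVarianceError

SCREEN_ALPHA = 0.01
MULTILEVEL_ALPHA = 0.05
#: exact Mann-Whitney null below this per-group size (no ties), else asymptotic
MW_EXACT_MAX_N = 10


@dataclass
class ComparisonResult:
    variable: str
    groups: tuple[str, str]
    test_name: str
    statistic: float
    p_two_sided: float
    summary: dict[str, dict]
    paired: bool
    alpha: float = SCREEN_ALPHA
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_two_sided < self.alpha


@dataclass
class CorrelationResult:
    var_x: str
    var_y: str
    method: str
    r: float | None
    p_two_sided: float | None
    n: int
    degenerate: bool = False
    alpha: float = SCREEN_ALPHA

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_two_sided < self.alpha


def normality_gate(x) -> str:
    """Return ``"normal"`` or ``"skewed"`` via the D'Agostino–Pearson K² test.

    Samples smaller than 8 (where the omnibus test is undefined) and
    zero-variance samples are forced to "skewed".  The decision threshold is
    p >= .05 for normality.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 8 or np.ptp(x) == 0:
        return "skewed"
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = ss.normaltest(x)
    return "normal" if p >= 0.05 else "skewed"


def describe(x, route: str | None = None) -> dict:
    """Summarise a sample: mean +/- SD if normal, median [IQR] if skewed.

    IQR bounds are the 25th/75th percentiles with linear interpolation.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise InvalidParameterError("cannot describe an empty sample")
    if route is None:
        route = normality_gate(x)
    out = {"n": len(x), "route": route}
    if route == "normal":
        out["mean"] = float(np.mean(x))
        out["sd"] = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        out["display"] = f"{out['mean']:.1f} ± {out['sd']:.1f}"
    else:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        out.update(median=float(med), q1=float(q1), q3=float(q3))
        out["display"] = f"{med:g} ({q1:g}–{q3:g})"
    return out


def _mannwhitney(x: np.ndarray, y: np.ndarray):
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if min(len(x), len(y)) <= MW_EXACT_MAX_N and not has_ties:
        return ss.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    return ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")


def compare_groups(x, y, paired: bool = False, variable: str = "",
                   groups: tuple[str, str] = ("group1", "group2"),
                   alpha: float = SCREEN_ALPHA,
                   route: str | None = None) -> ComparisonResult:
    """Compare two samples, routing the test on the normality of both.

    Both samples normal -> (paired) t test; otherwise Mann–Whitney U for
    independent samples or Wilcoxon signed-rank for paired ones.  An
    all-tied paired contrast is returned with ``degenerate=True`` rather
    than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InvalidParameterError("empty sample in group comparison")
    if paired and len(x) != len(y):
        raise InvalidParameterError("paired comparison needs equal lengths")
    if route is None:
        route = "normal" if (normality_gate(x) == "normal"
                             and normality_gate(y) == "normal") else "skewed"
    summary = {groups[0]: describe(x, route), groups[1]: describe(y, route)}
    degenerate = False
    notes: list[str] = []
    if route == "normal":
        if paired:
            test_name = "paired t"
            stat, p = ss.ttest_rel(x, y)
        else:
            test_name = "independent t"
            stat, p = ss.ttest_ind(x, y)
        if np.isnan(p):  # zero-variance difference
            degenerate, stat, p = True, 0.0, 1.0
    else:
        if paired:
            test_name = "wilcoxon signed-rank"
            d = x - y
            if np.all(d == 0):
                degenerate, stat, p = True, 0.0, 1.0
                notes.append("all paired differences are zero")
            else:
                stat, p = ss.wilcoxon(x, y)
        else:
            test_name = "mann-whitney u"
            if np.ptp(np.concatenate([x, y])) == 0:
                degenerate, stat, p = True, 0.0, 1.0
                notes.append("all observations tied across groups")
            else:
                stat, p = _mannwhitney(x, y)
    return ComparisonResult(variable=variable, groups=groups, test_name=test_name,
                            statistic=float(stat), p_two_sided=float(p),
                            summary=summary, paired=paired, alpha=alpha,
                            degenerate=degenerate, notes=notes)


def one_sample_vs_reference(x, ref: float = 10.0, variable: str = "",
                            alpha: float = SCREEN_ALPHA,
                            route: str | None = None) -> ComparisonResult:
    """One-sample contrast against a reference value (TLX midpoint 10).

    ``route`` forces the normal (t) or skewed (Wilcoxon) branch; by default
    the normality gate decides.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise InvalidParameterError("one-sample test needs n >= 2")
    if route is None:
        route = normality_gate(x)
    summary = {"sample": describe(x, route), "reference": {"value": ref}}
    degenerate = False
    notes: list[str] = []
    if np.ptp(x) == 0 and x[0] == ref:
        degenerate, stat, p = True, 0.0, 1.0
        test_name = "degenerate (constant at reference)"
        notes.append("sample constant and equal to reference")
    elif route == "normal":
        test_name = "one-sample t"
        stat, p = ss.ttest_1samp(x, ref)
    else:
        test_name = "one-sample wilcoxon"
        d = x - ref
        if np.all(d == 0):
            degenerate, stat, p = True, 0.0, 1.0
        else:
            stat, p = ss.wilcoxon(d)
    return ComparisonResult(variable=variable, groups=("sample", f"ref={ref:g}"),
                            test_name=test_name, statistic=float(stat),
                            p_two_sided=float(p), summary=summary, paired=False,
                            alpha=alpha, degenerate=degenerate, notes=notes)


def correlate(x, y, x_dichotomous: bool = False, var_x: str = "x",
              var_y: str = "y", alpha: float = SCREEN_ALPHA) -> CorrelationResult:
    """Spearman (continuous) or point-biserial (dichotomous x) correlation.

    Spearman uses average ranks for ties with the t-approximation for the
    two-sided p-value; point-biserial p comes from the t transform on n-2
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InvalidParameterError("correlate needs aligned samples")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 4:
        raise InvalidParameterError("correlation needs n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(var_x, var_y, "undefined", None, None, n,
                                 degenerate=True, alpha=alpha)
    if x_dichotomous:
        levels = np.unique(x)
        if len(levels) != 2:
            raise ValidationError(
                f"x marked dichotomous but has {len(levels)} distinct values")
        r, p = ss.pointbiserialr(x, y)
        method = "point_biserial"
    else:
        r, p = ss.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(var_x, var_y, method, float(r), float(p), n,
                             alpha=alpha)


def fisher_exact(table) -> dict:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The two-sided p sums hypergeometric tables whose probability does not
    exceed the observed table's.  A zero row or column margin gives p = 1
    with a ``degenerate`` flag.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InvalidParameterError("fisher_exact needs a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and np.any(t != np.floor(t)):
        raise InvalidParameterError("table entries must be non-negative integers")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return {"p_two_sided": 1.0, "odds_ratio": None, "degenerate": True}
    res = ss.fisher_exact(t, alternative="two-sided")
    return {"p_two_sided": float(res.pvalue),
            "odds_ratio": float(res.statistic), "degenerate": False}


def correlation_screen(cohort: pd.DataFrame,
                       pairs: list[tuple[str, str]],
                       dichotomous: set[str] = frozenset(),
                       alpha: float = SCREEN_ALPHA) -> pd.DataFrame:
    """Run the pairwise correlation screen and return a tidy edge table."""
    rows = []
    for vx, vy in pairs:
        x_dich = vx in dichotomous
        res = correlate(cohort[vx], cohort[vy], x_dichotomous=x_dich,
                        var_x=vx, var_y=vy, alpha=alpha)
        rows.append({
            "var_x": vx, "var_y": vy, "method": res.method,
            "r": np.nan if res.r is None else res.r,
            "p": np.nan if res.p_two_sided is None else res.p_two_sided,
            "n": res.n, "degenerate": res.degenerate,
            "significant": res.significant,
        })
    return pd.DataFrame(rows)
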