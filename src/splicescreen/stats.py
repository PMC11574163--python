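"""Core statistical primitives: two-sample t, Pearson r, one-way ANOVA,
Bonferroni and Dunnett multiple-comparison adjustment.

The statistics themselves are computed here from their defining formulas;
only the t / F distribution functions are delegated to scipy.  Dunnett's
adjustment is estimated by seeded Monte-Carlo sampling of the max-|t| null
and reported together with its Monte-Carlo standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "student_t_two_sample",
    "pearson",
    "anova_oneway",
    "adjust_bonferroni",
    "dunnett_contrasts",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    method: str
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if np.any(np.isnan(arr)):
        raise ValueError(f"{name} contains NaN; drop missing values first")
    return arr


def student_t_two_sample(x, y, pooled: bool = True) -> TestResult:
    """Two-tailed two-sample Student's t-test.

    Pooled-variance by default (df = n_x + n_y - 2); ``pooled=False`` gives
    the Welch form with Satterthwaite df.
    """
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs n >= 2")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    diff = x.mean() - y.mean()
    if pooled:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        if sp2 <= 0:
            raise ValueError("zero pooled variance: samples are constant")
        se = math.sqrt(sp2 * (1 / nx + 1 / ny))
        df: float = nx + ny - 2
        method = "student_t_pooled"
    else:
        if vx == 0 and vy == 0:
            raise ValueError("zero variance in both samples")
        a, b = vx / nx, vy / ny
        se = math.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (nx - 1) + b**2 / (ny - 1))
        method = "welch_t"
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(t, df, min(p, 1.0), method)


def pearson(x, y) -> TestResult:
    """Product-moment correlation with a two-tailed p-value from
    t = r * sqrt((n - 2) / (1 - r^2))."""
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0 or syy == 0:
        raise ValueError("constant series: correlation undefined")
    r = float(xc @ yc) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(r, df, min(p, 1.0), "pearson", extra={"n": n})


def anova_oneway(groups) -> TestResult:
    """One-way fixed-effects ANOVA from between/within mean squares."""
    gs = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    k = len(gs)
    if k < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    ns = np.array([len(g) for g in gs])
    n = int(ns.sum())
    grand = np.concatenate(gs).mean()
    means = np.array([g.mean() for g in gs])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        if ss_between == 0:
            raise ValueError("all observations identical: F undefined")
        return TestResult(math.inf, (df_b, df_w), 0.0, "anova_oneway")
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    f = ms_b / ms_w
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(f, (df_b, df_w), min(p, 1.0), "anova_oneway")


def adjust_bonferroni(p_list) -> list[float]:
    """Bonferroni family-wise adjustment: p_adj = min(1, m * p)."""
    ps = [float(p) for p in p_list]
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of [0,1]: {p}")
    m = len(ps)
    return [min(1.0, m * p) for p in ps]


def dunnett_contrasts(
    groups,
    control_index: int = 0,
    mc_reps: int = 200_000,
    seed: int | None = 0,
) -> list[TestResult]:
    """Many-to-one (Dunnett) comparisons against a control group.

    Per-contrast t statistics use the pooled within-group mean square
    (df = N - k).  Adjusted p-values are estimated by Monte-Carlo sampling
    of the joint null of the max-|t| statistic, preserving the correlation
    induced by the shared control mean and the shared variance estimate.
    Each result carries ``extra={"mc_se": ...}``, the binomial standard
    error of its adjusted p.
    """
    gs = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    k = len(gs)
    if k < 2:
        raise ValueError("Dunnett needs a control and >= 1 treatment group")
    if not 0 <= control_index < k:
        raise ValueError(f"control_index {control_index} out of range")
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    ns = np.array([len(g) for g in gs])
    n_tot = int(ns.sum())
    df_w = n_tot - k
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    if ss_within == 0:
        raise ValueError("zero within-group variance")
    ms_w = ss_within / df_w

    ctrl = gs[control_index]
    others = [i for i in range(k) if i != control_index]
    t_obs = np.array(
        [
            (gs[i].mean() - ctrl.mean())
            / math.sqrt(ms_w * (1 / len(gs[i]) + 1 / len(ctrl)))
            for i in others
        ]
    )

    rng = np.random.default_rng(seed)
    # Null: group means ~ N(0, sigma^2/n_g); shared s^2 ~ sigma^2 * chi2(df)/df.
    z = rng.standard_normal((mc_reps, k)) / np.sqrt(ns)
    s2 = rng.chisquare(df_w, size=mc_reps) / df_w
    se = np.sqrt(1 / ns[others] + 1 / ns[control_index])
    t_null = (z[:, others] - z[:, [control_index]]) / (
        np.sqrt(s2)[:, None] * se[None, :]
    )
    max_abs = np.abs(t_null).max(axis=1)

    results = []
    for idx, i in enumerate(others):
        p_adj = float(np.mean(max_abs >= abs(t_obs[idx])))
        mc_se = math.sqrt(max(p_adj * (1 - p_adj), 1.0 / mc_reps) / mc_reps)
        results.append(
            TestResult(
                float(t_obs[idx]),
                df_w,
                p_adj,
                "dunnett_mc",
                extra={"mc_se": mc_se, "group": i, "control": control_index},
            )
        )
    return results
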