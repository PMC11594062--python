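"""The study's statistical plan.

Site-level metrics are averaged within each (culture, treatment) cell —
the culture is the statistical unit (n = culture).  Raw metrics are tested
with a two-way fixed-effects ANOVA (treatment + culture, no interaction:
with one aggregated observation per cell the design is a randomized
complete block and an interaction term would exhaust the residual).
A significant treatment effect is followed by Dunnett's many-to-one test
against the vehicle group, using the ANOVA residual mean square.  Percentage
data use a one-way ANOVA with the same post-hoc; two-group comparisons use
the classic pooled-variance unpaired t-test.  All tests are two-sided at
alpha = 0.05.

Dunnett family-wise adjusted p-values come from the distribution of the
maximum absolute component of an equicorrelated multivariate t (correlation
1/2 in balanced designs), evaluated by deterministic Gauss quadrature; an
unbalanced design falls back to a seeded Monte-Carlo evaluation of the same
max-|T| law under the general product-correlation structure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy import optimize
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .model import DegenerateDataError

__all__ = [
    "AnovaResult",
    "aggregate_sites",
    "two_way_anova",
    "one_way_anova",
    "dunnett",
    "one_way_anova_dunnett",
    "t_test_unpaired",
    "dunnett_max_abs_t_cdf",
    "dunnett_critical_value",
    "simulate_null_anova",
    "significance_stars",
]

ALPHA = 0.05


def significance_stars(p: float) -> str:
    """Figure-caption star convention: * < .05, ** < .01, *** < .001,
    **** < .0001."""
    for cut, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < cut:
            return stars
    return ""


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

def aggregate_sites(
    site_metrics: pd.DataFrame,
    metric_columns: list[str] | None = None,
    flag_column: str = "qc_flags",
) -> pd.DataFrame:
    """Arithmetic mean of site-level metrics per (culture, group).

    QC-flagged sites are dropped before averaging; a (culture, group) cell
    left with zero usable sites raises.  Returns a long table
    (metric, culture, group, value, n_sites).
    """
    df = site_metrics.copy()
    if flag_column in df.columns:
        flagged = df[flag_column].fillna("").astype(str) != ""
        df = df[~flagged]
    if metric_columns is None:
        skip = {"culture", "group", "well", "site", flag_column}
        metric_columns = [c for c in site_metrics.columns
                          if c not in skip and pd.api.types.is_numeric_dtype(site_metrics[c])]
    expected_cells = (site_metrics[["culture", "group"]]
                      .drop_duplicates().itertuples(index=False))
    usable_cells = set(map(tuple, df[["culture", "group"]].drop_duplicates().values))
    for cell in expected_cells:
        if tuple(cell) not in usable_cells:
            raise DegenerateDataError(
                f"no unflagged site left in culture={cell.culture!r} "
                f"group={cell.group!r}"
            )
    rows = []
    grouped = df.groupby(["culture", "group"])
    for (culture, group), sub in grouped:
        for m in metric_columns:
            vals = sub[m].dropna()
            rows.append({
                "metric": m, "culture": culture, "group": group,
                "value": float(vals.mean()) if len(vals) else np.nan,
                "n_sites": int(len(vals)),
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# ANOVA
# --------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Decomposition table plus the pieces Dunnett's test needs."""

    table: pd.DataFrame        # rows: effect names; columns ss, df, ms, F, p
    residual_ss: float
    residual_df: int
    residual_ms: float
    group_means: pd.Series     # mean response per treatment group
    group_n: pd.Series         # observations per treatment group
    design: str                # "two-way additive (treatment + culture)" | "one-way"

    @property
    def treatment_f(self) -> float:
        return float(self.table.loc["treatment", "F"])

    @property
    def treatment_p(self) -> float:
        return float(self.table.loc["treatment", "p"])


def _complete_block(df: pd.DataFrame) -> pd.DataFrame:
    """Drop cultures that lack any treatment group (complete-block policy)."""
    groups = set(df["group"].unique())
    keep = [c for c, sub in df.groupby("culture")
            if set(sub["group"].unique()) == groups]
    return df[df["culture"].isin(keep)]


def two_way_anova(values: pd.DataFrame, drop_incomplete: bool = True) -> AnovaResult:
    """Additive two-way fixed-effects ANOVA on (culture, group, value) rows.

    Requires >= 2 treatments, >= 2 cultures and exactly one observation per
    (culture, group) cell; cultures missing a group are dropped when
    ``drop_incomplete`` (mirroring the varying n per metric in practice).
    The treatment F is tested against the residual mean square.
    """
    df = values.dropna(subset=["value"]).copy()
    if drop_incomplete:
        df = _complete_block(df)
    dup = df.duplicated(subset=["culture", "group"])
    if dup.any():
        raise ValueError("more than one observation per (culture, group) cell")
    n_groups = df["group"].nunique()
    n_cultures = df["culture"].nunique()
    if n_groups < 2:
        raise DegenerateDataError("need >= 2 treatment groups")
    if n_cultures < 2:
        raise DegenerateDataError(
            f"insufficient replication: {n_cultures} complete culture(s), need >= 2"
        )
    model = smf.ols("value ~ C(group) + C(culture)", data=df).fit()
    tab = anova_lm(model, typ=2)
    out = pd.DataFrame({
        "ss": [tab.loc["C(group)", "sum_sq"], tab.loc["C(culture)", "sum_sq"],
               tab.loc["Residual", "sum_sq"]],
        "df": [tab.loc["C(group)", "df"], tab.loc["C(culture)", "df"],
               tab.loc["Residual", "df"]],
    }, index=["treatment", "culture", "residual"])
    out["ms"] = out["ss"] / out["df"]
    resid_df = int(out.loc["residual", "df"])
    if resid_df < 1:
        raise DegenerateDataError("zero residual degrees of freedom")
    resid_ms = float(out.loc["residual", "ms"])
    out["F"] = [out.loc["treatment", "ms"] / resid_ms,
                out.loc["culture", "ms"] / resid_ms, np.nan]
    out["p"] = [sps.f.sf(out.loc["treatment", "F"], out.loc["treatment", "df"], resid_df),
                sps.f.sf(out.loc["culture", "F"], out.loc["culture", "df"], resid_df),
                np.nan]
    means = df.groupby("group")["value"].mean()
    ns = df.groupby("group")["value"].size()
    return AnovaResult(out, float(out.loc["residual", "ss"]), resid_df, resid_ms,
                       means, ns, design="two-way additive (treatment + culture)")


def one_way_anova(values: pd.DataFrame) -> AnovaResult:
    """One-way fixed-effects ANOVA on (group, value) rows (>= 2 per group)."""
    df = values.dropna(subset=["value"]).copy()
    counts = df.groupby("group")["value"].size()
    if len(counts) < 2:
        raise DegenerateDataError("need >= 2 groups")
    if (counts < 2).any():
        raise DegenerateDataError("every group needs >= 2 values")
    scale = float(np.abs(df["value"]).max())
    if df.groupby("group")["value"].var(ddof=1).max() <= 1e-24 * max(scale, 1.0) ** 2:
        raise DegenerateDataError("zero within-group variance: F undefined")
    model = smf.ols("value ~ C(group)", data=df).fit()
    tab = anova_lm(model, typ=2)
    out = pd.DataFrame({
        "ss": [tab.loc["C(group)", "sum_sq"], tab.loc["Residual", "sum_sq"]],
        "df": [tab.loc["C(group)", "df"], tab.loc["Residual", "df"]],
    }, index=["treatment", "residual"])
    out["ms"] = out["ss"] / out["df"]
    resid_df = int(out.loc["residual", "df"])
    resid_ms = float(out.loc["residual", "ms"])
    if resid_ms <= 0:
        raise DegenerateDataError("zero within-group variance: F undefined")
    out["F"] = [out.loc["treatment", "ms"] / resid_ms, np.nan]
    out["p"] = [sps.f.sf(out.loc["treatment", "F"], out.loc["treatment", "df"],
                         resid_df), np.nan]
    return AnovaResult(out, float(out.loc["residual", "ss"]), resid_df, resid_ms,
                       df.groupby("group")["value"].mean(),
                       df.groupby("group")["value"].size(), design="one-way")


# --------------------------------------------------------------------------
# Dunnett's many-to-one comparison
# --------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = hermgauss(64)
_GL_NODES, _GL_WEIGHTS = leggauss(64)


def dunnett_max_abs_t_cdf(t: float, k: int, df: int, rho: float = 0.5) -> float:
    """P(max_i |T_i| <= t) for k equicorrelated t statistics.

    T_i = Z_i / W with shared W = sqrt(chi2_df / df) and Z_i standard normal
    with common correlation rho (1/2 in balanced many-to-one designs).
    Evaluated by Gauss-Hermite quadrature over the shared normal factor and
    Gauss-Legendre quadrature over the quantile-transformed chi mixing
    variable; deterministic and accurate to well below 1e-4.
    """
    if t <= 0:
        return 0.0
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    # chi mixing variable via quantile transform of s ~ U(0,1)
    s = 0.5 * (_GL_NODES + 1.0)
    ws = 0.5 * _GL_WEIGHTS
    w = sps.chi.ppf(s, df) / np.sqrt(df)
    x = np.sqrt(2.0) * _GH_NODES
    wx = _GH_WEIGHTS / np.sqrt(np.pi)
    a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
    tw = t * w[:, None]                        # (nw, 1)
    ax = a * x[None, :]                        # (1, nx)
    upper = sps.norm.cdf((tw + ax) / b)
    lower = sps.norm.cdf((-tw + ax) / b)
    inner = (upper - lower) ** k               # (nw, nx)
    return float(ws @ (inner @ wx))


def dunnett_critical_value(k: int, df: int, alpha: float = ALPHA,
                           rho: float = 0.5) -> float:
    """Two-sided critical value c with P(max|T| > c) = alpha."""
    target = 1.0 - alpha
    return float(optimize.brentq(
        lambda t: dunnett_max_abs_t_cdf(t, k, df, rho) - target, 1e-6, 50.0,
        xtol=1e-10,
    ))


def _mc_max_abs_t_sf(tstats: np.ndarray, lam: np.ndarray, df: int,
                     draws: int, seed: int) -> np.ndarray:
    """Seeded Monte-Carlo P(max|T| >= |t_i|) under product correlation
    rho_ij = lam_i * lam_j (the unbalanced many-to-one structure)."""
    rng = np.random.default_rng(seed)
    k = lam.size
    z0 = rng.standard_normal(draws)
    zi = rng.standard_normal((draws, k))
    z = lam[None, :] * z0[:, None] + np.sqrt(1.0 - lam**2)[None, :] * zi
    w = np.sqrt(rng.chisquare(df, draws) / df)
    max_abs = np.abs(z).max(axis=1) / w
    return np.array([(max_abs >= abs(t)).mean() for t in tstats])


def dunnett(
    values: pd.DataFrame,
    control: str,
    anova: AnovaResult | None = None,
    seed: int = 0,
    mc_draws: int = 100_000,
) -> pd.DataFrame:
    """Dunnett's two-sided many-to-one comparisons against ``control``.

    Uses the residual mean square and degrees of freedom of ``anova``
    (computed as a two-way treatment+culture ANOVA when not supplied).
    Returns one row per non-control group: difference estimate, standard
    error, t, unadjusted p, family-wise adjusted p and stars.  With k = 1
    comparison the adjusted p equals the ordinary two-sided t-test p.
    """
    if anova is None:
        anova = two_way_anova(values)
    means, ns = anova.group_means, anova.group_n
    if control not in means.index:
        raise ValueError(f"control group {control!r} absent")
    if anova.residual_df < 1:
        raise DegenerateDataError("residual df < 1")
    if anova.residual_ms <= 0:
        raise DegenerateDataError("zero residual mean square")
    others = [g for g in means.index if g != control]
    k = len(others)
    n0 = float(ns[control])
    diffs = np.array([means[g] - means[control] for g in others])
    se = np.array([np.sqrt(anova.residual_ms * (1.0 / ns[g] + 1.0 / n0))
                   for g in others])
    tstats = diffs / se
    raw_p = 2.0 * sps.t.sf(np.abs(tstats), anova.residual_df)
    lam = np.array([np.sqrt(ns[g] / (ns[g] + n0)) for g in others])
    balanced = np.allclose(lam, lam[0])
    if balanced:
        rho = float(lam[0] ** 2)
        adj_p = np.array([
            1.0 - dunnett_max_abs_t_cdf(abs(t), k, anova.residual_df, rho)
            for t in tstats
        ])
    else:
        adj_p = _mc_max_abs_t_sf(tstats, lam, anova.residual_df, mc_draws, seed)
    adj_p = np.clip(np.maximum(adj_p, raw_p), 0.0, 1.0)
    return pd.DataFrame({
        "group": others,
        "control": control,
        "estimate": diffs,
        "se": se,
        "t": tstats,
        "df": anova.residual_df,
        "p_unadjusted": raw_p,
        "p_adjusted": adj_p,
        "stars": [significance_stars(p) for p in adj_p],
    })


def one_way_anova_dunnett(
    values: pd.DataFrame, control: str, seed: int = 0
) -> tuple[AnovaResult, pd.DataFrame]:
    """One-way ANOVA (percentage-type data) followed by Dunnett vs control
    with the pooled within-group mean square."""
    res = one_way_anova(values)
    return res, dunnett(values, control, anova=res, seed=seed)


# --------------------------------------------------------------------------
# two-group comparison
# --------------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    df: int
    p: float


def t_test_unpaired(x, y) -> TTestResult:
    """Classic pooled-variance two-sided unpaired t-test."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise DegenerateDataError("both groups have zero variance")
    res = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(res.statistic), df=x.size + y.size - 2,
                       p=float(res.pvalue))


# --------------------------------------------------------------------------
# null calibration of the blocked design
# --------------------------------------------------------------------------

def simulate_null_anova(
    n_groups: int = 6,
    n_cultures: int = 8,
    n_reps: int = 10_000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Vectorised null simulation of the blocked ANOVA layer.

    Draws ``n_reps`` independent (group x culture) tables of standard-normal
    culture means with no treatment effect and returns, per replicate, the
    treatment-F p-value and the maximum |Dunnett t| against group 0.  Used
    to verify that treatment p-values are uniform and that the family-wise
    error of the Dunnett step sits at its nominal level.
    """
    rng = np.random.default_rng(seed)
    G, B = n_groups, n_cultures
    y = rng.standard_normal((n_reps, G, B))
    gm = y.mean(axis=(1, 2), keepdims=True)
    group_mean = y.mean(axis=2, keepdims=True)
    block_mean = y.mean(axis=1, keepdims=True)
    resid = y - group_mean - block_mean + gm
    ss_res = (resid**2).sum(axis=(1, 2))
    df_res = (G - 1) * (B - 1)
    ms_res = ss_res / df_res
    ss_t = B * ((group_mean[:, :, 0] - gm[:, :, 0]) ** 2).sum(axis=1)
    f = (ss_t / (G - 1)) / ms_res
    p_treat = sps.f.sf(f, G - 1, df_res)
    diffs = group_mean[:, 1:, 0] - group_mean[:, :1, 0]
    t = diffs / np.sqrt(ms_res[:, None] * 2.0 / B)
    return {"treatment_p": p_treat, "max_abs_t": np.abs(t).max(axis=1),
            "residual_df": df_res}
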