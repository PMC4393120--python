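"""Cross-species statistics relating the impact of selection to census size.

Census population size (Nc) is proxied by geographic range (positive) and
individual body size (negative).  The main model is ordinary least squares

    impact ~ log10(range) + log10(size) + kingdom + log10(size):kingdom

with kingdom coded 0 for animals, 1 for plants.  Around it sit the
supporting nonparametric machinery: tie-corrected partial Kendall
correlations (diversity vs recombination controlling for coding density),
permutation tests for group differences, exact Wilcoxon and Fisher tests,
confounder comparisons (map quality, assembly quality, recombination rate,
genome size) and the census-size quadrant classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "LinearModelResult",
    "partial_kendall_tau",
    "permutation_group_test",
    "wilcoxon_rank_sum",
    "fisher_exact",
    "fit_main_model",
    "confounder_models",
    "nc_classes",
    "MAIN_FORMULA",
    "CONFOUNDERS",
]

MAIN_FORMULA = "impact ~ log10_range + log10_size + kingdom + log10_size:kingdom"

CONFOUNDERS = (
    "marker_density",
    "frac_useable_markers",
    "nongap_fraction",
    "anchored_fraction",
    "mean_recomb_rate",
    "log10_c_value",
)


@dataclass
class CorrelationResult:
    tau: float
    n: int
    tau_xy: float
    tau_xz: float
    tau_yz: float


def partial_kendall_tau(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> CorrelationResult:
    """First-order partial Kendall tau of x and y controlling for z.

    tau_xy.z = (tau_xy - tau_xz * tau_yz) / sqrt((1 - tau_xz^2)(1 - tau_yz^2)),
    with tie-corrected (tau-b) correlations throughout.  Rows with any
    missing value are dropped (pairwise-complete is the caller's job when
    the sources differ).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (len(x) == len(y) == len(z)):
        raise ValueError("x, y, z must have equal length")
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[keep], y[keep], z[keep]
    if len(x) < 10:
        raise ValueError(f"need >= 10 complete observations, got {len(x)}")
    t_xy = stats.kendalltau(x, y).statistic
    t_xz = stats.kendalltau(x, z).statistic
    t_yz = stats.kendalltau(y, z).statistic
    if abs(t_xz) >= 1.0 - 1e-12 or abs(t_yz) >= 1.0 - 1e-12:
        raise ValueError("control variable perfectly concordant: partial tau undefined")
    tau = (t_xy - t_xz * t_yz) / math.sqrt((1 - t_xz**2) * (1 - t_yz**2))
    return CorrelationResult(float(tau), len(x), float(t_xy), float(t_xz), float(t_yz))


def permutation_group_test(
    values: Sequence[float],
    labels: Sequence,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "mean",
) -> float:
    """Two-tailed permutation p for a two-group location difference.

    The statistic is the difference in group means (or medians).  When the
    number of distinct label assignments is at most ``n_perm`` the null
    distribution is enumerated exhaustively; otherwise Monte Carlo with the
    identity permutation included in numerator and denominator, so p > 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {len(groups)}")
    mask = labels == groups[0]
    n, n1 = len(values), int(mask.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("both groups must be non-empty")
    agg = np.mean if statistic == "mean" else np.median

    def stat(sel: np.ndarray) -> float:
        return float(agg(values[sel]) - agg(values[~sel]))

    observed = abs(stat(mask))
    total = math.comb(n, n1)
    eps = 1e-12
    if total <= n_perm:
        count = 0
        idx = np.arange(n)
        for chosen in combinations(idx, n1):
            sel = np.zeros(n, dtype=bool)
            sel[list(chosen)] = True
            if abs(stat(sel)) >= observed - eps:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 1  # identity permutation
    for _ in range(n_perm):
        sel = np.zeros(n, dtype=bool)
        sel[rng.choice(n, size=n1, replace=False)] = True
        if abs(stat(sel)) >= observed - eps:
            count += 1
    return count / (n_perm + 1)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 25
) -> float:
    """Two-sided Wilcoxon rank-sum p, exact for small samples without ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = (
        "exact" if (max(len(x), len(y)) <= exact_max_n and not has_ties) else "asymptotic"
    )
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p (sum of tables with probability <= observed)."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 contingency table")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("empty group in contingency table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass
class LinearModelResult:
    """OLS fit summary: per-term table, adjusted R^2, overall F."""

    params: pd.DataFrame  # estimate, std_error, t, p per term
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    residuals: np.ndarray = field(repr=False, default=None)
    model: object = field(repr=False, default=None)

    @classmethod
    def from_statsmodels(cls, res) -> "LinearModelResult":
        params = pd.DataFrame(
            {
                "estimate": res.params,
                "std_error": res.bse,
                "t": res.tvalues,
                "p": res.pvalues,
            }
        )
        return cls(
            params=params,
            r_squared=float(res.rsquared),
            adj_r_squared=float(res.rsquared_adj),
            f_statistic=float(res.fvalue),
            f_pvalue=float(res.f_pvalue),
            df_model=int(res.df_model),
            df_resid=int(res.df_resid),
            residuals=np.asarray(res.resid),
            model=res,
        )


def _check_design(df: pd.DataFrame, formula: str) -> None:
    mod = smf.ols(formula, data=df)
    rank = np.linalg.matrix_rank(mod.exog)
    if rank < mod.exog.shape[1]:
        names = mod.exog_names
        raise ValueError(
            f"rank-deficient design ({rank} < {len(names)}): collinear terms "
            f"among {names}"
        )


def fit_main_model(
    records: pd.DataFrame, formula: str = MAIN_FORMULA
) -> LinearModelResult:
    """OLS of the impact of selection on the census-size proxies."""
    if len(records) < 10:
        raise ValueError("need >= 10 species")
    if "kingdom" in formula and ":" in formula and records["kingdom"].nunique() < 2:
        raise ValueError("interaction term requested but only one kingdom present")
    _check_design(records, formula)
    res = smf.ols(formula, data=records).fit()
    return LinearModelResult.from_statsmodels(res)


@dataclass
class ConfounderComparison:
    confounder_only: LinearModelResult
    combined: LinearModelResult
    nested_f: float
    nested_f_pvalue: float
    nested_df: tuple[int, int]
    residual_model: LinearModelResult


def confounder_models(
    records: pd.DataFrame, confounders: Sequence[str] = CONFOUNDERS
) -> ConfounderComparison:
    """Compare census-size proxies against the nuisance-parameter model.

    Fits (a) the confounder-only model, (b) the combined model adding the
    census-size proxies, (c) their nested F comparison, and (d) the proxies
    fitted to the confounder-only residuals — a conservative lower bound on
    the variation the proxies explain.  Missing confounder columns shrink
    the confounder set with an explicit report.
    """
    present = [c for c in confounders if c in records.columns]
    missing = sorted(set(confounders) - set(present))
    if missing:
        logger.warning("confounders missing from records, fitted without: %s", missing)
    if not present:
        raise ValueError("no confounder columns present")
    conf_formula = "impact ~ " + " + ".join(present)
    proxy_terms = "log10_range + log10_size + kingdom + log10_size:kingdom"
    combined_formula = f"impact ~ {' + '.join(present)} + {proxy_terms}"

    conf_res = smf.ols(conf_formula, data=records).fit()
    comb_res = smf.ols(combined_formula, data=records).fit()
    anova = sm.stats.anova_lm(conf_res, comb_res)
    nested_f = float(anova["F"].iloc[1])
    nested_p = float(anova["Pr(>F)"].iloc[1])
    nested_df = (int(anova["df_diff"].iloc[1]), int(comb_res.df_resid))

    resid_df = records.copy()
    resid_df["impact"] = conf_res.resid
    resid_res = smf.ols(f"impact ~ {proxy_terms}", data=resid_df).fit()
    return ConfounderComparison(
        confounder_only=LinearModelResult.from_statsmodels(conf_res),
        combined=LinearModelResult.from_statsmodels(comb_res),
        nested_f=nested_f,
        nested_f_pvalue=nested_p,
        nested_df=nested_df,
        residual_model=LinearModelResult.from_statsmodels(resid_res),
    )


def nc_classes(records: pd.DataFrame) -> pd.Series:
    """Census-size quadrant classes from the range and size medians.

    high-Nc: range strictly above the median range *and* size strictly
    below the median size; low-Nc: the opposite quadrant; everything else
    (including species exactly at a median) is unclassified.
    """
    if records[["log10_size", "log10_range"]].isna().any().any():
        raise ValueError("size and range must be present for all species")
    med_range = records["log10_range"].median()
    med_size = records["log10_size"].median()
    cls = pd.Series("unclassified", index=records.index, dtype=object)
    cls[(records["log10_range"] > med_range) & (records["log10_size"] < med_size)] = "high"
    cls[(records["log10_range"] < med_range) & (records["log10_size"] > med_size)] = "low"
    return cls
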