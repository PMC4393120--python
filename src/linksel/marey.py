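"""Genetic-map curation and Marey-map recombination rate estimation.

A Marey map plots genetic position (cM) against physical position (bp); the
derivative of a smooth function fitted through the markers is the local
recombination rate.  Before fitting, maps are reconciled with the assembly:
markers whose genetic order disagrees with physical order are flagged by a
longest-common-subsequence (LCS) congruence filter, multi-candidate markers
are resolved to their single most congruent placement, and runs of
incongruent markers mask out low-quality map regions.

Fitting offers a polynomial and a linear B-spline, each with its complexity
chosen by information criterion over the prescribed search ranges
(polynomial degree 1 .. max(3, min(20, n/3)); spline degrees of freedom
1 .. min(100, max(2, n/2))).  Window rates are the fitted derivative at the
window's physical midpoint, clamped below at zero and winsorized above at
the genome-wide 99th percentile.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy.interpolate import LSQUnivariateSpline

logger = logging.getLogger(__name__)

__all__ = [
    "MareyFit",
    "RecombinationProfile",
    "lcs_congruent_subset",
    "resolve_duplicates",
    "mask_low_quality",
    "fit_marey_function",
    "choose_method",
    "window_recombination",
    "mean_intermarker_spacing",
    "CM_PER_MB_TO_R_BP",
]

#: 1 cM/Mb = 1e-8 crossovers per bp per generation.
CM_PER_MB_TO_R_BP = 1e-8

MIN_MARKERS_PER_CHROM = 5


def lcs_congruent_subset(genetic_cM: np.ndarray) -> np.ndarray:
    """Congruence flags for markers already sorted by physical position.

    Finds a maximum-length weakly increasing subsequence of genetic
    positions (the LCS of genetic rank against physical rank, ties allowed
    because dense maps share cM values) and flags its members congruent.
    With fewer than two markers everything is retained; the chromosome-size
    masking rule deals with such maps later.
    """
    cM = np.asarray(genetic_cM, dtype=float)
    n = len(cM)
    if n < 2:
        return np.ones(n, dtype=bool)
    # patience algorithm on (value, index); bisect_right keeps ties
    tails: list[float] = []
    tail_idx: list[int] = []
    prev = np.full(n, -1, dtype=int)
    for i, v in enumerate(cM):
        j = bisect_right(tails, v)
        if j == len(tails):
            tails.append(v)
            tail_idx.append(i)
        else:
            tails[j] = v
            tail_idx[j] = i
        prev[i] = tail_idx[j - 1] if j > 0 else -1
    flags = np.zeros(n, dtype=bool)
    i = tail_idx[-1]
    while i >= 0:
        flags[i] = True
        i = prev[i]
    return flags


def resolve_duplicates(markers: pd.DataFrame) -> pd.DataFrame:
    """Keep one physical placement per marker.

    ``markers`` columns: ``marker``, ``chrom``, ``bp``, ``cM`` with one row
    per candidate placement.  Each candidate is treated as a provisional
    marker for the congruence filter; a candidate inside the LCS wins.  If
    several candidates of one marker qualify, the one whose genetic position
    has the smallest absolute residual from linear interpolation between
    flanking congruent single-candidate markers wins; if none qualify the
    marker is dropped.
    """
    out = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        sub = sub.sort_values(["bp", "cM"], kind="mergesort").reset_index(drop=True)
        flags = lcs_congruent_subset(sub["cM"].to_numpy())
        counts = sub["marker"].value_counts()
        multi = set(counts.index[counts > 1])
        anchor = sub[flags & ~sub["marker"].isin(multi)]
        for name, grp in sub.groupby("marker", sort=False):
            if name not in multi:
                out.append(grp)
                continue
            hits = grp[flags[grp.index]]
            if len(hits) == 0:
                logger.info("marker %s: no congruent candidate, dropped", name)
                continue
            if len(hits) == 1:
                out.append(hits)
                continue
            resid = np.abs(
                hits["cM"].to_numpy() - _interp_cM(anchor, hits["bp"].to_numpy())
            )
            out.append(hits.iloc[[int(np.argmin(resid))]])
    if not out:
        return markers.iloc[0:0]
    return (
        pd.concat(out)
        .sort_values(["chrom", "bp"], kind="mergesort")
        .reset_index(drop=True)
    )


def _interp_cM(anchor: pd.DataFrame, bp: np.ndarray) -> np.ndarray:
    if len(anchor) == 0:
        return np.zeros(len(bp))
    return np.interp(bp, anchor["bp"].to_numpy(dtype=float), anchor["cM"].to_numpy(dtype=float))


def run_length_threshold(n_markers: int) -> int:
    """Length of an incongruent run that triggers masking.

    Five bad markers on chromosomes with at least 25 markers, otherwise
    ceil(0.2 * n).
    """
    if n_markers >= 25:
        return 5
    return math.ceil(0.2 * n_markers)


def mask_low_quality(
    markers: pd.DataFrame,
    congruent: np.ndarray | None = None,
    chrom_sizes: dict | None = None,
) -> pd.DataFrame:
    """Mask intervals (bp, per chromosome) spanned by bad-marker runs.

    Chromosomes with fewer than five markers are fully masked.  Masking is
    idempotent: rerunning on the same flags returns the same intervals.
    Returns a data frame with columns ``chrom``, ``start``, ``end``
    (0-based half-open bp).
    """
    if congruent is None:
        congruent = markers["congruent"].to_numpy(dtype=bool)
    congruent = np.asarray(congruent, dtype=bool)
    rows = []
    for chrom, sub in markers.assign(_ok=congruent).groupby("chrom", sort=False):
        sub = sub.sort_values("bp", kind="mergesort")
        n = len(sub)
        if n < MIN_MARKERS_PER_CHROM:
            end = chrom_sizes[chrom] if chrom_sizes else int(sub["bp"].max()) + 1
            rows.append((chrom, 0, int(end)))
            continue
        thresh = run_length_threshold(n)
        bad = ~sub["_ok"].to_numpy()
        bp = sub["bp"].to_numpy()
        i = 0
        while i < n:
            if bad[i]:
                j = i
                while j < n and bad[j]:
                    j += 1
                if j - i >= thresh:
                    rows.append((chrom, int(bp[i]), int(bp[j - 1]) + 1))
                i = j
            else:
                i += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class MareyFit:
    """A fitted Marey function for one chromosome."""

    method: str  # "polynomial" | "bspline"
    complexity: int  # polynomial degree or spline degrees of freedom
    n_markers: int
    bp_min: float
    bp_max: float
    criterion: dict[int, float] = field(repr=False, default_factory=dict)
    _predict: object = field(repr=False, default=None)
    _derivative: object = field(repr=False, default=None)

    def predict(self, bp):
        """Genetic position (cM) at physical position bp."""
        return np.asarray(self._predict(np.asarray(bp, dtype=float)))

    def derivative(self, bp):
        """Local rate in cM per bp (multiply by 1e6 for cM/Mb)."""
        return np.asarray(self._derivative(np.asarray(bp, dtype=float)))


def _aic(rss: float, n: int, k: int) -> float:
    return n * math.log(max(rss, 1e-300) / n) + 2.0 * (k + 1)


def polynomial_degree_range(n_markers: int) -> range:
    return range(1, max(3, min(20, n_markers // 3)) + 1)


def bspline_df_range(n_markers: int) -> range:
    return range(1, min(100, max(2, n_markers // 2)) + 1)


def fit_marey_function(
    markers: pd.DataFrame, method: str = "polynomial", select: str = "min"
) -> MareyFit:
    """Fit a smooth Marey function to congruent, unmasked markers.

    Complexity is searched over the prescribed range and chosen by Gaussian
    least-squares AIC (lowest wins; ties go to the simpler fit).  ``select``
    = ``"max"`` switches to literal AIC maximisation, which picks the most
    complex admissible fit and exists only to mirror a literal reading of
    the published procedure; it is off by default.
    """
    sub = markers.sort_values("bp", kind="mergesort")
    bp = sub["bp"].to_numpy(dtype=float)
    cM = sub["cM"].to_numpy(dtype=float)
    n = len(bp)
    if n < 2:
        raise ValueError("need at least two markers to fit a Marey function")
    better = (lambda a, b: a < b - 1e-9) if select == "min" else (lambda a, b: a > b + 1e-9)
    # fits closer than ~1e-9 of the map's span are numerically exact: floor
    # the RSS there so the simplest exact fit wins instead of float noise
    rss_floor = n * (1e-9 * max(float(np.ptp(cM)), 1.0)) ** 2

    best = None
    criterion: dict[int, float] = {}
    if method == "polynomial":
        for deg in polynomial_degree_range(n):
            if deg >= n:
                continue
            try:
                poly = Polynomial.fit(bp, cM, deg)
            except Exception:
                logger.warning("degree %d fit failed, skipped", deg, exc_info=True)
                continue
            rss = max(float(np.sum((poly(bp) - cM) ** 2)), rss_floor)
            aic = _aic(rss, n, deg + 1)
            criterion[deg] = aic
            if best is None or better(aic, best[0]):
                best = (aic, deg, poly)
        if best is None:
            raise ValueError("no polynomial degree could be fitted")
        _, deg, poly = best
        dpoly = poly.deriv()
        return MareyFit(
            "polynomial", deg, n, bp.min(), bp.max(), criterion, poly, dpoly
        )
    if method == "bspline":
        # duplicate physical positions collapse to their mean genetic position
        ubp, inv = np.unique(bp, return_inverse=True)
        ucM = np.bincount(inv, weights=cM) / np.bincount(inv)
        m = len(ubp)
        if m < 2:
            raise ValueError("need at least two distinct physical positions")
        for df in bspline_df_range(n):
            n_interior = df - 2  # coefficients = interior knots + 2 for k=1
            if n_interior < 0 or df > m:
                logger.debug("spline df %d infeasible, skipped", df)
                continue
            if n_interior > 0:
                q = np.linspace(0, 1, n_interior + 2)[1:-1]
                knots = np.quantile(ubp, q)
                knots = knots[(knots > ubp[0]) & (knots < ubp[-1])]
            else:
                knots = np.array([])
            try:
                spl = LSQUnivariateSpline(ubp, ucM, knots, k=1)
            except Exception:
                logger.debug("spline df %d failed (Schoenberg-Whitney), skipped", df)
                continue
            rss = max(float(np.sum((spl(bp) - cM) ** 2)), rss_floor)
            aic = _aic(rss, n, df)
            criterion[df] = aic
            if best is None or better(aic, best[0]):
                best = (aic, df, spl)
        if best is None:
            raise ValueError("no spline complexity could be fitted")
        _, df, spl = best
        return MareyFit(
            "bspline", df, n, bp.min(), bp.max(), criterion, spl, spl.derivative()
        )
    raise ValueError(f"unknown method {method!r}")


def mean_intermarker_spacing(markers: pd.DataFrame) -> float:
    """Mean successive genetic spacing (cM) of markers, by chromosome."""
    gaps = []
    for _, sub in markers.groupby("chrom", sort=False):
        cM = np.sort(sub["cM"].to_numpy(dtype=float))
        if len(cM) > 1:
            gaps.append(np.diff(cM))
    if not gaps:
        return float("nan")
    return float(np.mean(np.concatenate(gaps)))


def choose_method(mean_spacing_cM: float) -> str:
    """Polynomial for sparse maps (spacing > 2 cM), B-spline otherwise."""
    return "polynomial" if mean_spacing_cM > 2.0 else "bspline"


@dataclass
class RecombinationProfile:
    """Per-window recombination rates with the winsorizing cap applied."""

    windows: pd.DataFrame  # chrom, start, end, rate_cMMb, r_bp, extrapolated
    cap_cMMb: float
    cap_quantile: float
    sex_correction: str


def window_recombination(
    fits: dict[str, MareyFit],
    windows: pd.DataFrame,
    sex_correction: str = "none",
    cap_quantile: float = 0.99,
) -> RecombinationProfile:
    """Evaluate window recombination rates from fitted Marey functions.

    The rate is the fitted derivative at the window's physical midpoint
    (cM/Mb), halved when a single-sex map stands in for a species with
    recombination in one sex only, clamped below at zero and capped at the
    ``cap_quantile`` (default 99th percentile) of the clamped rates across
    all windows passed in — the cap is genome-wide, not per chromosome.
    ``r_bp`` is the per-bp, per-generation rate, ``rate_cMMb * 1e-8``.
    Windows whose midpoint falls outside the fitted marker span keep their
    (extrapolated) value and are flagged.
    """
    if sex_correction not in ("none", "halve"):
        raise ValueError("sex_correction must be 'none' or 'halve'")
    out = windows.copy().reset_index(drop=True)
    mid = (out["start"].to_numpy(dtype=float) + out["end"].to_numpy(dtype=float)) / 2.0
    rate = np.full(len(out), np.nan)
    extrap = np.zeros(len(out), dtype=bool)
    for chrom, idx in out.groupby("chrom", sort=False).groups.items():
        if chrom not in fits:
            continue
        fit = fits[chrom]
        m = mid[np.asarray(idx)]
        rate[np.asarray(idx)] = fit.derivative(m) * 1e6  # cM/bp -> cM/Mb
        extrap[np.asarray(idx)] = (m < fit.bp_min) | (m > fit.bp_max)
    if sex_correction == "halve":
        rate = rate / 2.0
    rate = np.clip(rate, 0.0, None)
    finite = np.isfinite(rate)
    cap = float(np.quantile(rate[finite], cap_quantile)) if finite.any() else float("nan")
    rate = np.minimum(rate, cap)
    out["rate_cMMb"] = rate
    out["r_bp"] = rate * CM_PER_MB_TO_R_BP
    out["extrapolated"] = extrap
    return RecombinationProfile(out, cap, cap_quantile, sex_correction)
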