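"""Joint background-selection + hitchhiking model of windowed neutral diversity.

The model family predicts four-fold degenerate diversity in genomic windows
from two linked-selection forces acting multiplicatively on the coalescence
rate:

    E[pi_i] = theta_neutral / (exp(G_i) + alpha * x_i)

where ``G_i`` is the cumulative background-selection coefficient of window
``i`` (purifying selection on flanking functional sites, Hudson–Kaplan
windowed form), ``alpha`` is a compound sweep-intensity parameter
(2N * Vbp * J_{2,2}; its factors are not separately identified and are never
decomposed here), and ``x_i`` is ``fd_i / rbp_i`` when sweep rates scale with
local functional density (model set 1) or ``1 / rbp_i`` for homogeneous
sweeps (model set 2).  Setting ``G = 0`` and ``alpha = 0`` recovers the
neutral expectation ``theta``.

The background-selection coefficient sums contributions from every window
``k`` on the same chromosome:

    G_i = sum_k  U * fd_k * sh^2
           / [ (sh + P*|M_i - M_k|) * (sh + P*|M_i - M_{k+1}|) ]

with ``M_k, M_{k+1}`` the genetic boundaries (Morgans) of window ``k``,
``M_i`` the focal window's genetic midpoint, ``U`` the diploid genome-wide
deleterious mutation rate, ``sh`` the compound selection-times-dominance
parameter, and ``P`` the index of panmixis scaling effective recombination
under self-fertilisation (1 outcrossing, 0.68 ~50% selfing, 0.04 ~98%
selfing).

Because U, sh and P are unknown they are profiled over a grid; for each grid
point the two continuous parameters (theta, alpha) are fitted by bounded
least squares, the best AIC per model class (BGS+HH, BGS-only, HH-only,
neutral) is retained, and Akaike weights over the four classes quantify
relative support.  The impact of selection is
``max(0, 1 - observed mean pi / theta_neutral)``, the fraction of neutral
diversity removed by linked selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "BgsParams",
    "ModelFit",
    "SelectionSummary",
    "u_grid",
    "sh_grid",
    "P_VALUES",
    "compute_G",
    "predict_pi",
    "fit_model_family",
    "akaike_weights",
    "selection_impact",
    "classify_support",
    "fit_selection",
]

#: Index-of-panmixis values by selfing class (outcrossing, ~50% selfing,
#: ~98% selfing).  Species of unknown selfing rate enter all three.
P_VALUES: dict[str, float] = {"outcrossing": 1.0, "partial": 0.68, "selfing": 0.04}

MODEL_NAMES = ("BGS+HH", "BGS-only", "HH-only", "neutral")

#: Continuously fitted parameters per model class (theta and/or alpha).
#: The residual-variance parameter adds one more inside the AIC formula.
MODEL_K = {"BGS+HH": 2, "BGS-only": 1, "HH-only": 2, "neutral": 1}

_RSS_FLOOR = 1e-300


@dataclass(frozen=True)
class BgsParams:
    """One grid point of the background-selection nuisance parameters."""

    U: float
    sh: float
    P: float

    def __post_init__(self) -> None:
        if self.sh <= 0:
            raise ValueError(f"sh must be positive, got {self.sh}")
        if self.P <= 0:
            raise ValueError(f"P must be positive, got {self.P}")
        if self.U < 0:
            raise ValueError(f"U must be non-negative, got {self.U}")


@dataclass
class ModelFit:
    """A fitted diversity model at one grid point (or its per-class best)."""

    model: str
    model_set: int
    theta: float
    alpha: float
    U: float | None
    sh: float | None
    P: float | None
    rss: float
    n: int
    k: int
    aic: float
    degenerate: bool = False

    def predict(self, G: np.ndarray, x: np.ndarray) -> np.ndarray:
        return self.theta / (np.exp(G) + self.alpha * x)


@dataclass
class SelectionSummary:
    """Species-level outcome of the model-selection procedure."""

    observed_mean_pi: float
    theta_neutral: float
    impact: float
    best_model: str
    weights: dict[str, float]
    neutrality_class: str
    hh_class: str
    fits: dict[str, ModelFit] = field(repr=False, default_factory=dict)


def u_grid(
    mu: float, exonic_bases: float, genome_size: float | None = None
) -> dict[str, float]:
    """Grid of diploid genome-wide deleterious mutation rates.

    ``Umin`` assumes only exonic coding bases are deleterious targets,
    ``Umax`` allows five times as many conserved bases (capped at the genome
    size), both doubled to the diploid scale; ``Uconst`` is 1 for every
    species.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if genome_size is not None and exonic_bases > genome_size:
        raise ValueError("exonic_bases cannot exceed genome_size")
    grid = {"Umin": 2.0 * mu * exonic_bases, "Uconst": 1.0}
    if genome_size is None:
        logger.warning("genome size missing: Umax omitted from the U grid")
    else:
        grid["Umax"] = 2.0 * mu * min(5.0 * exonic_bases, genome_size)
    return grid


def sh_grid(n_points: int = 13, low: float = 1e-5, high: float = 0.1) -> np.ndarray:
    """Log-spaced grid of the compound selection-dominance parameter."""
    return np.geomspace(low, high, n_points)


def _window_morgans(windows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m_start = np.asarray(windows["M_start"], dtype=float)
    m_end = np.asarray(windows["M_end"], dtype=float)
    if "M_mid" in windows.columns:
        m_mid = np.asarray(windows["M_mid"], dtype=float)
    else:
        m_mid = 0.5 * (m_start + m_end)
    return m_start, m_end, m_mid


def compute_G(
    windows: pd.DataFrame,
    params: BgsParams,
    *,
    fd_col: str = "fd",
    literal_fd_focal: bool = False,
) -> np.ndarray:
    """Per-window background-selection coefficient G.

    ``windows`` needs columns ``chrom``, ``M_start``, ``M_end`` (genetic
    boundaries in Morgans; ``M_mid`` optional, defaults to the midpoint) and
    a functional-density column, normalised internally so the genome-wide
    fractions sum to one.  Contributions are restricted to windows on the
    focal chromosome; cross-chromosome terms are negligible (a window 0.5 M
    away contributes ~4e-4 of a fully linked one at sh = 0.01).

    With ``literal_fd_focal`` the focal window's density multiplies the sum,
    reproducing the printed form of the model; the default attributes the
    deleterious input to the contributing window, which is the form the
    underlying background-selection theory implies.
    """
    fd = np.asarray(windows[fd_col], dtype=float)
    total = fd.sum()
    if total <= 0:
        raise ValueError("functional densities sum to zero")
    fd_frac = fd / total
    m_start, m_end, m_mid = _window_morgans(windows)
    chroms = np.asarray(windows["chrom"])
    G = np.zeros(len(windows), dtype=float)
    sh, P, U = params.sh, params.P, params.U
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        d0 = np.abs(m_mid[idx, None] - m_start[None, idx])
        d1 = np.abs(m_mid[idx, None] - m_end[None, idx])
        terms = sh * sh / ((sh + P * d0) * (sh + P * d1))
        if literal_fd_focal:
            G[idx] = U * fd_frac[idx] * terms.sum(axis=1)
        else:
            G[idx] = terms @ (U * fd_frac[idx])
    return G


def predict_pi(
    theta: float,
    G: np.ndarray | float,
    alpha: float,
    x: np.ndarray | float,
) -> np.ndarray:
    """Expected windowed diversity ``theta / (exp(G) + alpha * x)``.

    Windows where ``alpha * x`` is undefined because both the sweep scaling
    and the recombination rate vanish (0/0 in ``fd/rbp``) are guarded to
    ``E[pi] = 0`` upstream by :func:`sweep_scaling`.
    """
    G = np.asarray(G, dtype=float)
    x = np.asarray(x, dtype=float)
    denom = np.exp(G) + alpha * x
    with np.errstate(divide="ignore"):
        out = np.where(np.isinf(denom), 0.0, theta / np.where(np.isinf(denom), 1.0, denom))
    return out


def sweep_scaling(
    fd_frac: np.ndarray, r_bp: np.ndarray, model_set: int
) -> np.ndarray:
    """Sweep-term regressor x_i: fd/rbp (set 1) or 1/rbp (set 2).

    Zero recombination with a positive sweep scaling gives x = inf (diversity
    driven to zero); zero recombination *and* zero density is the guarded
    0/0 case, reported and treated as x = inf so E[pi] = 0.
    """
    fd_frac = np.asarray(fd_frac, dtype=float)
    r_bp = np.asarray(r_bp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if model_set == 1:
            x = fd_frac / r_bp
            both_zero = (fd_frac == 0) & (r_bp == 0)
            if both_zero.any():
                logger.warning(
                    "%d windows with rate and functional density both zero: "
                    "E[pi] guarded to 0",
                    int(both_zero.sum()),
                )
                x[both_zero] = np.inf
        elif model_set == 2:
            x = 1.0 / r_bp
        else:
            raise ValueError(f"model_set must be 1 or 2, got {model_set}")
    return x


def _aic(rss: float, n: int, k: int) -> float:
    """Gaussian least-squares AIC, constant term dropped: n ln(RSS/n) + 2(k+1)."""
    return n * math.log(max(rss, _RSS_FLOOR) / n) + 2.0 * (k + 1)


def _theta_hat(pi: np.ndarray, h: np.ndarray) -> float:
    """Closed-form LS theta for the linear-in-theta model pi ~ theta * h."""
    denom = float(h @ h)
    if denom == 0.0:
        return 0.0
    return max(float(pi @ h) / denom, 0.0)


def _profile_rss(pi: np.ndarray, eG: np.ndarray, x: np.ndarray, alpha: float) -> tuple[float, float]:
    with np.errstate(over="ignore"):
        denom = eG + alpha * x
    h = np.where(np.isinf(denom), 0.0, 1.0 / denom)
    theta = _theta_hat(pi, h)
    resid = pi - theta * h
    return float(resid @ resid), theta


def _fit_theta_alpha(
    pi: np.ndarray, eG: np.ndarray, x: np.ndarray
) -> tuple[float, float, float]:
    """Bounded least squares over (theta > 0, alpha >= 0).

    alpha is profiled out on a coarse log grid first; the best starts seed
    ``scipy.optimize.least_squares`` (multi-start: alpha = 0, the grid
    optimum and its neighbours), and the closed-form theta profile polishes
    the result.  Returns (rss, theta, alpha).
    """
    finite = np.isfinite(x) & (x > 0)
    candidates = [0.0]
    if finite.any():
        # alpha * x spanning 1e-4 .. 1e4 relative to exp(G) ~ 1
        lo = 1e-4 / float(np.max(x[finite]))
        hi = 1e4 / float(np.min(x[finite]))
        candidates.extend(np.geomspace(lo, hi, 41))
    scans = [(a, *_profile_rss(pi, eG, x, a)) for a in candidates]
    scans.sort(key=lambda t: t[1])
    best_rss, best_theta, best_alpha = scans[0][1], scans[0][2], scans[0][0]

    starts = {0.0, best_alpha}
    if best_alpha > 0:
        starts.update((best_alpha / 3.0, best_alpha * 3.0))
    for a0 in sorted(starts):
        theta0 = _profile_rss(pi, eG, x, a0)[1] or float(np.mean(pi))
        xf = np.where(np.isfinite(x), x, 0.0)
        keep = np.isfinite(x)
        try:
            sol = optimize.least_squares(
                lambda p: np.where(keep, p[0] / (eG + p[1] * xf), 0.0) - pi * keep,
                x0=[max(theta0, 1e-12), a0],
                bounds=([1e-300, 0.0], [np.inf, np.inf]),
                ftol=1e-15,
                xtol=1e-15,
                gtol=1e-15,
                max_nfev=400,
            )
        except Exception:  # singular Jacobian etc.: candidate skipped
            logger.debug("least_squares start alpha=%g failed", a0, exc_info=True)
            continue
        rss, theta = _profile_rss(pi, eG, x, float(sol.x[1]))
        if rss < best_rss:
            best_rss, best_theta, best_alpha = rss, theta, float(sol.x[1])
    return best_rss, best_theta, best_alpha


def fit_model_family(
    windows: pd.DataFrame,
    grid: Sequence[BgsParams],
    model_set: int = 1,
    *,
    fd_col: str = "fd",
    pi_col: str = "pi",
    r_col: str = "r_bp",
    literal_fd_focal: bool = False,
    g_profiles: Mapping[BgsParams, np.ndarray] | None = None,
) -> dict[str, ModelFit]:
    """Fit the four diversity models, returning the best-AIC fit per class.

    ``windows`` must carry pi, per-bp recombination rate, functional density
    and genetic window coordinates (for G).  Windows with zero recombination
    rate receive the smallest positive rate present (logged) so the sweep
    term stays finite; a constant sweep regressor leaves the hitchhiking
    term unidentifiable from theta and flags those fits degenerate.
    ``g_profiles`` may supply precomputed G arrays keyed by grid point.
    """
    if len(windows) < 20:
        raise ValueError(f"need >= 20 usable windows, got {len(windows)}")
    pi = np.asarray(windows[pi_col], dtype=float)
    n = len(pi)
    fd = np.asarray(windows[fd_col], dtype=float)
    fd_frac = fd / fd.sum()
    r_bp = np.asarray(windows[r_col], dtype=float).copy()
    zero_r = r_bp <= 0
    if zero_r.any():
        positive = r_bp[~zero_r]
        if positive.size == 0:
            raise ValueError("all recombination rates are zero")
        r_bp[zero_r] = positive.min()
        logger.info(
            "%d windows with rate 0 set to the smallest positive rate %g",
            int(zero_r.sum()),
            positive.min(),
        )
    x = sweep_scaling(fd_frac, r_bp, model_set)
    degenerate = bool(np.ptp(x[np.isfinite(x)]) <= 1e-12 * max(np.max(np.abs(x[np.isfinite(x)])), 1e-300))
    if degenerate:
        logger.warning("sweep regressor is constant: HH term unidentifiable from theta")

    fits: dict[str, ModelFit] = {}

    # neutral: closed form, no grid
    theta_n = float(np.mean(pi))
    rss_n = float(np.sum((pi - theta_n) ** 2))
    fits["neutral"] = ModelFit(
        "neutral", model_set, theta_n, 0.0, None, None, None,
        rss_n, n, MODEL_K["neutral"], _aic(rss_n, n, MODEL_K["neutral"]),
    )

    # HH-only: G = 0, no grid
    rss_h, theta_h, alpha_h = _fit_theta_alpha(pi, np.ones(n), x)
    fits["HH-only"] = ModelFit(
        "HH-only", model_set, theta_h, alpha_h, None, None, None,
        rss_h, n, MODEL_K["HH-only"], _aic(rss_h, n, MODEL_K["HH-only"]),
        degenerate=degenerate,
    )

    best_b: ModelFit | None = None
    best_f: ModelFit | None = None
    for params in grid:
        if g_profiles is not None and params in g_profiles:
            G = np.asarray(g_profiles[params], dtype=float)
        else:
            try:
                G = compute_G(windows, params, fd_col=fd_col, literal_fd_focal=literal_fd_focal)
            except Exception:
                logger.warning("G computation failed at %s: grid point skipped", params, exc_info=True)
                continue
        eG = np.exp(np.minimum(G, 700.0))  # overflow guard; e^700 already kills pi
        # BGS-only: alpha = 0, theta closed form
        w = 1.0 / eG
        theta_b = _theta_hat(pi, w)
        resid = pi - theta_b * w
        rss_b = float(resid @ resid)
        fit_b = ModelFit(
            "BGS-only", model_set, theta_b, 0.0, params.U, params.sh, params.P,
            rss_b, n, MODEL_K["BGS-only"], _aic(rss_b, n, MODEL_K["BGS-only"]),
        )
        if best_b is None or fit_b.aic < best_b.aic:
            best_b = fit_b
        # BGS+HH
        try:
            rss_f, theta_f, alpha_f = _fit_theta_alpha(pi, eG, x)
        except Exception:
            logger.warning("BGS+HH fit failed at %s: grid point skipped", params, exc_info=True)
            continue
        fit_f = ModelFit(
            "BGS+HH", model_set, theta_f, alpha_f, params.U, params.sh, params.P,
            rss_f, n, MODEL_K["BGS+HH"], _aic(rss_f, n, MODEL_K["BGS+HH"]),
            degenerate=degenerate,
        )
        if best_f is None or fit_f.aic < best_f.aic:
            best_f = fit_f
    if best_b is not None:
        fits["BGS-only"] = best_b
    else:
        logger.warning("all BGS-only grid points failed: class absent")
    if best_f is not None:
        fits["BGS+HH"] = best_f
    else:
        logger.warning("all BGS+HH grid points failed: class absent")
    return fits


def akaike_weights(best_aics: Mapping[str, float]) -> dict[str, float]:
    """Normalised relative likelihoods exp((AICmin - AIC_j)/2)."""
    if len(best_aics) < 2:
        raise ValueError("need at least two models to compare")
    aic_min = min(best_aics.values())
    rel = {m: math.exp((aic_min - a) / 2.0) for m, a in best_aics.items()}
    total = sum(rel.values())
    return {m: r / total for m, r in rel.items()}


def selection_impact(observed_mean_pi: float, theta_neutral: float) -> float:
    """Fraction of neutral diversity removed by linked selection, in [0, 1]."""
    if theta_neutral <= 0:
        raise ValueError("theta_neutral must be positive (fit invalid)")
    return max(0.0, 1.0 - observed_mean_pi / theta_neutral)


def _support_class(weight: float) -> str:
    if weight < 0.05:
        return "low"
    if weight < 0.9:
        return "medium"
    return "high"


def classify_support(weights: Mapping[str, float]) -> tuple[str, str]:
    """(neutrality class, hitchhiking class) from the Akaike weights.

    The hitchhiking class pools the HH-only and BGS+HH weights; thresholds
    are < 0.05 (low), [0.05, 0.9) (medium), >= 0.9 (high).
    """
    neutral_w = weights.get("neutral", 0.0)
    hh_w = weights.get("HH-only", 0.0) + weights.get("BGS+HH", 0.0)
    return _support_class(neutral_w), _support_class(hh_w)


def fit_selection(
    windows: pd.DataFrame,
    *,
    mu: float | None = None,
    exonic_bases: float | None = None,
    genome_size: float | None = None,
    u_values: Iterable[float] | None = None,
    p_values: Iterable[float] | None = None,
    selfing_class: str | None = None,
    sh_points: int = 13,
    model_set: int = 1,
    literal_fd_focal: bool = False,
) -> SelectionSummary:
    """End-to-end model selection for one species.

    The U grid comes either from ``u_values`` or from (mu, exonic bases,
    genome size); P from the selfing class, or all three canonical values
    when the class is unknown.  Returns the species summary with weights,
    impact of selection and support classes.
    """
    if u_values is None:
        if mu is None or exonic_bases is None:
            raise ValueError("provide u_values or (mu, exonic_bases)")
        u_values = u_grid(mu, exonic_bases, genome_size).values()
    if p_values is None:
        if selfing_class is not None:
            p_values = [P_VALUES[selfing_class]]
        else:
            p_values = list(P_VALUES.values())
    grid = [
        BgsParams(U=u, sh=s, P=p)
        for u in u_values
        for s in sh_grid(sh_points)
        for p in p_values
    ]
    fits = fit_model_family(
        windows, grid, model_set=model_set, literal_fd_focal=literal_fd_focal
    )
    weights = akaike_weights({m: f.aic for m, f in fits.items()})
    best_model = min(fits, key=lambda m: fits[m].aic)
    observed = float(np.mean(np.asarray(windows["pi"], dtype=float)))
    theta = fits[best_model].theta
    impact = selection_impact(observed, theta)
    neut_class, hh_class = classify_support(weights)
    return SelectionSummary(
        observed_mean_pi=observed,
        theta_neutral=theta,
        impact=impact,
        best_model=best_model,
        weights=weights,
        neutrality_class=neut_class,
        hh_class=hh_class,
        fits=fits,
    )
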