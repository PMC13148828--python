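"""Semi-parametric mixture model for transformed HCLC values.

The modeling pipeline is: truncate low counts, Box-Cox transform to a
continuous scale, estimate the mixture density f(z) by Lindsey's method
(Poisson regression of histogram counts on a natural cubic spline basis),
recover the singlet (null) component by Efron's central matching — a
quadratic fit to the log density near its mode — and derive the singlet
normal parameters (delta0, sigma0) and mixing proportions pi0 (among
retained cells) and pi0_tilde (whole library).  The truncation point x_min
is chosen by scanning a cross-entropy goodness-of-fit trace and taking its
elbow.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from sebula.fragments import HclcTable

logger = logging.getLogger(__name__)

DEFAULT_BINS = 120
DEFAULT_SPLINE_DF = 7
DEFAULT_WINDOW = (20.0, 60.0)
DEFAULT_MIN_CELLS = 200
_DENSITY_FLOOR = 1e-300


class ModelError(RuntimeError):
    """Base class for model-fitting failures."""


class InsufficientCellsError(ModelError):
    """Too few cells retained after truncation to fit the mixture."""


class ConcavityError(ModelError):
    """Central-matching quadratic has no concave peak (beta2 >= 0).

    Usually means the central window sits on a flat or rising stretch of
    the density; try a different x_min or window.
    """


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (without intercept) at points ``x``.

    Uses the truncated-power parametrization: for knots xi_1 < ... < xi_M
    the basis is {x, d_1 - d_{M-1}, ..., d_{M-2} - d_{M-1}} with
    d_k(x) = [(x - xi_k)^3_+ - (x - xi_M)^3_+] / (xi_M - xi_k), which is
    linear beyond the boundary knots.  M knots span an M-dimensional space
    including the intercept, so M = df + 1 knots give ``df`` basis columns.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    m = len(knots)
    if m < 3:
        raise ValueError("need at least 3 knots for a natural cubic spline")

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - knots[-1], 0, None) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x]
    d_last = d(m - 2)
    for k in range(m - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


def spline_knots(centers: np.ndarray, df: int) -> np.ndarray:
    """Knot vector for ``df`` natural-spline basis functions.

    Boundary knots at the extreme bin centers, interior knots at equally
    spaced quantiles of the centers.
    """
    probs = np.linspace(0, 1, df + 1)
    return np.quantile(np.asarray(centers, dtype=float), probs)


# ---------------------------------------------------------------------------
# truncation and Box-Cox


def truncate(
    hclc: HclcTable | np.ndarray, x_min: int, min_cells: int = DEFAULT_MIN_CELLS
) -> tuple[np.ndarray, int, int]:
    """Retain HCLC values >= x_min (and > 0) for model fitting.

    Zero counts are always excluded: the Box-Cox power transform requires
    strictly positive input, and zero-HCLC cells are assigned posterior 0
    downstream regardless.  Returns (X_T, N_T, N).
    """
    if x_min < 0:
        raise ValueError(f"x_min must be >= 0, got {x_min}")
    x = hclc.counts.values if isinstance(hclc, HclcTable) else np.asarray(hclc)
    n_total = len(x)
    retained = x[(x >= x_min) & (x > 0)].astype(float)
    if len(retained) < min_cells:
        raise InsufficientCellsError(
            f"only {len(retained)} cells retained at x_min={x_min} "
            f"(minimum {min_cells})"
        )
    return retained, len(retained), n_total


def boxcox_apply(x: np.ndarray, lam: float) -> np.ndarray:
    """z = (x^lam - 1)/lam, or log x in the lam -> 0 limit."""
    x = np.asarray(x, dtype=float)
    if abs(lam) < 1e-12:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


@dataclass
class BoxCoxTransform:
    """A fitted Box-Cox transform together with the data it was fitted on."""

    lam: float
    x_min: int
    values: np.ndarray  # X_T, retained positive HCLC
    z: np.ndarray  # Z_T, transformed values
    n_retained: int
    n_total: int

    def transform(self, x: np.ndarray) -> np.ndarray:
        return boxcox_apply(x, self.lam)


def boxcox_mle(
    x: np.ndarray, bounds: tuple[float, float] = (-2.0, 2.0), tol: float = 1e-5
) -> float:
    """Box-Cox exponent maximizing the profile log-likelihood over ``bounds``."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if np.ptp(x) == 0:
        raise ModelError("all values identical: Box-Cox likelihood is degenerate")
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, x),
        bounds=bounds,
        method="bounded",
        options={"xatol": tol},
    )
    return float(res.x)


def robust_boxcox_lambda(
    x: np.ndarray,
    pi0: float = 1.0,
    bounds: tuple[float, float] = (-2.0, 2.0),
    tol: float = 1e-5,
) -> float:
    """Contamination-robust Box-Cox exponent for the singlet component.

    The plain profile-likelihood MLE normalizes the whole sample; with a
    right-shifted multiplet component present it over-compresses the scale
    and leaves the transformed singlet left-skewed, which breaks central
    matching in the right tail.  This estimator instead chooses the
    exponent that straightens the normal Q-Q plot of the singlet-dominated
    lower quantile range: for a singlet fraction ``pi0``, the mixture
    quantile at probability p is the singlet quantile at p/pi0 as long as
    the multiplet CDF is negligible there (the zero assumption), so the
    curvature of transformed quantiles against Phi^{-1}(p/pi0) is zero at
    the singlet-normalizing exponent.  Only quantiles up to the 75th
    singlet percentile enter, keeping the estimator unaffected by
    multiplet fractions up to ~40%.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if np.ptp(x) == 0:
        raise ModelError("all values identical: transform is degenerate")
    p0 = min(max(pi0, 0.55), 1.0)
    probs = np.linspace(0.04, min(0.85, 0.75 * p0), 60)
    u = np.clip(probs / p0, 1e-4, 0.92)
    q = np.quantile(x, probs)
    phi = stats.norm.ppf(u)
    design = np.column_stack([np.ones(len(u)), phi, phi**2])

    def curvature(lam: float) -> float:
        zq = boxcox_apply(q, lam)
        s = zq.std()
        zq = (zq - zq.mean()) / (s if s > 0 else 1.0)
        return float(np.linalg.lstsq(design, zq, rcond=None)[0][2])

    lo, hi = bounds
    try:
        if curvature(lo) * curvature(hi) < 0:
            return float(optimize.brentq(curvature, lo, hi, xtol=tol))
    except ValueError:
        pass
    res = optimize.minimize_scalar(
        lambda lam: curvature(lam) ** 2, bounds=bounds, method="bounded",
        options={"xatol": tol},
    )
    return float(res.x)


def fit_boxcox(
    hclc: HclcTable | np.ndarray,
    x_min: int,
    min_cells: int = DEFAULT_MIN_CELLS,
    bounds: tuple[float, float] = (-2.0, 2.0),
) -> BoxCoxTransform:
    values, n_retained, n_total = truncate(hclc, x_min, min_cells=min_cells)
    lam = boxcox_mle(values, bounds=bounds)
    return BoxCoxTransform(
        lam=lam,
        x_min=x_min,
        values=values,
        z=boxcox_apply(values, lam),
        n_retained=n_retained,
        n_total=n_total,
    )


# ---------------------------------------------------------------------------
# mixture density (Lindsey's method)


@dataclass
class MixtureFit:
    """Poisson-spline (Lindsey) estimate of the mixture density of Z_T.

    ``fitted`` holds expected bin counts from the GLM; ``rho`` is the
    normalized per-bin probability mass.  The continuous density and CDF
    are exposed through :meth:`density` and :meth:`cdf`.
    """

    edges: np.ndarray
    centers: np.ndarray
    counts: np.ndarray
    knots: np.ndarray
    beta: np.ndarray  # intercept followed by spline coefficients
    fitted: np.ndarray
    rho: np.ndarray
    n_obs: int

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def log_intensity(self, z: np.ndarray) -> np.ndarray:
        """Fitted spline log bin-count at arbitrary z (linear outside knots)."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        design = np.column_stack(
            [np.ones(len(z)), natural_spline_basis(z, self.knots)]
        )
        return design @ self.beta

    def density(self, z: np.ndarray) -> np.ndarray:
        """Estimated mixture density f(z), normalized to integrate to 1."""
        norm = self.fitted.sum() * self.bin_width
        return np.exp(self.log_intensity(z)) / norm

    def cdf(self, z: np.ndarray) -> np.ndarray:
        """Piecewise-linear CDF through (c_i, cumulative rho), 0/1 outside."""
        z = np.asarray(z, dtype=float)
        cum = np.cumsum(self.rho)
        return np.interp(z, self.centers, cum, left=0.0, right=1.0)


def fit_mixture_density(
    z: np.ndarray, k: int = DEFAULT_BINS, spline_df: int = DEFAULT_SPLINE_DF
) -> MixtureFit:
    """Histogram Z_T on ``k`` equal bins and fit a Poisson spline GLM.

    Bin counts are treated as independent Poisson responses and regressed
    on a natural cubic spline in the bin centers with ``spline_df`` basis
    functions (log link).  With the canonical link and an intercept the
    fitted counts sum exactly to N_T, so rho sums exactly to 1.
    """
    z = np.asarray(z, dtype=float)
    if k < 20:
        raise ValueError(f"k must be >= 20, got {k}")
    counts, edges = np.histogram(z, bins=k, range=(z.min(), z.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if int((counts > 0).sum()) < spline_df + 2:
        raise ModelError(
            f"only {(counts > 0).sum()} non-empty bins for {spline_df} spline df: "
            "data too sparse"
        )
    knots = spline_knots(centers, spline_df)
    design = np.column_stack(
        [np.ones(k), natural_spline_basis(centers, knots)]
    )
    glm = sm.GLM(counts, design, family=sm.families.Poisson())
    try:
        res = glm.fit(maxiter=200)
    except Exception as err:  # pragma: no cover - statsmodels failure path
        raise ModelError(f"Poisson spline GLM failed: {err}") from err
    if not res.converged:
        raise ModelError("Poisson spline GLM did not converge")
    fitted = np.asarray(res.fittedvalues, dtype=float)
    return MixtureFit(
        edges=edges,
        centers=centers,
        counts=counts,
        knots=knots,
        beta=np.asarray(res.params, dtype=float),
        fitted=fitted,
        rho=fitted / fitted.sum(),
        n_obs=int(counts.sum()),
    )


# ---------------------------------------------------------------------------
# central matching


@dataclass
class NullFit:
    """Singlet (empirical null) component recovered by central matching."""

    c_max: float
    quad: tuple[float, float, float]  # (beta0, beta1, beta2) about c_max
    delta0: float
    sigma0: float
    pi0_hat: float  # singlet proportion among retained cells
    pi0_tilde: float  # singlet proportion in the whole library
    f_tilde: np.ndarray  # unnormalized singlet counts per bin
    window: tuple[float, float]
    window_used: tuple[float, float] | None = None  # after refinement shrink
    n_refine: int = 0

    def density(self, z: np.ndarray) -> np.ndarray:
        return stats.norm.pdf(z, loc=self.delta0, scale=self.sigma0)

    def cdf(self, z: np.ndarray) -> np.ndarray:
        return stats.norm.cdf(z, loc=self.delta0, scale=self.sigma0)


def _window_quadratic(
    centers: np.ndarray, resp: np.ndarray, sel: np.ndarray, c_max: float
) -> tuple[float, float, float]:
    t = centers[sel] - c_max
    design = np.column_stack([np.ones(t.size), t, t**2])
    coef, *_ = np.linalg.lstsq(
        design, np.log(np.maximum(resp[sel], 1e-12)), rcond=None
    )
    return tuple(float(v) for v in coef)


def fit_null_central_matching(
    fit: MixtureFit,
    z: np.ndarray,
    n_retained: int,
    n_total: int,
    window: tuple[float, float] = DEFAULT_WINDOW,
    refine: bool = True,
    max_refine: int = 10,
    min_residual: float = 0.005,
    overshoot_tol: float = 0.008,
) -> NullFit:
    """Quadratic fit to the log fitted density around its mode.

    A normal singlet density makes log{pi0 f0(z)} exactly quadratic, so
    OLS of log fitted counts on (c - c_max) and (c - c_max)^2 over bins in
    the central percentile window identifies delta0, sigma0 and (by
    integrating the implied singlet counts) pi0.  The window percentiles
    are taken on Z_T, and the smoothed (fitted) counts are used as the
    response so empty bins cause no trouble.

    With ``refine`` (the default) the initial fit is iteratively
    decontaminated: when the multiplet component overlaps the central
    window, the plain quadratic drifts wide and absorbs it.  Two
    self-consistency signals drive the loop.  First, excess fitted counts
    to the right of the null peak (beyond delta0 + sigma0) are summarized
    by a normal bump — its moments corrected for the one-sided cut — whose
    extension into the window is subtracted from the response.  Second, if
    the implied singlet counts overshoot the observed fit on the left
    flank (left of the window, where essentially only singlets live), the
    window's upper, contamination-prone edge is stepped down, never below
    the 40th percentile.  On data where the null component is cleanly
    separated both signals stay silent and the result equals the plain
    central-matching fit.
    """
    z = np.asarray(z, dtype=float)
    lo, hi = np.percentile(z, window)
    q40 = np.percentile(z, 40)
    i_max = int(np.argmax(fit.fitted))  # lowest index wins ties via argmax
    c_max = float(fit.centers[i_max])
    sel0 = (fit.centers >= lo) & (fit.centers <= hi) & (fit.fitted > 0)
    if int(sel0.sum()) < 3:
        raise ModelError(
            f"fewer than 3 positive-density bins inside the central window "
            f"[{lo:.3g}, {hi:.3g}]"
        )
    centers, fitted, dlt = fit.centers, fit.fitted, fit.bin_width
    t_all = centers - c_max
    hi_cur = hi
    resp = fitted.copy()
    result = None
    n_iter = 0
    for it in range(max_refine + 1):
        sel = (centers >= lo) & (centers <= hi_cur) & (resp > 0)
        if int(sel.sum()) < 3:
            break
        b0, b1, b2 = _window_quadratic(centers, resp, sel, c_max)
        if b2 >= 0:
            if result is not None:
                break
            raise ConcavityError(
                f"central-matching quadratic is not concave (beta2={b2:.4g}); "
                "try a different x_min or central window"
            )
        f_tilde = np.exp(b0 + b1 * t_all + b2 * t_all**2)
        delta0 = c_max - b1 / (2.0 * b2)
        sigma0 = (-2.0 * b2) ** -0.5
        result = (b0, b1, b2, delta0, sigma0, f_tilde)
        n_iter = it
        if not refine or it == max_refine:
            break
        acted = False
        # signal 1: right-tail residual bump, extrapolated into the window
        mask = centers > delta0 + sigma0
        resid = np.where(mask, np.maximum(fitted - f_tilde, 0.0), 0.0)
        if resid.sum() / fitted.sum() > min_residual:
            d1 = float((resid * centers).sum() / resid.sum())
            if d1 > delta0 + sigma0:
                s1 = float(
                    np.sqrt(
                        max((resid * (centers - d1) ** 2).sum() / resid.sum(), 1e-6)
                    )
                )
                # visible residual mass, modestly extrapolated below the cut
                # (the factor is capped at 2 to keep the correction tame)
                total = resid.sum() / max(
                    stats.norm.sf((delta0 + sigma0 - d1) / s1), 0.5
                )
                bump = np.minimum(
                    total * stats.norm.pdf(centers, d1, s1) * dlt, 0.9 * fitted
                )
                new_resp = np.maximum(fitted - bump, 1e-12)
                if not np.allclose(new_resp, resp, rtol=1e-4):
                    acted = True
                resp = new_resp
        # signal 2: left-flank overshoot marks a contaminated window top
        overshoot = (
            np.maximum(f_tilde - fitted, 0.0)[centers < lo].sum() / fitted.sum()
        )
        if overshoot > overshoot_tol and hi_cur - dlt > q40:
            hi_cur -= dlt
            acted = True
        if not acted:
            break
    if result is None:
        raise ModelError("central-matching window collapsed during refinement")
    b0, b1, b2, delta0, sigma0, f_tilde = result
    if not np.isfinite(sigma0) or sigma0 <= 0:
        raise ConcavityError(f"non-finite singlet s.d. (sigma0={sigma0!r})")
    pi0_hat = min(1.0, float(f_tilde.sum() / fitted.sum()))
    pi0_tilde = 1.0 - (n_retained / n_total) * (1.0 - pi0_hat)
    return NullFit(
        c_max=c_max,
        quad=(b0, b1, b2),
        delta0=float(delta0),
        sigma0=float(sigma0),
        pi0_hat=pi0_hat,
        pi0_tilde=pi0_tilde,
        f_tilde=f_tilde,
        window=(float(lo), float(hi)),
        window_used=(float(lo), float(min(hi_cur, hi))),
        n_refine=n_iter,
    )



def cross_entropy(null: NullFit, z: np.ndarray) -> float:
    """Goodness-of-fit of the singlet normal in its one-sigma central band.

    CE = -mean log f0_hat(z_j) over S = {z_j : delta0 - sigma0 <= z_j <=
    delta0 + sigma0}; lower is better.
    """
    z = np.asarray(z, dtype=float)
    s = z[(z >= null.delta0 - null.sigma0) & (z <= null.delta0 + null.sigma0)]
    if s.size == 0:
        raise ModelError(
            f"no observations inside [{null.delta0 - null.sigma0:.4g}, "
            f"{null.delta0 + null.sigma0:.4g}] for cross-entropy"
        )
    return float(-np.mean(stats.norm.logpdf(s, loc=null.delta0, scale=null.sigma0)))


# ---------------------------------------------------------------------------
# full model and truncation-point selection


@dataclass
class SebulaModel:
    """Bundle of the fitted transform, mixture density and singlet null."""

    transform: BoxCoxTransform
    mixture: MixtureFit
    null: NullFit
    ce: float

    @property
    def x_min(self) -> int:
        return self.transform.x_min

    def to_dict(self) -> dict:
        return {
            "lam": self.transform.lam,
            "x_min": self.transform.x_min,
            "n_retained": self.transform.n_retained,
            "n_total": self.transform.n_total,
            "k": len(self.mixture.centers),
            "edges": self.mixture.edges.tolist(),
            "counts": self.mixture.counts.tolist(),
            "knots": self.mixture.knots.tolist(),
            "beta": self.mixture.beta.tolist(),
            "c_max": self.null.c_max,
            "quad": list(self.null.quad),
            "delta0": self.null.delta0,
            "sigma0": self.null.sigma0,
            "pi0_hat": self.null.pi0_hat,
            "pi0_tilde": self.null.pi0_tilde,
            "window": list(self.null.window),
            "cross_entropy": self.ce,
        }

    def to_json(self, path: str | Path, scan: "TruncationScan | None" = None) -> None:
        payload = self.to_dict()
        if scan is not None:
            payload["xmin_scan"] = {
                "grid": [int(g) for g in scan.grid],
                "ce": [None if not np.isfinite(c) else float(c) for c in scan.ce],
                "retained": [int(r) for r in scan.retained],
                "chosen": int(scan.chosen),
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SebulaModel":
        with open(path) as fh:
            d = json.load(fh)
        edges = np.asarray(d["edges"], dtype=float)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = np.asarray(d["counts"], dtype=float)
        knots = np.asarray(d["knots"], dtype=float)
        beta = np.asarray(d["beta"], dtype=float)
        design = np.column_stack(
            [np.ones(len(centers)), natural_spline_basis(centers, knots)]
        )
        fitted = np.exp(design @ beta)
        mixture = MixtureFit(
            edges=edges,
            centers=centers,
            counts=counts,
            knots=knots,
            beta=beta,
            fitted=fitted,
            rho=fitted / fitted.sum(),
            n_obs=int(counts.sum()),
        )
        null = NullFit(
            c_max=d["c_max"],
            quad=tuple(d["quad"]),
            delta0=d["delta0"],
            sigma0=d["sigma0"],
            pi0_hat=d["pi0_hat"],
            pi0_tilde=d["pi0_tilde"],
            f_tilde=np.exp(
                d["quad"][0]
                + d["quad"][1] * (centers - d["c_max"])
                + d["quad"][2] * (centers - d["c_max"]) ** 2
            ),
            window=tuple(d["window"]),
        )
        # Z_T is not stored; reconstruct the transform shell for metadata.
        transform = BoxCoxTransform(
            lam=d["lam"],
            x_min=d["x_min"],
            values=np.array([]),
            z=np.array([]),
            n_retained=d["n_retained"],
            n_total=d["n_total"],
        )
        return cls(transform=transform, mixture=mixture, null=null, ce=d["cross_entropy"])


def _fit_at_lambda(
    values: np.ndarray,
    n_retained: int,
    n_total: int,
    x_min: int,
    lam: float,
    k: int,
    spline_df: int,
    window: tuple[float, float],
    refine: bool,
) -> SebulaModel:
    transform = BoxCoxTransform(
        lam=lam,
        x_min=x_min,
        values=values,
        z=boxcox_apply(values, lam),
        n_retained=n_retained,
        n_total=n_total,
    )
    mixture = fit_mixture_density(transform.z, k=k, spline_df=spline_df)
    null = fit_null_central_matching(
        mixture,
        transform.z,
        n_retained,
        n_total,
        window=window,
        refine=refine,
    )
    ce = cross_entropy(null, transform.z)
    return SebulaModel(transform=transform, mixture=mixture, null=null, ce=ce)


def estimate_lambda(
    hclc: HclcTable | np.ndarray,
    k: int = DEFAULT_BINS,
    spline_df: int = DEFAULT_SPLINE_DF,
    window: tuple[float, float] = DEFAULT_WINDOW,
    min_cells: int = DEFAULT_MIN_CELLS,
    refine: bool = True,
    max_iter: int = 4,
    starts: tuple[float, ...] = (1.0, 0.8, 0.6),
) -> float:
    """Singlet-normalizing Box-Cox exponent for a library.

    Runs the robust quantile-curvature estimator in a small fixed-point
    loop with the central-matching fit: the estimator needs the singlet
    fraction to map mixture quantiles onto singlet quantiles, and the fit
    needs the exponent.  Starting from an all-singlet assumption, each
    round re-estimates the exponent at the fitted pi0.  If a start fails
    to produce a concave central fit, progressively more contaminated
    starting fractions are tried.  The exponent is estimated on all
    positive counts and is independent of any truncation threshold, so
    downstream results are stable across x_min choices.
    """
    x = hclc.counts.values if isinstance(hclc, HclcTable) else np.asarray(hclc)
    xpos = x[x > 0].astype(float)
    values, n_ret, n_tot = truncate(x, 0, min_cells=min_cells)
    last_err: Exception | None = None
    for p0 in starts:
        lam = robust_boxcox_lambda(xpos, pi0=p0)
        lam_ok: float | None = None
        for it in range(max_iter):
            try:
                model = _fit_at_lambda(
                    values, n_ret, n_tot, 0, lam, k, spline_df, window, refine
                )
            except ModelError as err:
                last_err = err
                break
            lam_ok = lam
            if it < max_iter - 1:
                lam_new = robust_boxcox_lambda(xpos, pi0=model.null.pi0_hat)
                if abs(lam_new - lam) < 1e-3:
                    break
                lam = lam_new
        if lam_ok is not None:
            return lam_ok
        logger.info("lambda start pi0=%.2f failed (%s); trying next", p0, last_err)
    raise ModelError(f"no Box-Cox exponent produced a concave fit: {last_err}")


def fit_model(
    hclc: HclcTable | np.ndarray,
    x_min: int,
    k: int = DEFAULT_BINS,
    spline_df: int = DEFAULT_SPLINE_DF,
    window: tuple[float, float] = DEFAULT_WINDOW,
    min_cells: int = DEFAULT_MIN_CELLS,
    lam: float | str = "robust",
    refine: bool = True,
) -> SebulaModel:
    """Fit the full semi-parametric model at a fixed truncation point.

    ``lam`` selects the transform policy: "robust" (default) estimates
    the singlet-normalizing exponent on all positive counts via
    :func:`estimate_lambda`; "mle" uses the plain Box-Cox profile MLE on
    the retained values; a float fixes the exponent directly.
    """
    x = hclc.counts.values if isinstance(hclc, HclcTable) else np.asarray(hclc)
    values, n_ret, n_tot = truncate(x, x_min, min_cells=min_cells)
    if lam == "robust":
        lam_val = estimate_lambda(
            x, k=k, spline_df=spline_df, window=window, min_cells=min_cells,
            refine=refine,
        )
    elif lam == "mle":
        lam_val = boxcox_mle(values)
    else:
        lam_val = float(lam)
    return _fit_at_lambda(
        values, n_ret, n_tot, x_min, lam_val, k, spline_df, window, refine
    )


@dataclass
class TruncationScan:
    """Cross-entropy trace over candidate truncation points."""

    grid: np.ndarray
    ce: np.ndarray  # NaN where the fit failed
    retained: np.ndarray
    chosen: int
    lam: float | None = None  # transform exponent shared across the scan
    models: dict[int, SebulaModel] = field(default_factory=dict)


def _elbow(grid: np.ndarray, ce: np.ndarray) -> int:
    """Elbow of the CE trace: maximum perpendicular distance to the chord.

    Both axes are rescaled to [0, 1] before measuring distance so the
    choice does not depend on the units of either axis.  Only candidates
    on the convex (below-chord) side count as elbows: a point below the
    chord marks super-linear early improvement followed by diminishing
    returns, which is the trade-off the trace scan is looking for.  A
    trace with no point below the chord — linear, or flat-then-plunging,
    where heavier truncation buys no early gain — resolves to the
    smallest candidate, as do ties.
    """
    ok = np.isfinite(ce)
    g, c = grid[ok].astype(float), ce[ok].astype(float)
    gs = (g - g[0]) / (g[-1] - g[0]) if g[-1] > g[0] else np.zeros_like(g)
    span = c.max() - c.min()
    cs = (c - c[0]) / span if span > 0 else np.zeros_like(c)
    # signed offset of each point from the chord joining first and last
    # points; cross < 0 means below the chord (convex side)
    dx, dy = gs[-1] - gs[0], cs[-1] - cs[0]
    norm = np.hypot(dx, dy)
    if norm == 0:
        return int(g[0])
    cross = dx * (cs - cs[0]) - dy * (gs - gs[0])
    dist = np.round(-cross / norm, 12)
    if dist.max() <= 0:
        return int(g[0])
    return int(g[int(np.argmax(dist))])


def select_xmin(
    hclc: HclcTable | np.ndarray,
    grid: Sequence[int] | None = None,
    k: int = DEFAULT_BINS,
    spline_df: int = DEFAULT_SPLINE_DF,
    window: tuple[float, float] = DEFAULT_WINDOW,
    min_cells: int = DEFAULT_MIN_CELLS,
    keep_models: bool = False,
) -> TruncationScan:
    """Scan candidate x_min values and pick the elbow of the CE trace.

    The default grid is the integers 0..Q1 where Q1 is the 25th percentile
    of the positive HCLC values.  Candidates whose fit fails (too few
    cells, no concave peak) are skipped with a log message; if fewer than
    two candidates yield a finite CE the scan falls back to x_min = 0.
    """
    x = hclc.counts.values if isinstance(hclc, HclcTable) else np.asarray(hclc)
    if grid is None:
        q1 = int(np.percentile(x[x > 0], 25))
        grid = list(range(0, q1 + 1))
    grid = np.asarray(sorted(set(int(g) for g in grid)))
    # one transform for the whole scan: estimated on all positive counts,
    # so the CE trace compares truncations on a common scale
    lam = estimate_lambda(
        x, k=k, spline_df=spline_df, window=window, min_cells=min_cells
    )
    ce = np.full(len(grid), np.nan)
    retained = np.zeros(len(grid), dtype=int)
    models: dict[int, SebulaModel] = {}
    for i, g in enumerate(grid):
        try:
            # the trace uses the plain central-matching fit: CE is a pure
            # goodness-of-fit diagnostic of the quadratic null
            m = fit_model(
                hclc, int(g), k=k, spline_df=spline_df, window=window,
                min_cells=min_cells, lam=lam, refine=False,
            )
        except ModelError as err:
            logger.info("x_min=%d skipped: %s", g, err)
            continue
        ce[i] = m.ce
        retained[i] = m.transform.n_retained
        if keep_models:
            models[int(g)] = m
    n_finite = int(np.isfinite(ce).sum())
    if n_finite < 2:
        logger.warning(
            "fewer than 2 candidates produced a finite cross-entropy; "
            "falling back to x_min=0"
        )
        chosen = 0
    elif len(grid) == 1:
        chosen = int(grid[0])
    else:
        chosen = _elbow(grid, ce)
    return TruncationScan(
        grid=grid, ce=ce, retained=retained, chosen=chosen, lam=lam, models=models
    )
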