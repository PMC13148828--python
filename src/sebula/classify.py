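"""Per-cell multiplet posteriors and calling rules.

Posterior: p_j = 1 - pi0_hat * f0_hat(z_j) / f_hat(z_j), clipped to [0, 1],
with p_j = 0 for cells excluded by truncation (x_j < x_min or x_j = 0).
Calls are made either by thresholding p_j (lfdr rule, default p > 0.8,
i.e. an lfdr of at most 20%) or by the tail-FDR rule: call all cells with
z >= t*, where t* is the smallest threshold whose estimated tail FDR
pi0_hat * (1 - F0_hat(t)) / (1 - F_hat(t)) meets the target level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from sebula.fragments import HclcTable
from sebula.model import SebulaModel, _DENSITY_FLOOR

logger = logging.getLogger(__name__)

DEFAULT_LFDR_THRESHOLD = 0.8
DEFAULT_FDR_TARGET = 0.2

#: Scale of the rank-based tie-break added to monotone posteriors.  Far
#: below any calling threshold or printed precision; only orders cells
#: whose posteriors are numerically identical.
_TIE_EPS = 1e-9


def posterior_probs(
    hclc: HclcTable, model: SebulaModel, monotone: bool = True
) -> pd.DataFrame:
    """Per-barcode multiplet posterior under a fitted model.

    Returns a frame with columns barcode, hclc, z, posterior, posterior_raw,
    lfdr.  Cells below the truncation point (or with zero HCLC) get
    posterior 0 and an undefined z; cells exactly at x_min are scored by
    the model.

    ``posterior_raw`` is the plain density-ratio value 1 - pi0 f0(z)/f(z)
    clipped to [0, 1].  Because a multiplet carries roughly the chromatin
    of two nuclei, the likelihood ratio f1/f0 is monotone in the count, so
    with ``monotone`` (the default) the reported posterior is additionally
    the isotonic projection of the raw values onto non-decreasing-in-z,
    which irons out spline wiggle; remaining exact ties are ordered by the
    underlying count at a 1e-9 scale so that rankings are well defined.
    """
    x = hclc.counts.values.astype(float)
    retained = (x >= model.x_min) & (x > 0)
    z = np.full(len(x), np.nan)
    p_raw = np.zeros(len(x))
    if retained.any():
        z_r = model.transform.transform(x[retained])
        f = model.mixture.density(z_r)
        n_floored = int((f <= _DENSITY_FLOOR).sum())
        if n_floored:
            logger.warning(
                "mixture density underflowed at %d cells; floored at %g",
                n_floored,
                _DENSITY_FLOOR,
            )
        f = np.maximum(f, _DENSITY_FLOOR)
        f0 = model.null.density(z_r)
        p_raw[retained] = np.clip(1.0 - model.null.pi0_hat * f0 / f, 0.0, 1.0)
        z[retained] = z_r
    p = p_raw.copy()
    if monotone and retained.any():
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
        p[retained] = iso.fit_transform(z[retained], p_raw[retained])
        ranks = rankdata(z[retained], method="average")
        p[retained] = np.minimum(p[retained] + _TIE_EPS * ranks / ranks.size, 1.0)
    return pd.DataFrame(
        {
            "barcode": hclc.counts.index,
            "hclc": hclc.counts.values,
            "z": z,
            "posterior": p,
            "posterior_raw": p_raw,
            "lfdr": 1.0 - p,
        }
    )


def call_by_lfdr(
    posteriors: pd.DataFrame, threshold: float = DEFAULT_LFDR_THRESHOLD
) -> pd.DataFrame:
    """Call multiplets where posterior > threshold (strict inequality)."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    out = posteriors.copy()
    out["call"] = out["posterior"].values > threshold
    return out


@dataclass
class FdrCurve:
    """Estimated tail FDR over a grid of transformed-scale thresholds."""

    thresholds: np.ndarray
    fdr: np.ndarray
    target: float
    t_star: float | None  # smallest threshold achieving the target, if any


def fdr_curve(
    model: SebulaModel, target: float = DEFAULT_FDR_TARGET, n_grid: int = 2001
) -> FdrCurve:
    """Tail-FDR estimate Fdr(t) = pi0_hat (1 - F0(t)) / (1 - F(t)).

    The grid spans [min Z_T, max Z_T + 3 sigma0]; the mixture survival
    (1 - F) is floored at 1/N_T so the extreme tail stays defined, and the
    estimate is clipped to [0, 1].  t* is the smallest grid threshold with
    Fdr(t) <= target; if none achieves it the rule makes no calls.
    """
    if not 0 < target < 1:
        raise ValueError(f"target must be in (0, 1), got {target}")
    z = model.transform.z
    if z.size:
        t_lo, t_hi = float(z.min()), float(z.max()) + 3.0 * model.null.sigma0
    else:  # model reloaded from JSON: fall back to the bin grid
        t_lo = float(model.mixture.edges[0])
        t_hi = float(model.mixture.edges[-1]) + 3.0 * model.null.sigma0
    grid = np.linspace(t_lo, t_hi, n_grid)
    surv0 = 1.0 - model.null.cdf(grid)
    surv = np.maximum(1.0 - model.mixture.cdf(grid), 1.0 / model.transform.n_retained)
    fdr = np.clip(model.null.pi0_hat * surv0 / surv, 0.0, 1.0)
    below = np.nonzero(fdr <= target)[0]
    t_star = float(grid[below[0]]) if below.size else None
    if t_star is None:
        logger.warning("no threshold achieves tail FDR <= %g; zero calls", target)
    return FdrCurve(thresholds=grid, fdr=fdr, target=target, t_star=t_star)


def call_by_fdr(posteriors: pd.DataFrame, curve: FdrCurve) -> pd.DataFrame:
    """Call multiplets with z >= t*; excluded cells are never called."""
    out = posteriors.copy()
    if curve.t_star is None:
        out["call"] = False
    else:
        z = out["z"].values
        out["call"] = np.where(np.isnan(z), False, z >= curve.t_star)
    return out


def write_calls(calls: pd.DataFrame, path) -> None:
    """Write the calls table as TSV with 6-significant-digit probabilities."""
    df = calls.copy()
    for col in ("z", "posterior", "posterior_raw", "lfdr"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    df.to_csv(path, sep="\t", index=False)
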