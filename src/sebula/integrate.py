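"""Naive-Bayes integration of HCLC evidence with external per-cell scores.

The HCLC analysis is summarized per cell by a Bayes factor
BF_j = [p_j / (1 - p_j)] / [(1 - pi0_tilde) / pi0_tilde], the posterior
odds of multiplet divided by the prior odds.  Treating an external
per-cell multiplet probability q as a prior and assuming the two evidence
sources are conditionally independent given the label, the combined
posterior is q BF / (q BF + 1 - q).  Updating with the prior q =
1 - pi0_tilde recovers the HCLC-only posterior exactly, and updates
compose multiplicatively (BF_a then BF_b equals BF_a * BF_b).

External evidence may arrive as posteriors (used directly), z-scores
(an empirical-null central-matching fit converts them to posteriors), or
p-values (mapped to z-scores by the inverse-normal transform first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from sebula.model import (
    cross_entropy,
    fit_mixture_density,
    fit_null_central_matching,
    _DENSITY_FLOOR,
)

logger = logging.getLogger(__name__)

EVIDENCE_KINDS = ("posterior", "zscore", "pvalue")
_EPS = 1e-10
_MIN_SCORES_FOR_NULL_FIT = 200


def bayes_factor(p: np.ndarray | float, pi0_tilde: float) -> np.ndarray | float:
    """Bayes factor of the HCLC data from its posterior and the library prior.

    BF = [p/(1-p)] * [pi0_tilde/(1-pi0_tilde)].  Posteriors are clipped to
    [eps, 1-eps] before forming odds, except that p = 0 exactly (an
    excluded cell) maps to BF = 0.
    """
    if not 0 < pi0_tilde < 1:
        raise ValueError(f"pi0_tilde must be in (0, 1), got {pi0_tilde}")
    p_arr = np.asarray(p, dtype=float)
    pc = np.clip(p_arr, _EPS, 1.0 - _EPS)
    bf = (pc / (1.0 - pc)) * (pi0_tilde / (1.0 - pi0_tilde))
    bf = np.where(p_arr == 0.0, 0.0, bf)
    return float(bf) if np.isscalar(p) else bf


def update_posterior(
    q: np.ndarray | float, bf: np.ndarray | float
) -> np.ndarray | float:
    """Sequential Bayes update: combined = q bf / (q bf + 1 - q).

    q = 0 and q = 1 are absorbing regardless of the Bayes factor.
    """
    q_arr = np.asarray(q, dtype=float)
    bf_arr = np.asarray(bf, dtype=float)
    if np.any((q_arr < 0) | (q_arr > 1)):
        raise ValueError("prior probabilities must lie in [0, 1]")
    if np.any(bf_arr < 0):
        raise ValueError("Bayes factors must be non-negative")
    num = q_arr * bf_arr
    denom = num + (1.0 - q_arr)
    with np.errstate(invalid="ignore"):
        combined = np.where(denom > 0, num / np.maximum(denom, 1e-300), 1.0)
    combined = np.where(q_arr == 1.0, 1.0, combined)
    combined = np.where(q_arr == 0.0, 0.0, combined)
    scalar = np.isscalar(q) and np.isscalar(bf)
    return float(combined) if scalar else combined


def evidence_to_prior(
    scores: pd.Series | np.ndarray,
    kind: str,
    k: int = 120,
    spline_df: int = 7,
    window: tuple[float, float] = (20.0, 60.0),
) -> np.ndarray:
    """Convert external per-cell scores into multiplet prior probabilities.

    posterior: passed through, clipped to [0, 1].
    zscore: the empirical-null machinery (Lindsey density + central
        matching, no Box-Cox) is fitted to the scores and the resulting
        multiplet posterior is returned.
    pvalue: p-values are mapped to z = Phi^{-1}(1 - p), then as zscore.
    """
    if kind not in EVIDENCE_KINDS:
        raise ValueError(f"kind must be one of {EVIDENCE_KINDS}, got {kind!r}")
    values = np.asarray(
        scores.values if isinstance(scores, pd.Series) else scores, dtype=float
    )
    if kind == "posterior":
        if np.any((values < 0) | (values > 1)):
            raise ValueError("posterior scores must lie in [0, 1]")
        return np.clip(values, 0.0, 1.0)
    if kind == "pvalue":
        if np.any((values <= 0) | (values > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        values = stats.norm.ppf(1.0 - values)
    if len(values) < _MIN_SCORES_FOR_NULL_FIT:
        raise ValueError(
            f"need >= {_MIN_SCORES_FOR_NULL_FIT} scores for empirical-null "
            f"fitting, got {len(values)}"
        )
    mixture = fit_mixture_density(values, k=k, spline_df=spline_df)
    null = fit_null_central_matching(
        mixture, values, n_retained=len(values), n_total=len(values), window=window
    )
    f = np.maximum(mixture.density(values), _DENSITY_FLOOR)
    raw = np.clip(1.0 - null.pi0_hat * null.density(values) / f, 0.0, 1.0)
    # scores with larger values are more multiplet-like: project onto a
    # non-decreasing curve so spline wiggle cannot invert the ranking
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    prior = iso.fit_transform(values, raw)
    ranks = stats.rankdata(values)
    return np.minimum(prior + 1e-9 * ranks / ranks.size, 1.0)


def integrate_evidence(
    calls: pd.DataFrame,
    evidence: pd.DataFrame,
    kind: str,
    pi0_tilde: float,
    lfdr_threshold: float = 0.8,
) -> pd.DataFrame:
    """Join HCLC calls with an external evidence table and update posteriors.

    ``calls`` must carry barcode and posterior columns (from the classify
    stage); ``evidence`` must carry barcode and score.  Barcodes present
    in only one source keep that source's posterior alone and are flagged
    in the ``sources`` column.
    """
    if not {"barcode", "score"}.issubset(evidence.columns):
        raise ValueError("evidence table must have columns 'barcode' and 'score'")
    ev = evidence.copy()
    ev["prior"] = evidence_to_prior(ev["score"], kind)
    merged = calls.merge(ev[["barcode", "prior"]], on="barcode", how="outer")
    p_atac = merged["posterior"].values
    prior = merged["prior"].values
    has_atac = ~np.isnan(p_atac)
    has_prior = ~np.isnan(prior)
    bf = np.where(has_atac, bayes_factor(np.nan_to_num(p_atac), pi0_tilde), 1.0)
    combined = np.where(
        has_prior,
        update_posterior(np.nan_to_num(prior), bf),
        np.nan_to_num(p_atac),
    )
    sources = np.select(
        [has_atac & has_prior, has_atac, has_prior],
        ["both", "hclc_only", "evidence_only"],
        default="none",
    )
    out = pd.DataFrame(
        {
            "barcode": merged["barcode"],
            "p_atac": p_atac,
            "prior": prior,
            "bf": bf,
            "combined": combined,
            "call": combined > lfdr_threshold,
            "sources": sources,
        }
    )
    n_partial = int((sources != "both").sum())
    if n_partial:
        logger.warning("%d barcodes present in only one evidence source", n_partial)
    return out


@dataclass
class DependenceReport:
    """Correlation diagnostics for the conditional-independence assumption."""

    pearson: float
    spearman: float
    n: int


def score_dependence(a: np.ndarray, b: np.ndarray) -> DependenceReport:
    """Pearson and Spearman correlation between two per-cell score vectors.

    A diagnostic for the naive-Bayes independence assumption: strongly
    correlated evidence sources overstate the combined posterior.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired scores")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("zero variance in a score vector; correlation undefined")
        return DependenceReport(pearson=np.nan, spearman=np.nan, n=a.size)
    report = DependenceReport(
        pearson=float(stats.pearsonr(a, b).statistic),
        spearman=float(stats.spearmanr(a, b).statistic),
        n=a.size,
    )
    logger.info(
        "score dependence: pearson=%.3f spearman=%.3f n=%d",
        report.pearson,
        report.spearman,
        report.n,
    )
    return report
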