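"""Synthetic singlet/doublet data and evaluation metrics.

Two generators mirror the artificial-doublet protocol used to benchmark
HCLC-based multiplet detection:

* HCLC mode draws singlet counts from an overdispersed negative binomial
  and forms each doublet as the sum of two independent singlet draws —
  pooling two nuclei roughly doubles the number of high-coverage loci.
* Fragment mode writes an actual 5-column fragment file on a toy genome:
  singlet cells scatter fragments over a fixed locus layout, and doublet
  barcodes receive the union of two singlet cells' fragments, so the full
  preprocessing pipeline (sweep line, merge, binary matrix) can be
  exercised end to end.

The negative binomial is parametrized by its mean and its dispersion
index (variance-to-mean ratio), the natural overdispersion scale for
count data; index 1 recovers the Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
)

from sebula.fragments import HclcTable

DEFAULT_NB_MEAN = 40.0
DEFAULT_NB_DISPERSION = 5.0  # variance-to-mean ratio


@dataclass
class SimConfig:
    """Configuration for one synthetic dataset.

    ``nb_dispersion`` is the variance-to-mean ratio of the singlet
    negative binomial (must exceed 1); the NB shape parameter is
    mean / (dispersion - 1).  Fragment-mode extras control the toy genome
    layout.  Identical configs yield identical datasets.
    """

    n_cells: int = 10_000
    doublet_prop: float = 0.2
    nb_mean: float = DEFAULT_NB_MEAN
    nb_dispersion: float = DEFAULT_NB_DISPERSION
    seed: int = 0
    mode: str = "hclc"
    # fragment-mode layout
    genome_length: int = 200_000
    n_loci: int = 60
    locus_width: int = 400
    frag_rate: float = 1.5  # mean fragments per (cell, locus)
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if not 0 <= self.doublet_prop <= 0.5:
            raise ValueError(
                f"doublet_prop must be in [0, 0.5], got {self.doublet_prop}"
            )
        if self.nb_mean <= 0:
            raise ValueError("nb_mean must be positive")
        if self.nb_dispersion <= 1:
            raise ValueError(
                "nb_dispersion (variance/mean ratio) must exceed 1; "
                "use a Poisson generator for equidispersed counts"
            )
        if self.mode not in ("hclc", "fragments"):
            raise ValueError(f"mode must be 'hclc' or 'fragments', got {self.mode!r}")
        if self.mode == "fragments":
            span = self.n_loci * 2 * self.locus_width
            if span > self.genome_length:
                raise ValueError(
                    f"genome too small: {self.n_loci} loci of width "
                    f"{self.locus_width} need > {span} bp"
                )

    @property
    def nb_shape(self) -> float:
        return self.nb_mean / (self.nb_dispersion - 1.0)


def _nb_draw(rng: np.random.Generator, config: SimConfig, size: int) -> np.ndarray:
    r = config.nb_shape
    p = r / (r + config.nb_mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_hclc(config: SimConfig) -> pd.DataFrame:
    """HCLC-level singlets and pair-sum doublets with truth labels.

    Returns a frame with columns barcode, hclc, label ('singlet' or
    'doublet'); the doublet count is round(n_cells * doublet_prop).
    """
    rng = np.random.default_rng(config.seed)
    n_doub = int(round(config.n_cells * config.doublet_prop))
    n_sing = config.n_cells - n_doub
    sing = _nb_draw(rng, config, n_sing)
    doub = _nb_draw(rng, config, n_doub) + _nb_draw(rng, config, n_doub)
    hclc = np.concatenate([sing, doub])
    labels = np.array(["singlet"] * n_sing + ["doublet"] * n_doub)
    barcodes = np.array([f"BC{i:06d}" for i in range(config.n_cells)])
    order = rng.permutation(config.n_cells)
    return pd.DataFrame(
        {"barcode": barcodes, "hclc": hclc[order], "label": labels[order]}
    )


def simulate_fragments(
    config: SimConfig, outdir: str | Path | None = None
) -> dict[str, object]:
    """Fragment-level simulation on a toy genome.

    Each latent cell draws a Poisson number of fragments at each locus
    (fragments overlap heavily within a locus so three or more of them
    form a high-coverage locus); doublet barcodes take the union of two
    latent cells' fragments.  Returns the fragment table, truth labels and
    whitelist; when ``outdir`` is given, also writes fragments.tsv,
    barcodes.txt and truth.tsv there.
    """
    if config.mode != "fragments":
        raise ValueError("simulate_fragments requires mode='fragments'")
    rng = np.random.default_rng(config.seed)
    n_doub = int(round(config.n_cells * config.doublet_prop))
    n_sing = config.n_cells - n_doub
    n_latent = n_sing + 2 * n_doub
    # evenly spaced loci with a gap of at least locus_width between them
    spacing = config.genome_length // config.n_loci
    locus_starts = np.arange(config.n_loci) * spacing + spacing // 4

    def _cell_fragments(cell_rng: np.random.Generator) -> list[tuple[int, int]]:
        frags: list[tuple[int, int]] = []
        counts = cell_rng.poisson(config.frag_rate, size=config.n_loci)
        for locus_start, k in zip(locus_starts, counts):
            for _ in range(int(k)):
                start = locus_start + int(cell_rng.integers(0, config.locus_width // 2))
                length = int(cell_rng.integers(100, config.locus_width))
                frags.append((start, start + length))
        return frags

    latent = [_cell_fragments(rng) for _ in range(n_latent)]
    rows: list[tuple[str, int, int, str, int]] = []
    barcodes: list[str] = []
    labels: list[str] = []
    for i in range(n_sing):
        bc = f"SG{i:06d}"
        barcodes.append(bc)
        labels.append("singlet")
        for s, e in latent[i]:
            rows.append((config.chrom, s, e, bc, 1))
    for i in range(n_doub):
        bc = f"DB{i:06d}"
        barcodes.append(bc)
        labels.append("doublet")
        a, b = latent[n_sing + 2 * i], latent[n_sing + 2 * i + 1]
        for s, e in a + b:
            rows.append((config.chrom, s, e, bc, 1))
    frag_df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "barcode", "count"]
    ).sort_values(["chrom", "start", "end"], kind="stable", ignore_index=True)
    truth = pd.DataFrame({"barcode": barcodes, "label": labels})
    result: dict[str, object] = {
        "fragments": frag_df,
        "truth": truth,
        "barcodes": barcodes,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frag_df.to_csv(
            outdir / "fragments.tsv", sep="\t", index=False, header=False
        )
        (outdir / "barcodes.txt").write_text("\n".join(barcodes) + "\n")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        result["paths"] = {
            "fragments": outdir / "fragments.tsv",
            "barcodes": outdir / "barcodes.txt",
            "truth": outdir / "truth.tsv",
        }
    return result


def hclc_table_from_sim(sim: pd.DataFrame) -> HclcTable:
    """Wrap a simulated HCLC frame as an :class:`HclcTable`."""
    return HclcTable(pd.Series(sim["hclc"].values, index=sim["barcode"].values))


def optimal_f1(scores: np.ndarray, truth: np.ndarray) -> float:
    """Best F1 over all thresholds of a score vector (1 = doublet)."""
    precision, recall, _ = precision_recall_curve(truth, scores)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = 2 * precision * recall / (precision + recall)
    return float(np.nanmax(f1))


def evaluate(
    pred: pd.DataFrame,
    truth: pd.DataFrame,
    pi0_tilde: float | None = None,
) -> dict[str, float | None]:
    """Classification metrics of a posterior/call table against truth labels.

    ``pred`` needs barcode and posterior columns, optionally call; ``truth``
    needs barcode and label ('singlet'/'doublet').  Returns F1 at the
    active call rule, optimal F1 over posterior thresholds, AUROC, AUPRC,
    the realized FDR among called cells, and (when ``pi0_tilde`` is given)
    estimated vs true multiplet proportions.  With single-class truth the
    ranking metrics are undefined and reported as None.
    """
    merged = pred.merge(truth, on="barcode", how="inner", validate="1:1")
    if len(merged) != len(pred) or len(merged) != len(truth):
        raise ValueError("pred and truth barcodes do not align")
    y = (merged["label"].values == "doublet").astype(int)
    scores = merged["posterior"].values.astype(float)
    metrics: dict[str, float | None] = {
        "n_cells": float(len(merged)),
        "true_multiplet_prop": float(y.mean()),
    }
    if 0 < y.sum() < len(y):
        metrics["auroc"] = float(roc_auc_score(y, scores))
        metrics["auprc"] = float(average_precision_score(y, scores))
        metrics["optimal_f1"] = optimal_f1(scores, y)
    else:
        metrics["auroc"] = metrics["auprc"] = metrics["optimal_f1"] = None
    if "call" in merged.columns:
        called = merged["call"].values.astype(bool)
        tp = int((called & (y == 1)).sum())
        fp = int((called & (y == 0)).sum())
        fn = int((~called & (y == 1)).sum())
        metrics["n_called"] = float(called.sum())
        metrics["f1_at_call"] = (
            2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else None
        )
        metrics["realized_fdr"] = fp / (tp + fp) if (tp + fp) > 0 else None
    if pi0_tilde is not None:
        metrics["estimated_multiplet_prop"] = 1.0 - pi0_tilde
    return metrics
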