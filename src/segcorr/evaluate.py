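"""Detection metrics: gene- and region-level TPR/FPR and ROC AUC.

Gene level: a gene is predicted positive at level alpha when it lies in a
region whose adjusted p-value is <= alpha; rates are computed over per-gene
H0/H1 labels.  Region level is stricter — it scores boundary accuracy: each
gene gets a status in {TP, FP, TN, FN} from its predicted vs true label,
maximal runs of equal status are merged into regions, and the rates are
computed over those status regions.  The ROC is traced by a grid of alpha
values, augmented with (0,0) and (1,1), and integrated by trapezoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SimulationSpec, SimulationTruth, simulate

__all__ = [
    "EvaluationResult",
    "default_alpha_grid",
    "gene_adjusted_pvalues",
    "evaluate_gene_level",
    "evaluate_region_level",
    "run_benchmark",
]


@dataclass(frozen=True)
class EvaluationResult:
    level: str
    alphas: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def default_alpha_grid(num: int = 50) -> np.ndarray:
    return np.logspace(-8, 0, num)


def gene_adjusted_pvalues(region_table: pd.DataFrame, truth: SimulationTruth) -> np.ndarray:
    """Per-gene adjusted p-value of the containing region, aligned to truth order."""
    t = truth.table
    out = np.full(len(t), np.nan)
    offsets = {}
    for chrom, sub in t.groupby("chromosome", sort=False):
        offsets[str(chrom)] = sub.index[0]
    for _, row in region_table.iterrows():
        off = offsets[str(row["chromosome"])]
        a = off + int(row["first_gene_index"]) - 1
        b = off + int(row["last_gene_index"])
        out[a:b] = row["adjusted_pvalue"]
    if np.isnan(out).any():
        raise ValueError("region table does not cover all genes of the truth")
    return out


def _roc_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    f = np.concatenate([[0.0], fpr, [1.0]])
    t = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((t, f))
    return float(np.trapezoid(t[order], f[order]))


def evaluate_gene_level(
    truth: SimulationTruth, region_table: pd.DataFrame, alphas=None
) -> EvaluationResult:
    if alphas is None:
        alphas = default_alpha_grid()
    alphas = np.asarray(alphas, dtype=float)
    labels = truth.labels.astype(bool)
    pvals = gene_adjusted_pvalues(region_table, truth)
    pos = labels.sum()
    neg = (~labels).sum()
    pred = pvals[None, :] <= alphas[:, None]
    tp = (pred & labels).sum(axis=1)
    fp = (pred & ~labels).sum(axis=1)
    tpr = tp / pos if pos else np.full(len(alphas), np.nan)
    fpr = fp / neg if neg else np.full(len(alphas), np.nan)
    return EvaluationResult("gene", alphas, tpr, fpr, _roc_auc(fpr, tpr))


def _region_rates(true_labels: np.ndarray, pred_labels: np.ndarray):
    """Merge per-gene statuses into runs and count status regions."""
    status = np.where(
        true_labels,
        np.where(pred_labels, 0, 3),   # TP / FN
        np.where(pred_labels, 1, 2),   # FP / TN
    )
    change = np.nonzero(np.diff(status) != 0)[0] + 1
    run_status = status[np.concatenate([[0], change])]
    counts = np.bincount(run_status, minlength=4)
    tp, fp, tn, fn = counts
    tpr = tp / (tp + fn) if (tp + fn) else np.nan
    fpr = fp / (fp + tn) if (fp + tn) else np.nan
    return tpr, fpr


def evaluate_region_level(
    truth: SimulationTruth, region_table: pd.DataFrame, alphas=None
) -> EvaluationResult:
    if alphas is None:
        alphas = default_alpha_grid()
    alphas = np.asarray(alphas, dtype=float)
    labels = truth.labels.astype(bool)
    pvals = gene_adjusted_pvalues(region_table, truth)
    # chromosome boundaries must break runs: evaluate per chromosome and pool counts
    chrom = truth.table["chromosome"].to_numpy()
    tprs, fprs = [], []
    for alpha in alphas:
        pred = pvals <= alpha
        tp = fp = tn = fn = 0
        for c in pd.unique(chrom):
            mask = chrom == c
            status = np.where(
                labels[mask],
                np.where(pred[mask], 0, 3),
                np.where(pred[mask], 1, 2),
            )
            change = np.nonzero(np.diff(status) != 0)[0] + 1
            run_status = status[np.concatenate([[0], change])]
            counts = np.bincount(run_status, minlength=4)
            tp += counts[0]
            fp += counts[1]
            tn += counts[2]
            fn += counts[3]
        tprs.append(tp / (tp + fn) if (tp + fn) else np.nan)
        fprs.append(fp / (fp + tn) if (fp + tn) else np.nan)
    tpr, fpr = np.asarray(tprs), np.asarray(fprs)
    auc = np.nan if np.isnan(tpr).all() else _roc_auc(fpr, tpr)
    return EvaluationResult("region", alphas, tpr, fpr, auc)


def run_benchmark(
    specs,
    replicates: int,
    seed: int,
    alphas=None,
    S: float = 0.7,
    K_max: int | None = None,
) -> pd.DataFrame:
    """End-to-end benchmark: simulate -> segment -> test -> evaluate.

    ``specs`` is a SimulationSpec or a mapping name -> SimulationSpec; each
    replicate draws a fresh dataset from an independent child seed of
    ``seed``.  Returns one row per (config, replicate) with gene- and
    region-level AUC.
    """
    from .pipeline import analyze_expression  # deferred: pipeline imports io only

    if isinstance(specs, SimulationSpec):
        specs = {"config": specs}
    if alphas is None:
        alphas = default_alpha_grid()
    rows = []
    for name, spec in specs.items():
        streams = np.random.SeedSequence(seed).spawn(replicates)
        for r, ss in enumerate(streams):
            rng = np.random.default_rng(ss)
            expr, truth = simulate(spec, rng=rng)
            table, _ = analyze_expression(expr, S=S, K_max=K_max)
            gene = evaluate_gene_level(truth, table, alphas)
            region = evaluate_region_level(truth, table, alphas)
            rows.append(
                {
                    "config": name,
                    "replicate": r,
                    "auc_gene": gene.auc,
                    "auc_region": region.auc,
                }
            )
    return pd.DataFrame(rows)
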