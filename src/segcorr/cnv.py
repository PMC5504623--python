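"""Correction of expression for copy-number variation before segmentation.

CNV shared by patients induces expression correlation between neighbouring
genes that has a known cause; to look for other mechanisms (e.g. epigenetic
silencing) it is removed first.  The procedure:

1. segment each patient's SNP-array signal into piecewise-constant
   copy-number levels (least-squares change-point model, exact DP, number
   of segments chosen by the same slope heuristic as the correlation
   segmentation);
2. map the fitted segment means onto genes, averaging when several probes
   fall inside a gene and interpolating linearly (at the gene midpoint)
   when none does;
3. regress log-scale expression on this per-patient, per-gene covariate
   (single intercept and slope by default) and keep the residuals, which
   are re-standardized and fed to the segmentation module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    drop_degenerate_genes,
    log_transform,
    standardize,
)
from .segmentation import DEFAULT_S, default_K_max, dp_partition, select_K

__all__ = [
    "SnpProfile",
    "CnvSegmentation",
    "CnvCovariate",
    "CorrectionFit",
    "read_snp",
    "segment_snp_profile",
    "map_probes_to_genes",
    "correct_expression",
    "corrected_pipeline",
]


@dataclass(frozen=True)
class SnpProfile:
    """One patient's SNP signal along one chromosome (positions increasing)."""

    patient_id: object
    positions: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions)
        if len(pos) != len(self.signal):
            raise ValueError("positions and signal lengths differ")
        if len(pos) > 1 and not (np.diff(pos) > 0).all():
            raise ValueError("probe positions must be strictly increasing")


@dataclass(frozen=True)
class CnvSegmentation:
    """Piecewise-constant fit of one SNP profile."""

    patient_id: object
    breakpoints: np.ndarray   # tau_0=0 < ... < tau_K = m (probe indices)
    means: np.ndarray
    sigma2: float

    @property
    def K(self) -> int:
        return len(self.means)

    def fitted(self) -> np.ndarray:
        """Fitted value at each probe."""
        return np.repeat(self.means, np.diff(self.breakpoints))


@dataclass(frozen=True)
class CnvCovariate:
    """Per-patient, per-gene copy-number level x_ij, gene order matching
    the expression matrix it corrects."""

    x: np.ndarray
    provenance: np.ndarray  # per gene: 'averaged' or 'interpolated'


@dataclass(frozen=True)
class CorrectionFit:
    beta0: np.ndarray
    beta1: np.ndarray
    residuals: np.ndarray


def read_snp(path) -> pd.DataFrame:
    """SNP TSV: probe_id, chrom, pos, then one signal column per patient."""
    df = pd.read_csv(path, sep="\t")
    required = ("probe_id", "chrom", "pos")
    if tuple(df.columns[:3]) != required:
        raise ValueError(f"SNP file must start with columns {required}")
    return df


def _rss_cost_matrix(signal: np.ndarray) -> np.ndarray:
    """cost[a, b] = residual sum of squares of a constant fit on a..b (0-based)."""
    m = len(signal)
    s1 = np.concatenate([[0.0], np.cumsum(signal)])
    s2 = np.concatenate([[0.0], np.cumsum(signal**2)])
    a, b = np.triu_indices(m)
    length = (b - a + 1).astype(float)
    seg_sum = s1[b + 1] - s1[a]
    seg_sq = s2[b + 1] - s2[a]
    cost = np.full((m, m), np.inf)
    cost[a, b] = seg_sq - seg_sum**2 / length
    return cost


def segment_snp_profile(
    profile: SnpProfile,
    K_max: int | None = None,
    S: float = DEFAULT_S,
    K: int | None = None,
) -> CnvSegmentation:
    """Least-squares change-point segmentation of one SNP profile.

    The DP is exact for each number of segments; unless ``K`` is forced,
    the number of segments is selected by the slope heuristic applied to
    the Gaussian least-squares log-likelihood.
    """
    signal = np.asarray(profile.signal, dtype=float)
    m = len(signal)
    if m < 2:
        raise ValueError("need at least two probes to segment a profile")
    if K_max is None:
        K_max = default_K_max(m) if K is None else K
    if K_max > m:
        raise ValueError(f"K_max={K_max} exceeds the probe count {m}")
    cost = _rss_cost_matrix(signal)
    rss, boundary_lists = dp_partition(cost, K_max)
    if K is not None:
        K_hat = K
    elif K_max < 3:
        K_hat = 1
    else:
        # profile Gaussian log-likelihood: -(m/2) log(RSS/m) up to constants
        loglik = -0.5 * m * np.log(np.maximum(rss, 1e-300) / m)
        K_hat = select_K(loglik, m, S=S).selected_K
    bounds = boundary_lists[K_hat - 1]
    means = np.array(
        [signal[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    )
    return CnvSegmentation(
        patient_id=profile.patient_id,
        breakpoints=bounds,
        means=means,
        sigma2=float(rss[K_hat - 1] / m),
    )


def map_probes_to_genes(
    cnvsegs: list[CnvSegmentation],
    probe_positions: np.ndarray,
    gene_starts: np.ndarray,
    gene_ends: np.ndarray,
) -> CnvCovariate:
    """Build the per-gene covariate from fitted per-probe copy-number levels.

    A gene overlapping >= 1 probe gets the mean of their fitted values; a
    gene with no probe gets the linear interpolation, at its midpoint,
    between the fitted values of the flanking probes (clamped to the
    nearest probe's value beyond the outermost probe).
    """
    probe_positions = np.asarray(probe_positions, dtype=float)
    if len(probe_positions) == 0:
        raise ValueError("chromosome has no SNP probes; cannot build covariate")
    gene_starts = np.asarray(gene_starts, dtype=float)
    gene_ends = np.asarray(gene_ends, dtype=float)
    p = len(gene_starts)
    n = len(cnvsegs)
    # probes inside gene j under the half-open BED convention
    first = np.searchsorted(probe_positions, gene_starts, side="left")
    last = np.searchsorted(probe_positions, gene_ends, side="left")
    has_probe = last > first
    midpoints = 0.5 * (gene_starts + gene_ends)
    x = np.empty((n, p))
    for i, seg in enumerate(cnvsegs):
        fitted = seg.fitted()
        if len(fitted) != len(probe_positions):
            raise ValueError("segmentation does not match the probe positions")
        interp = np.interp(midpoints, probe_positions, fitted)
        x[i] = interp
        for j in np.nonzero(has_probe)[0]:
            x[i, j] = fitted[first[j] : last[j]].mean()
    provenance = np.where(has_probe, "averaged", "interpolated")
    return CnvCovariate(x=x, provenance=provenance)


def _ols_1d(y: np.ndarray, x: np.ndarray):
    vx = x.var()
    if vx == 0:
        return float(y.mean()), 0.0
    b1 = float(np.cov(x, y, bias=True)[0, 1] / vx)
    b0 = float(y.mean() - b1 * x.mean())
    return b0, b1


def correct_expression(
    y_chrom: ExpressionMatrix,
    covariate: CnvCovariate,
    mode: str = "global",
    zero_policy: str = "keep",
) -> tuple[ExpressionMatrix, CorrectionFit]:
    """Regress expression on the CNV covariate; return the residual signal.

    ``mode='global'`` fits a single intercept and slope over all (patient,
    gene) pairs of the chromosome; ``mode='per-gene'`` fits one line per
    gene column.  ``zero_policy='drop-zero'`` excludes Y == 0 observations
    from the fit and sets their residuals to 0.
    """
    if y_chrom.standardized:
        raise ValueError("correction expects the log-scale, unstandardized signal")
    y = y_chrom.values
    x = covariate.x
    if x.shape != y.shape:
        raise ValueError("covariate shape does not match the expression matrix")
    if mode not in ("global", "per-gene"):
        raise ValueError(f"unknown mode {mode!r}")
    if zero_policy not in ("keep", "drop-zero"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")

    fit_mask = np.ones_like(y, dtype=bool) if zero_policy == "keep" else (y != 0)
    resid = np.zeros_like(y)
    if mode == "global":
        ym, xm = y[fit_mask], x[fit_mask]
        if xm.var() == 0:
            warnings.warn("CNV covariate has zero variance; slope set to 0")
        b0, b1 = _ols_1d(ym, xm)
        resid[fit_mask] = (y - b0 - b1 * x)[fit_mask]
        fit = CorrectionFit(np.array([b0]), np.array([b1]), resid)
    else:
        b0s, b1s = np.empty(y.shape[1]), np.empty(y.shape[1])
        for j in range(y.shape[1]):
            mask = fit_mask[:, j]
            if not mask.any():
                b0s[j], b1s[j] = 0.0, 0.0
                continue
            b0s[j], b1s[j] = _ols_1d(y[mask, j], x[mask, j])
            resid[mask, j] = y[mask, j] - b0s[j] - b1s[j] * x[mask, j]
        fit = CorrectionFit(b0s, b1s, resid)
    corrected = replace(y_chrom, values=resid, standardized=False)
    return corrected, fit


def corrected_pipeline(
    expr_raw: ExpressionMatrix,
    snp: pd.DataFrame,
    mode: str = "global",
    zero_policy: str = "keep",
    S: float = DEFAULT_S,
    snp_K_max: int | None = None,
    log: bool = True,
) -> ExpressionMatrix:
    """Full CNV correction: log -> drop degenerate -> segment SNP -> map ->
    regress -> re-standardized residuals ready for segmentation.

    ``expr_raw`` must carry genomic coordinates (start/end) so probes can be
    assigned to genes; ``snp`` is the frame from :func:`read_snp` with
    patient columns matching the expression sample ids.
    """
    if expr_raw.start is None:
        raise ValueError("expression matrix lacks genomic coordinates")
    expr = log_transform(expr_raw) if log else expr_raw
    expr = drop_degenerate_genes(expr)
    patients = list(expr.sample_ids)
    missing = [s for s in patients if s not in snp.columns]
    if missing:
        raise ValueError(f"SNP data missing patients: {missing[:5]}")

    corrected_chunks = []
    for chrom in expr.chromosomes:
        sub = expr.chromosome_view(chrom)
        probes = snp[snp["chrom"].astype(str) == str(chrom)].sort_values("pos")
        if probes.empty:
            raise ValueError(f"no SNP probes on chromosome {chrom}")
        positions = probes["pos"].to_numpy(dtype=float)
        segs = [
            segment_snp_profile(
                SnpProfile(s, positions, probes[s].to_numpy(dtype=float)),
                K_max=snp_K_max,
                S=S,
            )
            for s in patients
        ]
        cov = map_probes_to_genes(segs, positions, sub.start, sub.end)
        corrected, _ = correct_expression(sub, cov, mode=mode, zero_policy=zero_policy)
        corrected_chunks.append(corrected)

    values = np.concatenate([c.values for c in corrected_chunks], axis=1)
    merged = replace(
        expr,
        values=values,
        gene_ids=np.concatenate([c.gene_ids for c in corrected_chunks]),
        chromosome=np.concatenate([c.chromosome for c in corrected_chunks]),
        start=np.concatenate([c.start for c in corrected_chunks]),
        end=np.concatenate([c.end for c in corrected_chunks]),
        standardized=False,
        gene_order_index=None,
    )
    merged = drop_degenerate_genes(merged)
    return standardize(merged)
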