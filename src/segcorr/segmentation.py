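"""Block-diagonal segmentation of the gene-gene correlation matrix.

The model: patient expression profiles are i.i.d. centred Gaussian vectors
whose correlation matrix is block diagonal, each block compound-symmetric
(unit diagonal, common off-diagonal value ``rho_k``).  For fixed region
boundaries the within-region correlation MLE and the maximised likelihood
have closed forms in terms of the empirical Gram matrix
``G_hat = Y.T @ Y / n``:

    rho_hat  = (sum over the block of G_hat - p_k) / (p_k**2 - p_k)
    -2 L_hat = n * [p_k + (p_k - 1) log(1 - rho_hat)
                        + log(1 + (p_k - 1) rho_hat)]

Since the total -2 log-likelihood is additive over regions, the optimal
boundaries for every number of regions K are found exactly by dynamic
programming in O(K p^2), with each block Gram sum obtained in O(n) from
per-patient prefix sums.  The number of regions is then selected by a slope
heuristic on the penalised likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "GramAccumulator",
    "Segmentation",
    "ModelSelectionTrace",
    "block_rho_mle",
    "block_neg2_loglik",
    "segment_dp",
    "select_K",
    "segment_chromosome",
    "dp_partition",
    "slope_change_candidates",
    "default_K_max",
]

RHO_CLAMP_EPS = 1e-8
DEFAULT_S = 0.7


def _as_standardized_array(block, atol: float = 1e-6) -> np.ndarray:
    """Accept an ExpressionMatrix or ndarray; insist on standardized columns.

    ``atol`` loosens the numeric check for callers that work with
    model-standardized draws (population unit variance), whose empirical
    column moments deviate by O(1/sqrt(n)).
    """
    if isinstance(block, ExpressionMatrix):
        if not block.standardized:
            raise ValueError("block must be standardized (call standardize first)")
        return block.values
    y = np.asarray(block, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    if not (
        np.allclose(y.mean(axis=0), 0.0, atol=atol)
        and np.allclose((y**2).sum(axis=0) / n, 1.0, atol=atol)
    ):
        raise ValueError("block columns are not standardized under the 1/n convention")
    return y


class GramAccumulator:
    """Per-patient prefix sums giving any block's Gram-matrix sum in O(n).

    With ``C_i(j) = sum_{j' <= j} Y_ij'`` (and ``C_i(0) = 0``), the sum of
    ``G_hat`` over the square block of genes ``a..b`` (1-based inclusive) is
    ``n**-1 * sum_i (C_i(b) - C_i(a-1))**2``.
    """

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        self.n, self.p = y.shape
        self._prefix = np.concatenate(
            [np.zeros((self.n, 1)), np.cumsum(y, axis=1)], axis=1
        )

    def block_gram_sum(self, a: int, b: int) -> float:
        """Sum of G_hat over genes a..b, both 1-based inclusive."""
        d = self._prefix[:, b] - self._prefix[:, a - 1]
        return float(d @ d) / self.n

    def gram_sum_matrix(self) -> np.ndarray:
        """Upper-triangular matrix M with M[a-1, b-1] = block_gram_sum(a, b)."""
        m = np.zeros((self.p, self.p))
        for a in range(1, self.p + 1):
            d = self._prefix[:, a:] - self._prefix[:, a - 1 : a]
            m[a - 1, a - 1 :] = np.einsum("ij,ij->j", d, d) / self.n
        return m


@dataclass(frozen=True)
class Segmentation:
    """A partition of p ordered genes into K contiguous regions.

    ``boundaries`` is ``tau_0=0 < tau_1 < ... < tau_K = p``; region k covers
    genes ``tau_{k-1}+1 .. tau_k`` (1-based inclusive).
    """

    boundaries: np.ndarray
    rho: np.ndarray
    neg2_loglik_per_region: np.ndarray

    @property
    def K(self) -> int:
        return len(self.boundaries) - 1

    @property
    def p(self) -> int:
        return int(self.boundaries[-1])

    @property
    def p_k(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @property
    def neg2_loglik(self) -> float:
        return float(self.neg2_loglik_per_region.sum())

    @property
    def loglik(self) -> float:
        return -0.5 * self.neg2_loglik

    def regions(self):
        """Yield (first, last) 1-based inclusive gene indices per region."""
        for k in range(self.K):
            yield int(self.boundaries[k]) + 1, int(self.boundaries[k + 1])


@dataclass(frozen=True)
class ModelSelectionTrace:
    K_max: int
    loglik: np.ndarray          # L_K, K = 1..K_max
    normalized: np.ndarray      # L_tilde_K
    penalty: np.ndarray         # K_tilde_j, j = 1..K_max
    threshold: float
    candidates: np.ndarray
    selected_K: int


def _clamp_rho(rho, p_k):
    """Keep both log arguments strictly positive."""
    lo = np.where(p_k >= 2, -1.0 / np.maximum(p_k - 1, 1) + RHO_CLAMP_EPS, 0.0)
    return np.clip(rho, lo, 1.0 - RHO_CLAMP_EPS)


def block_rho_mle(block, clamp: bool = True) -> float:
    """Correlation MLE of one compound-symmetric block of standardized columns.

    A single-gene block returns 0 by convention (no off-diagonal terms).
    """
    y = _as_standardized_array(block)
    n, p_k = y.shape
    if p_k == 1:
        return 0.0
    s = y.sum(axis=1)
    gram_sum = float(s @ s) / n
    rho = (gram_sum - p_k) / (p_k**2 - p_k)
    if clamp:
        rho = float(_clamp_rho(rho, p_k))
    return float(rho)


def block_neg2_loglik(block) -> float:
    """Maximised -2 log-likelihood of one block (closed form at the MLE)."""
    y = _as_standardized_array(block)
    n, p_k = y.shape
    rho = block_rho_mle(y)
    return float(n * (p_k + (p_k - 1) * np.log1p(-rho) + np.log1p((p_k - 1) * rho)))


def _cost_matrix(y: np.ndarray) -> np.ndarray:
    """cost[a-1, b-1] = -2 L_hat of the block of genes a..b (upper triangle)."""
    n, p = y.shape
    m = GramAccumulator(y).gram_sum_matrix()
    a_idx, b_idx = np.triu_indices(p)
    p_k = (b_idx - a_idx + 1).astype(float)
    gram = m[a_idx, b_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(p_k >= 2, (gram - p_k) / (p_k**2 - p_k), 0.0)
    rho = _clamp_rho(rho, p_k)
    cost_vals = n * (p_k + (p_k - 1) * np.log1p(-rho) + np.log1p((p_k - 1) * rho))
    cost = np.full((p, p), np.inf)
    cost[a_idx, b_idx] = cost_vals
    return cost


def dp_partition(cost: np.ndarray, K_max: int):
    """Minimise additive segment costs over partitions into K = 1..K_max parts.

    ``cost[a, b]`` (0-based, inclusive) is the cost of one segment covering
    items a..b.  Returns ``(opt, boundary_lists)`` where ``opt[K-1]`` is the
    optimal total cost and ``boundary_lists[K-1]`` the 1-based boundaries
    ``[0, tau_1, ..., p]``.  Ties prefer the smallest last change-point,
    applied recursively (argmin takes the first minimiser).
    """
    p = cost.shape[0]
    if not 1 <= K_max <= p:
        raise ValueError(f"K_max must be in [1, {p}], got {K_max}")
    dp = np.full((K_max, p), np.inf)
    back = np.zeros((K_max, p), dtype=int)
    dp[0] = cost[0]
    for k in range(1, K_max):
        for b in range(k, p):
            # last segment starts at a in [k, b] (0-based)
            cand = dp[k - 1, k - 1 : b] + cost[k : b + 1, b]
            j = int(np.argmin(cand))
            dp[k, b] = cand[j]
            back[k, b] = k + j  # start index of the last segment
    opt = dp[:, p - 1].copy()
    boundary_lists = []
    for k in range(K_max):
        bounds = [p]
        b = p - 1
        for kk in range(k, 0, -1):
            a = back[kk, b]
            bounds.append(a)
            b = a - 1
        bounds.append(0)
        boundary_lists.append(np.array(bounds[::-1]))
    return opt, boundary_lists


def _segmentation_from_boundaries(y: np.ndarray, boundaries: np.ndarray) -> Segmentation:
    n = y.shape[0]
    rhos, costs = [], []
    for a, b in zip(boundaries[:-1] + 1, boundaries[1:]):
        block = y[:, a - 1 : b]
        p_k = b - a + 1
        if p_k == 1:
            rhos.append(0.0)
            costs.append(float(n))
            continue
        s = block.sum(axis=1)
        rho = ((s @ s) / n - p_k) / (p_k**2 - p_k)
        rho = float(_clamp_rho(rho, p_k))
        rhos.append(rho)
        costs.append(float(n * (p_k + (p_k - 1) * np.log1p(-rho) + np.log1p((p_k - 1) * rho))))
    return Segmentation(np.asarray(boundaries), np.asarray(rhos), np.asarray(costs))


def segment_dp(y_chrom, K_max: int) -> list[Segmentation]:
    """Exact optimal segmentations of one chromosome for every K = 1..K_max."""
    y = _as_standardized_array(y_chrom)
    p = y.shape[1]
    if K_max > p:
        raise ValueError(f"K_max={K_max} exceeds the number of genes p={p}")
    cost = _cost_matrix(y)
    _, boundary_lists = dp_partition(cost, K_max)
    return [_segmentation_from_boundaries(y, b) for b in boundary_lists]


def penalty(j, p) -> np.ndarray:
    """Slope-heuristic penalty 5 j + 2 j log(p / j) (natural log)."""
    j = np.asarray(j, dtype=float)
    return 5.0 * j + 2.0 * j * np.log(p / j)


def slope_change_candidates(normalized: np.ndarray, S: float) -> np.ndarray:
    """K values whose slope change of the normalized criterion exceeds S.

    The slope change at K is the centered second difference
    ``D_K = L~_{K-1} - 2 L~_K + L~_{K+1}`` (defined for 2 <= K <= K_max-1):
    a kink of the criterion at K — steep improvement up to K, little
    beyond — makes D_K large at K itself.
    """
    lt = np.asarray(normalized, dtype=float)
    d2 = lt[:-2] - 2.0 * lt[1:-1] + lt[2:]
    return np.nonzero(d2 > S)[0] + 2


def select_K(loglik, p: int, S: float = DEFAULT_S, rule: str = "largest") -> ModelSelectionTrace:
    """Choose the number of regions by the slope heuristic.

    ``loglik`` holds the maximal log-likelihood L_K for K = 1..K_max.  The
    normalized criterion is rescaled so that L~_{K_max} = 1 and
    L~_1 = K~_{K_max} - K~_1 + 1; K values where its centered slope change
    exceeds S are candidates.  ``rule='largest'`` (default) picks the
    largest candidate; ``rule='smallest'`` the arg-min reading.  An empty
    candidate set falls back to K_hat = 1.
    """
    L = np.asarray(loglik, dtype=float)
    K_max = len(L)
    if K_max < 3:
        raise ValueError("select_K needs K_max >= 3 to form second differences")
    if rule not in ("largest", "smallest"):
        raise ValueError(f"unknown rule {rule!r}")
    pen = penalty(np.arange(1, K_max + 1), p)
    span = L[-1] - L[0]
    if span <= 0:
        # block models are not nested across K, so the likelihood can be
        # flat or even decreasing; the slope heuristic has nothing to work
        # with and the conservative choice is a single region
        warnings.warn("flat or decreasing likelihood across K; selecting K=1")
        lt = np.ones(K_max)
        return ModelSelectionTrace(K_max, L, lt, pen, S, np.array([], dtype=int), 1)
    lt = (L[-1] - L) / span * (pen[-1] - pen[0]) + 1.0
    cand = slope_change_candidates(lt, S)
    if len(cand) == 0:
        K_hat = 1
    else:
        K_hat = int(cand.max() if rule == "largest" else cand.min())
    return ModelSelectionTrace(K_max, L, lt, pen, S, cand, K_hat)


def default_K_max(p: int) -> int:
    return max(1, min(p // 2, 40))


def segment_chromosome(
    y_chrom,
    K_max: int | None = None,
    S: float = DEFAULT_S,
    rule: str = "largest",
) -> Segmentation:
    """Segment one chromosome and return the segmentation at the selected K."""
    y = _as_standardized_array(y_chrom)
    p = y.shape[1]
    if K_max is None:
        K_max = default_K_max(p)
    if p == 1:
        return _segmentation_from_boundaries(y, np.array([0, 1]))
    segs = segment_dp(y, K_max)
    if K_max < 3:
        return segs[0]
    trace = select_K([s.loglik for s in segs], p, S=S, rule=rule)
    if trace.selected_K == K_max:
        warnings.warn(
            f"selected K equals K_max={K_max}; the grid may be too small "
            "(possible under-segmentation)"
        )
    return segs[trace.selected_K - 1]
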