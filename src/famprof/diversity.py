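"""Alpha diversity, rarefaction, Bray-Curtis, PCoA and one-way PERMANOVA.

All statistics are computed directly from the count matrix:

* Observed richness and the Shannon index H = -sum p_i ln p_i.
* Exact analytic rarefaction, E[S_n] = sum_i (1 - C(N - N_i, n)/C(N, n)),
  evaluated with log-gamma for numerical stability.
* Bray-Curtis dissimilarity on per-sample proportions, optionally
  square-root transformed first (the default, which damps the dominance
  of the most abundant taxon in a compositional matrix).
* Metric PCoA by Gower double-centering and eigendecomposition.
* One-way PERMANOVA with a seeded label-permutation null; sums of squares
  follow the classical distance-based decomposition
  SS_total = (1/n) sum_{i<j} d_ij^2,
  SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2.

Distance matrices are scikit-bio :class:`~skbio.stats.distance.DistanceMatrix`
objects throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from skbio.stats.distance import DistanceMatrix

from .tables import OtuTable, OtuTableError, relative_abundance


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def observed_richness(counts: Sequence[float] | np.ndarray) -> int:
    """Number of OTUs with a nonzero count."""
    counts = np.asarray(counts)
    return int(np.count_nonzero(counts > 0))


def shannon(counts: Sequence[float] | np.ndarray, base: float | None = None) -> float:
    """Shannon index over nonzero proportions; natural log by default."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise OtuTableError("shannon: sample has zero total count")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


@dataclass
class RarefactionCurve:
    depths: np.ndarray
    expected_richness: np.ndarray


def rarefaction_curve(
    counts: Sequence[float] | np.ndarray, depths: Sequence[int]
) -> RarefactionCurve:
    """Expected OTU richness in a without-replacement subsample of each depth.

    Uses the exact hypergeometric expectation; at depth == total it equals
    the observed richness, and it is non-decreasing in depth.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    depths = np.asarray(list(depths), dtype=np.int64)
    if np.any(depths < 1):
        raise OtuTableError("rarefaction depths must be >= 1")
    if np.any(depths > total):
        raise OtuTableError(
            f"rarefaction depth {int(depths.max())} exceeds sample total {total}"
        )

    def log_choose(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    expected = np.empty(depths.shape, dtype=float)
    for idx, n in enumerate(depths):
        rest = total - counts  # reads not belonging to each OTU
        ok = rest >= n         # else C(rest, n) = 0 and the OTU is certain
        absent_prob = np.zeros(counts.shape, dtype=float)
        absent_prob[ok] = np.exp(log_choose(rest[ok], int(n)) - log_choose(np.int64(total), int(n)))
        expected[idx] = float((1.0 - absent_prob).sum())
    return RarefactionCurve(depths=depths, expected_richness=expected)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: OtuTable, transform: str = "sqrt") -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples.

    Computed on per-sample proportions, square-root transformed when
    ``transform='sqrt'`` (default).  BC(j,k) = sum |x_j - x_k| / sum (x_j + x_k).
    """
    if table.n_samples < 2:
        raise OtuTableError("bray_curtis needs at least two samples")
    if transform not in ("none", "sqrt"):
        raise OtuTableError(f"unknown transform {transform!r}")
    x = relative_abundance(table).to_numpy()
    if transform == "sqrt":
        x = np.sqrt(x)
    # pairwise |x_j - x_k| sums via broadcasting; n_samples is small
    diff = np.abs(x[:, :, None] - x[:, None, :]).sum(axis=0)
    summ = (x[:, :, None] + x[:, None, :]).sum(axis=0)
    with np.errstate(invalid="ignore"):
        d = np.where(summ > 0, diff / summ, 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(d, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    coordinates: pd.DataFrame          # sample x axis, positive axes only
    eigenvalues: np.ndarray            # all eigenvalues, descending
    proportion_explained: np.ndarray   # per positive axis


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Classical metric scaling (principal coordinates analysis).

    Gower-centers -D^2/2, eigendecomposes, and embeds on the positive
    eigenvalues; negative eigenvalues are reported but excluded from the
    coordinates and the proportion-explained denominator.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise OtuTableError("pcoa needs at least three samples")
    a = -0.5 * d * d
    row_mean = a.mean(axis=1, keepdims=True)
    col_mean = a.mean(axis=0, keepdims=True)
    g = a - row_mean - col_mean + a.mean()
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    df_among: int
    df_resid: int
    ss_among: float
    ss_within: float
    ss_total: float
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None

    def summary(self) -> str:
        return (
            f"PERMANOVA: Df = {self.df_among}, R2 = {self.r_squared:.2f}, "
            f"pseudo-F = {self.pseudo_f:.3f}, "
            f"p = {self.p_value:.3g} ({self.n_permutations} permutations)"
        )


def _within_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """SS_within for each row of label codes (B x n) against squared distances."""
    out = np.zeros(codes.shape[0], dtype=float)
    for g in range(n_groups):
        mask = (codes == g).astype(float)      # B x n
        sizes = mask.sum(axis=1)
        quad = np.einsum("bi,ij,bj->b", mask, d2, mask)  # counts each pair twice
        out += quad / (2.0 * sizes)
    return out


def permanova(
    dm: DistanceMatrix,
    factor: Mapping[str, str] | pd.Series,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``factor`` maps every sample id to a group label.  The p-value is
    (#{F* >= F} + 1) / (n_permutations + 1) under random relabelling with
    fixed group sizes.  R^2 = SS_among / SS_total does not depend on the
    permutations.
    """
    ids = list(dm.ids)
    if isinstance(factor, pd.Series):
        factor = factor.to_dict()
    missing = [s for s in ids if s not in factor]
    if missing:
        raise OtuTableError(f"permanova: unlabelled samples {missing}")
    labels = [factor[s] for s in ids]
    level_names = sorted(set(labels))
    a = len(level_names)
    n = len(ids)
    if a < 2:
        raise OtuTableError("permanova: factor has one level")
    if a >= n:
        raise OtuTableError("permanova: no residual degrees of freedom")
    code_of = {lab: g for g, lab in enumerate(level_names)}
    codes = np.array([code_of[lab] for lab in labels], dtype=np.int64)

    d2 = np.asarray(dm.data, dtype=float) ** 2
    ss_total = float(d2.sum() / (2.0 * n))
    ss_within = float(_within_ss(d2, codes[np.newaxis, :], a)[0])
    ss_among = ss_total - ss_within
    df_among, df_resid = a - 1, n - a
    with np.errstate(divide="ignore"):
        pseudo_f = float(np.divide(ss_among / df_among, ss_within / df_resid))
    r_squared = ss_among / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    perm_codes = np.empty((n_permutations, n), dtype=np.int64)
    for b in range(n_permutations):
        perm_codes[b] = rng.permutation(codes)
    perm_within = _within_ss(d2, perm_codes, a)
    with np.errstate(divide="ignore", invalid="ignore"):
        perm_f = ((ss_total - perm_within) / df_among) / (perm_within / df_resid)
    exceed = int(np.count_nonzero(perm_f >= pseudo_f - 1e-12))
    p_value = (exceed + 1) / (n_permutations + 1)

    return PermanovaResult(
        df_among=df_among,
        df_resid=df_resid,
        ss_among=ss_among,
        ss_within=ss_within,
        ss_total=ss_total,
        pseudo_f=pseudo_f,
        r_squared=r_squared,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
    )
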