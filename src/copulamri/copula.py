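"""Empirical copula transform and discretization into the joint-distribution matrix.

The empirical copula transform maps each marginal to pseudo-observations
``rank/(n+1)`` in (0,1), discarding the marginal distributions and keeping
only the dependence structure between the two channels. Discretizing the
transformed pairs on an equal-width N x N grid over the unit square gives a
joint-distribution matrix: near-uniform under independence, concentrated on
the main diagonal under strong positive dependence, and on the anti-diagonal
under negative dependence. Because ranks are invariant under strictly
increasing transforms of either channel, so is the matrix — which also makes
the construction a scanner/sequence normalization in its own right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .imaging_io import VoxelPairSample

DEFAULT_BINS = 10


@dataclass
class CopulaSample:
    """Pseudo-observations (u, v) of one patient's paired voxel sample.

    ``u`` holds the transformed ADC ranks and ``v`` the transformed rCBV
    ranks; both lie strictly inside (0,1) because ranks are divided by n+1.
    Ties receive average ranks (midranks).
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape or self.u.ndim != 1:
            raise ValueError("u and v must be 1-D arrays of equal length")
        if np.any((self.u <= 0) | (self.u >= 1) | (self.v <= 0) | (self.v >= 1)):
            raise ValueError("pseudo-observations must lie strictly inside (0,1)")

    @property
    def n(self) -> int:
        return self.u.size


@dataclass
class JointDistributionMatrix:
    """N x N discretized copula density: probabilities ``p`` and raw ``counts``.

    Rows index ADC bins, columns index rCBV bins; row/column 0 is the lowest
    value bin. ``p = counts / n`` and sums to 1.
    """

    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if self.counts.shape[0] < 2:
            raise ValueError("need at least 2 bins")
        if int(self.counts.sum()) != self.n:
            raise ValueError("counts must sum to n")

    @property
    def bins(self) -> int:
        return self.counts.shape[0]

    @property
    def p(self) -> np.ndarray:
        return self.counts / self.n


def empirical_copula_transform(sample: VoxelPairSample) -> CopulaSample:
    """Rank-transform a paired voxel sample to pseudo-observations.

    u_k = rank(adc_k)/(n+1), v_k = rank(rcbv_k)/(n+1), with midranks for
    ties. With no ties, the sorted entries of each channel are exactly
    {k/(n+1): k=1..n}, so the marginals are uniform by construction.
    """
    n = sample.n_voxels
    if n < 2:
        raise ValueError("need at least 2 voxel pairs for the copula transform")
    u = rankdata(sample.adc, method="average") / (n + 1)
    v = rankdata(sample.rcbv, method="average") / (n + 1)
    return CopulaSample(u=u, v=v)


def discretize_joint(cs: CopulaSample, bins: int = DEFAULT_BINS) -> JointDistributionMatrix:
    """Bin pseudo-observations on an equal-width grid over [0,1]^2.

    Cell (i, j) counts pairs with u in bin i and v in bin j; bins are
    half-open [l, r) with the final bin closed (irrelevant here since
    pseudo-observations never touch 1).
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _, _ = np.histogram2d(cs.u, cs.v, bins=(edges, edges))
    return JointDistributionMatrix(counts=counts.astype(np.int64), n=cs.n)


def patient_matrix(sample: VoxelPairSample, bins: int = DEFAULT_BINS) -> JointDistributionMatrix:
    """Convenience composition: copula transform then discretization."""
    return discretize_joint(empirical_copula_transform(sample), bins=bins)
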