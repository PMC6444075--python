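"""Second-order (Haralick-style) features of a joint-distribution matrix.

Nine scalar summaries of an N x N probability matrix p(i,j), with indices
i, j running 1..N and marginals p_x(i) = sum_j p(i,j), p_y(j) = sum_i p(i,j):

====================  ========================================================
energy                sum p(i,j)^2                       (uniformity; in (0,1])
contrast              sum (i-j)^2 p(i,j)                 (off-diagonality)
entropy               -sum p log2 p, 0*log 0 == 0        (randomness, >= 0)
homogeneity           sum p/(1+|i-j|)                    (inverse difference)
correlation           (sum i*j*p - mu_x mu_y)/(sigma_x sigma_y)
sum_average           sum_{k=2}^{2N} k * p_{x+y}(k),  p_{x+y}(k)=sum_{i+j=k} p
variance              sum (i-mu_x)^2 p(i,j)
dissimilarity         sum |i-j| p(i,j)
autocorrelation       sum i*j*p(i,j)
====================  ========================================================

For the copula matrix, a near-uniform p (independent channels) has maximal
entropy and zero correlation; a diagonal p (comonotone channels) has zero
contrast/dissimilarity and correlation 1. ``variance`` is defined against the
row-marginal mean mu_x (the GLCM convention) and is therefore the one feature
that is *not* invariant under matrix transpose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .copula import JointDistributionMatrix

logger = logging.getLogger(__name__)

#: Canonical feature order, used for table columns.
FEATURE_NAMES = (
    "energy",
    "contrast",
    "entropy",
    "homogeneity",
    "correlation",
    "sum_average",
    "variance",
    "dissimilarity",
    "autocorrelation",
)

#: Homogeneity variants: inverse difference (default) or inverse difference moment.
HOMOGENEITY_VARIANTS = ("inverse_difference", "inverse_difference_moment")


@dataclass(frozen=True)
class FeatureVector:
    energy: float
    contrast: float
    entropy: float
    homogeneity: float
    correlation: float
    sum_average: float
    variance: float
    dissimilarity: float
    autocorrelation: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


assert tuple(f.name for f in dc_fields(FeatureVector)) == FEATURE_NAMES


def second_order_features(
    m: JointDistributionMatrix | np.ndarray,
    homogeneity_variant: str = "inverse_difference",
    entropy_base: float = 2.0,
) -> FeatureVector:
    """Compute the nine second-order statistics of a normalized matrix.

    Accepts either a :class:`JointDistributionMatrix` or a bare probability
    matrix. If the marginal standard deviations vanish (all mass in one
    row/column), correlation is undefined and returned as 0 with a warning.
    """
    if homogeneity_variant not in HOMOGENEITY_VARIANTS:
        raise ValueError(f"unknown homogeneity_variant {homogeneity_variant!r}")
    p = m.p if isinstance(m, JointDistributionMatrix) else np.asarray(m, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("probability matrix must be square")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"matrix not normalized: sum = {total!r}")

    n = p.shape[0]
    idx = np.arange(1, n + 1, dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    sigma_x = float(np.sqrt(((idx - mu_x) ** 2) @ px))
    sigma_y = float(np.sqrt(((idx - mu_y) ** 2) @ py))

    energy = float(np.sum(p**2))
    contrast = float(np.sum((i - j) ** 2 * p))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log(nz) / np.log(entropy_base)))
    if homogeneity_variant == "inverse_difference":
        homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    else:
        homogeneity = float(np.sum(p / (1.0 + (i - j) ** 2)))
    autocorrelation = float(np.sum(i * j * p))
    if sigma_x * sigma_y > 0:
        correlation = (autocorrelation - mu_x * mu_y) / (sigma_x * sigma_y)
    else:
        logger.warning("degenerate marginals: correlation undefined, returning 0")
        correlation = 0.0
    # sum-distribution p_{x+y}(k), k = 2..2N
    ksum = (np.arange(n)[:, None] + np.arange(n)[None, :] + 2).ravel()
    p_xpy = np.bincount(ksum, weights=p.ravel(), minlength=2 * n + 1)
    sum_average = float(np.arange(2 * n + 1) @ p_xpy)
    variance = float(np.sum((i - mu_x) ** 2 * p))
    dissimilarity = float(np.sum(np.abs(i - j) * p))

    return FeatureVector(
        energy=energy,
        contrast=contrast,
        entropy=entropy,
        homogeneity=homogeneity,
        correlation=float(correlation),
        sum_average=sum_average,
        variance=variance,
        dissimilarity=dissimilarity,
        autocorrelation=autocorrelation,
    )


def cohort_feature_table(
    matrices: list[tuple[str, JointDistributionMatrix]],
    homogeneity_variant: str = "inverse_difference",
    entropy_base: float = 2.0,
) -> pd.DataFrame:
    """Build the patients x 9 feature table, indexed by patient_id in given order.

    All matrices must share the same bin count and patient ids must be unique.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 patients")
    bins = {m.bins for _, m in matrices}
    if len(bins) != 1:
        raise ValueError(f"mixed bin counts in cohort: {sorted(bins)}")
    ids = [pid for pid, _ in matrices]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient_id in cohort")
    rows = [
        second_order_features(m, homogeneity_variant, entropy_base).as_array()
        for _, m in matrices
    ]
    return pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"), columns=list(FEATURE_NAMES))
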