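"""Weighted delete-one-block jackknife.

Genomic blocks carry unequal SNP counts, so the package uses the weighted
jackknife throughout: with total count n, block counts m_j and h_j = n/m_j,
pseudovalues are

    tau_j = h_j * theta_hat - (h_j - 1) * theta_(-j)

the bias-corrected estimate is the weighted combination
theta_J = B*theta_hat - sum_j (1 - m_j/n) theta_(-j), and the variance is
(1/B) * sum_j (tau_j - theta_J)^2 / (h_j - 1). The same pseudovalue form
gives the covariance matrix when theta is a vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class JackknifeResult:
    estimate: np.ndarray  # full-data estimate (scalar -> shape ())
    mean: np.ndarray  # bias-corrected jackknife mean
    se: np.ndarray  # standard error(s)
    covariance: np.ndarray | None  # for vector-valued estimates
    loo: np.ndarray  # leave-one-block-out estimates, shape (B, ...)
    weights: np.ndarray  # block counts m_j


def weighted_jackknife(
    estimate: np.ndarray,
    loo: np.ndarray,
    weights: np.ndarray,
    covariance: bool = False,
) -> JackknifeResult:
    """Weighted delete-one jackknife from precomputed leave-one-out estimates.

    Parameters
    ----------
    estimate
        Full-data estimate, scalar or vector of length d.
    loo
        Leave-one-block-out estimates, shape (B,) or (B, d).
    weights
        Per-block counts m_j (positive); blocks with zero weight are dropped.
    covariance
        Also return the d x d jackknife covariance matrix.
    """
    estimate = np.asarray(estimate, dtype=float)
    loo = np.asarray(loo, dtype=float)
    weights = np.asarray(weights, dtype=float)
    keep = weights > 0
    loo = loo[keep]
    weights = weights[keep]
    B = loo.shape[0]
    if B < 2:
        raise ValueError("weighted jackknife needs at least 2 non-empty blocks")
    n = weights.sum()
    h = n / weights  # shape (B,)
    hs = h.reshape((B,) + (1,) * (loo.ndim - 1))
    theta_j = B * estimate - ((1.0 - weights.reshape(hs.shape) / n) * loo).sum(axis=0)
    tau = hs * estimate - (hs - 1.0) * loo
    dev = tau - theta_j
    var = (dev**2 / (hs - 1.0)).sum(axis=0) / B
    cov = None
    if covariance:
        d = dev.reshape(B, -1)
        cov = (d[:, :, None] * d[:, None, :] / (h - 1.0)[:, None, None]).sum(axis=0) / B
    return JackknifeResult(
        estimate=estimate,
        mean=theta_j,
        se=np.sqrt(np.maximum(var, 0.0)),
        covariance=cov,
        loo=loo,
        weights=weights,
    )


def ratio_loo(sums: np.ndarray, counts: np.ndarray) -> tuple[float, np.ndarray]:
    """Full and leave-one-out estimates of sum(sums)/sum(counts) per block.

    ``sums``/``counts`` are per-block totals of a per-SNP statistic and the
    SNPs contributing to it. Blocks where the remaining count would be zero
    get the full-data estimate (they carry zero jackknife weight anyway).
    """
    S, N = sums.sum(), counts.sum()
    if N <= 0:
        raise ValueError("no SNPs retained for statistic")
    est = S / N
    rem = N - counts
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = np.where(rem > 0, (S - sums) / np.maximum(rem, 1e-300), est)
    return est, loo
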