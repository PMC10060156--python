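"""Admixture-weight estimation from f4 statistics (qpAdm-style).

A target population T is modelled as a mixture of k source ("left")
populations S_1..S_k relative to m right/reference populations R_0..R_{m-1}.
With R_0 as base, the statistics

    y_j   = f4(T,   R_0; R_j, R_0)          j = 1..m-1
    A_kj  = f4(S_k, R_0; R_j, R_0)

satisfy y = A' w when T is a mixture with weights w, because allele
frequencies mix linearly. The weights are estimated by generalized least
squares under the constraint sum(w) = 1 (closed-form Lagrange solve), with
the residual covariance Q estimated by the weighted block jackknife of the
residual vector and refined by iterated reweighting. The model-fit p-value
is the chi-square upper tail of the minimized Mahalanobis form with
(m-1) - (k-1) degrees of freedom; weight SEs and covariance come from
re-solving on every leave-one-block replicate.

The module also implements the source-cycling procedure (every non-empty
subset of candidate sources is fit with the complementary candidates moved
to the right) and a mixed-source grid: a pseudo-source with per-SNP
frequency pi * p_Persian + (1-pi) * p_Indian is scanned over pi, scoring
each fit with a Hotelling T-squared tail using the number of jackknife
blocks as the effective sample size.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fstats import _label, f4_vector
from .genotype_io import BlockAssignment, GenotypeDataset, assign_blocks, group_freqs
from .jackknife import weighted_jackknife

MIN_X_BLOCKS = 10


@dataclass
class AdmixtureModelFit:
    target: str
    sources: tuple
    rights: tuple[str, ...]
    weights: np.ndarray
    weight_se: np.ndarray
    weight_cov: np.ndarray
    fit_p: float
    chisq: float
    dof: int
    feasible: bool
    chromosome_set: str
    n_snps: int
    n_blocks: int
    warnings: list[str] = field(default_factory=list)

    @property
    def source_labels(self) -> tuple[str, ...]:
        return tuple(s if isinstance(s, str) else "<mixed>" for s in self.sources)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": self.source_labels,
                "weight": self.weights,
                "se": self.weight_se,
            }
        )


@dataclass
class CyclingTable:
    target: str
    candidates: tuple[str, ...]
    fits: pd.DataFrame  # one row per (subset, augmented rights)
    best: tuple[str, ...] | None  # minimal feasible fitting subset


def _constrained_gls(A: np.ndarray, y: np.ndarray, Qinv: np.ndarray) -> np.ndarray:
    """argmin_w (y - A'w)' Qinv (y - A'w) subject to sum(w) = 1."""
    k = A.shape[0]
    if k == 1:
        return np.array([1.0])
    M = A @ Qinv @ A.T
    b = A @ Qinv @ y
    ones = np.ones(k)
    try:
        Mi_b = np.linalg.solve(M, b)
        Mi_1 = np.linalg.solve(M, ones)
    except np.linalg.LinAlgError:
        Mp = np.linalg.pinv(M)
        Mi_b, Mi_1 = Mp @ b, Mp @ ones
    lam = (1.0 - ones @ Mi_b) / (ones @ Mi_1)
    return Mi_b + lam * Mi_1


def _safe_inverse(Q: np.ndarray, warnings: list[str]) -> np.ndarray:
    """Invert a jackknife covariance, ridge-regularizing if near-singular."""
    q = Q.shape[0]
    cond = np.linalg.cond(Q)
    if not np.isfinite(cond) or cond > 1e12:
        ridge = 1e-9 * np.trace(Q) / q + 1e-300
        warnings.append(f"residual covariance near-singular; ridge {ridge:.3e} added")
        Q = Q + ridge * np.eye(q)
    return np.linalg.inv(Q)


def qpadm_fit(
    ds: GenotypeDataset,
    target,
    sources,
    rights,
    blocks: BlockAssignment | None = None,
    chromosome_set: str = "autosomes",
    span_cM: float = 5.0,
    min_copies: int = 1,
    n_iter: int = 3,
) -> AdmixtureModelFit:
    """Fit mixture weights of ``target`` from ``sources`` given ``rights``.

    ``target`` and ``sources`` entries may be group labels or
    ``(freq, copies)`` pseudo-populations (e.g. a single individual or a
    frequency-mixed source). Requires at least |sources|+1 rights and >= 2
    jackknife blocks (>= 10 on X, where blocks are scarce).
    """
    sources = list(sources)
    rights = list(rights)
    k = len(sources)
    m = len(rights)
    if k < 1:
        raise ValueError("need at least one source")
    if m < k + 1:
        raise ValueError(f"need at least {k + 1} rights for {k} sources, got {m}")
    dof = (m - 1) - (k - 1)
    if dof <= 0:
        raise ValueError("model not testable: dof <= 0")
    if blocks is None:
        blocks = assign_blocks(ds, span_cM, chromosome_set)
    if blocks.chromosome_set == "X" and blocks.n_blocks < MIN_X_BLOCKS:
        raise ValueError(
            f"only {blocks.n_blocks} X-chromosome blocks; need >= {MIN_X_BLOCKS}"
        )

    base = rights[0]
    quads = [(target, base, rj, base) for rj in rights[1:]]
    for src in sources:
        quads.extend((src, base, rj, base) for rj in rights[1:])
    vec = f4_vector(ds, quads, blocks, min_copies=min_copies)
    mm = m - 1
    y = vec.estimate[:mm]
    A = vec.estimate[mm:].reshape(k, mm)
    y_loo = vec.loo[:, :mm]  # (B, mm)
    A_loo = vec.loo[:, mm:].reshape(-1, k, mm)  # (B, k, mm)
    weights_b = vec.block_counts

    warn: list[str] = []
    w = np.full(k, 1.0 / k)
    Qinv = None
    for _ in range(max(n_iter, 1)):
        e = y - w @ A
        e_loo = y_loo - np.einsum("k,bkm->bm", w, A_loo)
        jk = weighted_jackknife(e, e_loo, weights_b, covariance=True)
        Qinv = _safe_inverse(jk.covariance, warn)
        w = _constrained_gls(A, y, Qinv)
    e = y - w @ A
    chisq = float(e @ Qinv @ e)
    fit_p = float(stats.chi2.sf(chisq, dof))

    # weight uncertainty: re-solve on each leave-one-block replicate
    B = y_loo.shape[0]
    w_loo = np.empty((B, k))
    for b in range(B):
        w_loo[b] = _constrained_gls(A_loo[b], y_loo[b], Qinv)
    wjk = weighted_jackknife(w, w_loo, weights_b, covariance=True)

    feasible = bool(((w >= -1e-9) & (w <= 1 + 1e-9)).all())
    return AdmixtureModelFit(
        target=_label(target),
        sources=tuple(s if isinstance(s, str) else s for s in sources),
        rights=tuple(rights),
        weights=w,
        weight_se=np.atleast_1d(wjk.se),
        weight_cov=wjk.covariance,
        fit_p=fit_p,
        chisq=chisq,
        dof=dof,
        feasible=feasible,
        chromosome_set=blocks.chromosome_set,
        n_snps=vec.n_snps,
        n_blocks=vec.n_blocks,
        warnings=warn,
    )


def qpadm_cycle(
    ds: GenotypeDataset,
    target: str,
    candidates,
    base_rights,
    blocks: BlockAssignment | None = None,
    fit_threshold: float = 0.05,
    subset_cap: int = 1024,
    **fit_kwargs,
) -> CyclingTable:
    """Source cycling: fit every non-empty candidate subset, moving the
    complementary candidates to the right set.

    The returned table is sorted by (subset size, fit p descending); ``best``
    is the smallest feasible subset whose fit p-value clears the threshold.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("cycling needs at least 2 candidate sources")
    n_subsets = 2 ** len(candidates) - 1
    if n_subsets > subset_cap:
        raise ValueError(
            f"{n_subsets} candidate subsets exceed the cap ({subset_cap}); "
            "reduce the candidate list or raise subset_cap"
        )
    if blocks is None:
        blocks = assign_blocks(ds, fit_kwargs.get("span_cM", 5.0), "autosomes")
    rows = []
    fits: dict[tuple[str, ...], AdmixtureModelFit] = {}
    for r in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            rights = list(base_rights) + [c for c in candidates if c not in subset]
            fit = qpadm_fit(ds, target, list(subset), rights, blocks, **fit_kwargs)
            fits[subset] = fit
            rows.append(
                {
                    "sources": ",".join(subset),
                    "n_sources": r,
                    "weights": ",".join(f"{w:.4f}" for w in fit.weights),
                    "ses": ",".join(f"{s:.4f}" for s in fit.weight_se),
                    "fit_p": fit.fit_p,
                    "feasible": fit.feasible,
                    "fitting": fit.feasible and fit.fit_p >= fit_threshold,
                }
            )
    table = (
        pd.DataFrame(rows)
        .sort_values(["n_sources", "fit_p"], ascending=[True, False])
        .reset_index(drop=True)
    )
    best = None
    ok = table[table.fitting]
    if len(ok):
        best = tuple(ok.iloc[0].sources.split(","))
    return CyclingTable(target=target, candidates=tuple(candidates), fits=table, best=best)


def hotelling_pvalue(chisq: float, q: int, n_blocks: int) -> float:
    """Hotelling T^2 tail: T^2 * (B-q)/(q(B-1)) against F(q, B-q)."""
    B = n_blocks
    if B <= q:
        raise ValueError("need more jackknife blocks than residual dimensions")
    f_stat = chisq * (B - q) / (q * (B - 1))
    return float(stats.f.sf(f_stat, q, B - q))


def mixed_source_grid(
    ds: GenotypeDataset,
    target: str,
    african_source: str,
    persian_source: str,
    indian_source: str,
    rights,
    pi_grid,
    blocks: BlockAssignment | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Scan the Persian share pi of a frequency-mixed Persian–Indian source.

    For each pi the pseudo-source has per-SNP frequency
    pi * p_Persian + (1-pi) * p_Indian with conservative effective copy
    counts min(n_Persian, n_Indian); the two-source model
    (African + mixed) is fit and scored with a Hotelling T^2 p-value.
    """
    pi_grid = np.atleast_1d(np.asarray(pi_grid, dtype=float))
    if ((pi_grid < 0) | (pi_grid > 1)).any():
        raise ValueError("pi values must lie in [0, 1]")
    if blocks is None:
        blocks = assign_blocks(ds, fit_kwargs.get("span_cM", 5.0), "autosomes")
    pP, nP = group_freqs(ds, persian_source)
    pI, nI = group_freqs(ds, indian_source)
    n_mix = np.minimum(nP, nI)
    rows = []
    for pi in pi_grid:
        p_mix = pi * pP + (1.0 - pi) * pI
        fit = qpadm_fit(
            ds, target, [african_source, (p_mix, n_mix)], rights, blocks, **fit_kwargs
        )
        rows.append(
            {
                "pi": float(pi),
                "T2": fit.chisq,
                "p": hotelling_pvalue(fit.chisq, fit.dof, fit.n_blocks),
                "w_african": fit.weights[0],
                "w_mixed": fit.weights[1],
                "n_blocks": fit.n_blocks,
            }
        )
    return pd.DataFrame(rows)
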