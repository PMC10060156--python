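"""f2 and f4 statistics with weighted block-jackknife errors.

f2(A, B) measures drift separating two populations:

    f2 = E[(pA - pB)^2] - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)

with the finite-sample bias correction in allele-copy counts n. f4(A, B; C, D)
measures correlated drift between the two population pairs:

    f4 = E[(pA - pB)(pC - pD)]

and needs no bias correction when the four groups share no individuals.
Estimates average the per-SNP quantity within contiguous genetic blocks
(default 5 cM) and standard errors / covariance matrices come from the
weighted delete-one-block jackknife, with block weights proportional to the
number of retained SNPs.

A SNP enters a statistic only when every population of that statistic has at
least one called allele copy (two for f2, whose correction divides by n-1).
This per-statistic completeness policy is configurable via the
``min_copies`` argument.

Populations may be given as group labels of the dataset or directly as
``(freq_array, copy_count_array)`` pairs; the latter lets callers build
synthetic pseudo-populations (e.g. a frequency-mixed source).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_io import BlockAssignment, GenotypeDataset, group_freqs
from .jackknife import JackknifeResult, ratio_loo, weighted_jackknife


@dataclass
class FStatBlocks:
    """A vector of f-statistics with per-block sums and jackknife results."""

    labels: list[str]
    block_sums: np.ndarray  # (n_stats, B)
    block_counts: np.ndarray  # (B,) retained SNPs per block (common policy)
    estimate: np.ndarray  # (n_stats,)
    se: np.ndarray  # (n_stats,)
    loo: np.ndarray  # (B, n_stats)
    covariance: np.ndarray | None
    n_snps: int
    n_blocks: int

    @property
    def z(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.estimate / self.se

    def scalar(self) -> tuple[float, float]:
        return float(self.estimate[0]), float(self.se[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "statistic": self.labels,
                "estimate": self.estimate,
                "se": self.se,
                "z": self.z,
                "n_snps": self.n_snps,
                "n_blocks": self.n_blocks,
            }
        )


def _resolve(ds: GenotypeDataset, pop) -> tuple[np.ndarray, np.ndarray, frozenset]:
    """Return (freq, copies, individual-index set) for a population spec."""
    if isinstance(pop, str):
        p, n = group_freqs(ds, pop)
        return p, n, frozenset(ds.group_indices(pop).tolist())
    p, n = pop
    return np.asarray(p, float), np.asarray(n, float), frozenset()


def _label(pop) -> str:
    return pop if isinstance(pop, str) else "<freqs>"


def _check_disjoint(sets: Sequence[frozenset], labels: Sequence[str]) -> None:
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if sets[i] & sets[j]:
                raise ValueError(
                    f"populations {labels[i]!r} and {labels[j]!r} share individuals; "
                    "overlapping groups bias f-statistics and are refused"
                )


def _jackknife_stats(
    per_snp: np.ndarray,
    retained: np.ndarray,
    blocks: BlockAssignment,
    labels: list[str],
    covariance: bool,
) -> FStatBlocks:
    """Block-aggregate per-SNP statistic rows and jackknife them jointly."""
    use = retained & (blocks.block_id >= 0)
    n_used = int(use.sum())
    if n_used == 0:
        raise ValueError("no SNPs retained for statistic")
    ids = blocks.block_id[use]
    counts = np.bincount(ids, minlength=blocks.n_blocks).astype(float)
    nonzero = np.flatnonzero(counts > 0)
    if nonzero.size < 2:
        raise ValueError("fewer than 2 non-empty jackknife blocks")
    sums = np.stack(
        [np.bincount(ids, weights=row[use], minlength=blocks.n_blocks) for row in per_snp]
    )
    ests, loos = [], []
    for row in sums:
        est, loo = ratio_loo(row[nonzero], counts[nonzero])
        ests.append(est)
        loos.append(loo)
    estimate = np.array(ests)
    loo = np.stack(loos, axis=1)  # (B, n_stats)
    jk: JackknifeResult = weighted_jackknife(estimate, loo, counts[nonzero], covariance=covariance)
    return FStatBlocks(
        labels=labels,
        block_sums=sums[:, nonzero],
        block_counts=counts[nonzero],
        estimate=estimate,
        se=np.atleast_1d(jk.se),
        loo=jk.loo,
        covariance=jk.covariance,
        n_snps=n_used,
        n_blocks=int(nonzero.size),
    )


def f2_stat(
    ds: GenotypeDataset,
    popA,
    popB,
    blocks: BlockAssignment,
    min_copies: int = 2,
) -> FStatBlocks:
    """Unbiased f2 between two populations."""
    pA, nA, sA = _resolve(ds, popA)
    pB, nB, sB = _resolve(ds, popB)
    la, lb = _label(popA), _label(popB)
    if sA and sB and la != lb:
        _check_disjoint([sA, sB], [la, lb])
    retained = (nA >= max(min_copies, 2)) & (nB >= max(min_copies, 2))
    if isinstance(popA, str) and isinstance(popB, str) and la == lb:
        # a group compared with itself: no two-panel sampling, f2 is 0
        stat = np.zeros(ds.n_snps)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = (
                (pA - pB) ** 2
                - pA * (1 - pA) / np.maximum(nA - 1, 1)
                - pB * (1 - pB) / np.maximum(nB - 1, 1)
            )
    stat = np.where(retained, stat, 0.0)
    return _jackknife_stats(
        stat[None, :], retained, blocks, [f"f2({la},{lb})"], covariance=False
    )


def f4_stat(
    ds: GenotypeDataset,
    popA,
    popB,
    popC,
    popD,
    blocks: BlockAssignment,
    min_copies: int = 1,
) -> FStatBlocks:
    """f4(A, B; C, D) with sign convention (pA - pB)(pC - pD)."""
    res = f4_vector(ds, [(popA, popB, popC, popD)], blocks, min_copies=min_copies)
    return res


def f4_vector(
    ds: GenotypeDataset,
    quadruples: Sequence[tuple],
    blocks: BlockAssignment,
    min_copies: int = 1,
) -> FStatBlocks:
    """A vector of f4 statistics on a common retained-SNP set, with covariance.

    All populations appearing in any quadruple must have >= ``min_copies``
    called copies at a SNP for it to be retained, so every statistic of the
    vector (and its jackknife covariance) uses exactly the same SNPs.
    """
    cache: dict = {}

    def resolve(pop):
        key = pop if isinstance(pop, str) else id(pop)
        if key not in cache:
            cache[key] = _resolve(ds, pop)
        return cache[key]

    labels: list[str] = []
    rows: list[np.ndarray] = []
    retained = np.ones(ds.n_snps, dtype=bool)
    # distinct labelled groups across the whole vector must be disjoint
    seen: dict[str, frozenset] = {}
    for quad in quadruples:
        if len(quad) != 4:
            raise ValueError("each f4 statistic needs exactly 4 populations")
        for pop in quad:
            if isinstance(pop, str) and pop not in seen:
                seen[pop] = resolve(pop)[2]
    names = list(seen)
    _check_disjoint([seen[n] for n in names], names)

    for quad in quadruples:
        (pA, nA, _), (pB, nB, _), (pC, nC, _), (pD, nD, _) = (resolve(p) for p in quad)
        labs = [_label(p) for p in quad]
        labels.append(f"f4({labs[0]},{labs[1]};{labs[2]},{labs[3]})")
        retained &= (nA >= min_copies) & (nB >= min_copies)
        retained &= (nC >= min_copies) & (nD >= min_copies)
        rows.append((pA - pB) * (pC - pD))
    per_snp = np.nan_to_num(np.stack(rows), nan=0.0)
    return _jackknife_stats(per_snp, retained, blocks, labels, covariance=True)
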