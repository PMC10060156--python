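"""Sex-biased admixture from the X-vs-autosome ancestry contrast.

Autosomes spend equal time in males and females, the X spends two thirds of
its history in females. If a source contributed a fraction f of the
female-side ancestors and m of the male-side ancestors, its ancestry
coefficients are C_A = (m + f)/2 on the autosomes and C_X = (2f + m)/3 on
X. Inverting the system gives the closed-form point estimator

    f = 3*C_X - 2*C_A        m = 4*C_A - 3*C_X        (f + m = 2*C_A)

normalized to shares f_hat = f/(f+m), m_hat = m/(f+m). Shares falling
outside [0, 1] are truncated to the boundary (and flagged), mirroring how
such estimates are reported when the admixture history is strongly
single-sex.

Uncertainty comes from a Monte-Carlo procedure: coefficient vectors are
drawn from multivariate normals centred on the jackknife means with the
jackknife error covariances (autosomes and X independently), covariances
are repaired to positive semidefinite by adding |lambda_min| to the
diagonal when needed, draws with any negative coefficient are discarded,
and per-draw normalized shares yield means, SDs and central 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qpadm import AdmixtureModelFit


@dataclass
class AncestryEstimate:
    """Per-source ancestry coefficients for one chromosome set."""

    sources: tuple[str, ...]
    coefficients: np.ndarray
    covariance: np.ndarray
    chromosome_set: str

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        k = len(self.sources)
        if self.coefficients.shape != (k,):
            raise ValueError("coefficients must be one per source")
        if self.covariance.shape != (k, k):
            raise ValueError("covariance must be square, one row per source")

    @classmethod
    def from_fit(cls, fit: AdmixtureModelFit) -> "AncestryEstimate":
        return cls(
            sources=fit.source_labels,
            coefficients=fit.weights,
            covariance=fit.weight_cov,
            chromosome_set=fit.chromosome_set,
        )

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))


@dataclass
class SexBiasResult:
    sources: tuple[str, ...]
    table: pd.DataFrame  # per source: f_mean, f_sd, f_lo, f_hi, m_*, truncated
    n_requested: int
    n_accepted: int
    psd_repair: dict[str, float] = field(default_factory=dict)

    def female_interval(self, source: str) -> tuple[float, float]:
        row = self.table.set_index("source").loc[source]
        return float(row.f_lo), float(row.f_hi)


def point_sex_fractions(c_auto: float, c_x: float) -> tuple[float, float, bool]:
    """Closed-form (f_hat, m_hat, truncated) from one source's C_A and C_X."""
    if c_auto <= 0:
        raise ValueError("C_A must be positive (f + m = 2*C_A)")
    f = 3.0 * c_x - 2.0 * c_auto
    m = 4.0 * c_auto - 3.0 * c_x
    f_hat = f / (f + m)  # f + m = 2*C_A > 0
    truncated = not 0.0 <= f_hat <= 1.0
    f_hat = float(np.clip(f_hat, 0.0, 1.0))
    return f_hat, 1.0 - f_hat, truncated


def _repair_psd(cov: np.ndarray) -> tuple[np.ndarray, float]:
    lam_min = float(np.linalg.eigvalsh(cov).min())
    if lam_min < 0:
        return cov + abs(lam_min) * np.eye(cov.shape[0]), abs(lam_min)
    return cov, 0.0


def mc_sex_fractions(
    auto: AncestryEstimate,
    x: AncestryEstimate,
    n_draws: int = 1_000_000,
    seed: int | np.random.Generator = 0,
    min_acceptance: float = 1e-3,
) -> SexBiasResult:
    """Monte-Carlo female/male shares per source from autosome and X fits."""
    if auto.sources != x.sources:
        raise ValueError("autosome and X estimates must share source labels")
    if n_draws < 10_000:
        raise ValueError("n_draws must be >= 10^4 for stable intervals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov_a, off_a = _repair_psd(auto.covariance)
    cov_x, off_x = _repair_psd(x.covariance)
    draws_a = rng.multivariate_normal(auto.coefficients, cov_a, size=n_draws, method="eigh")
    draws_x = rng.multivariate_normal(x.coefficients, cov_x, size=n_draws, method="eigh")
    ok = (draws_a >= 0).all(axis=1) & (draws_x >= 0).all(axis=1)
    n_acc = int(ok.sum())
    if n_acc < min_acceptance * n_draws:
        raise ValueError(
            f"only {n_acc}/{n_draws} draws feasible; review the coefficient "
            "estimates and covariances before interpreting sex bias"
        )
    ca, cx = draws_a[ok], draws_x[ok]
    f = 3.0 * cx - 2.0 * ca
    m = 4.0 * ca - 3.0 * cx
    tot = f + m  # = 2*ca > 0 on accepted draws... unless ca == 0
    tot = np.where(tot == 0, np.nan, tot)
    f_hat = f / tot
    rows = []
    for j, src in enumerate(auto.sources):
        fj = f_hat[:, j]
        fj = fj[np.isfinite(fj)]
        lo, hi = np.percentile(fj, [2.5, 97.5])
        truncated = lo < 0 or hi > 1
        lo, hi = float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))
        rows.append(
            {
                "source": src,
                "f_mean": float(fj.mean()),
                "f_sd": float(fj.std()),
                "f_lo": lo,
                "f_hi": hi,
                "m_mean": float(1.0 - fj.mean()),
                "m_sd": float(fj.std()),
                "m_lo": 1.0 - hi,
                "m_hi": 1.0 - lo,
                "truncated": truncated,
            }
        )
    return SexBiasResult(
        sources=auto.sources,
        table=pd.DataFrame(rows),
        n_requested=n_draws,
        n_accepted=n_acc,
        psd_repair={"autosomes": off_a, "X": off_x},
    )


def xa_z_score(auto: AncestryEstimate, x: AncestryEstimate) -> np.ndarray:
    """Per-source Z = (C_A - C_X)/sqrt(SE_A^2 + SE_X^2).

    Negative when the X estimate exceeds the autosomal one, i.e. for a
    female-biased source.
    """
    if auto.sources != x.sources:
        raise ValueError("autosome and X estimates must share source labels")
    denom = np.sqrt(auto.se**2 + x.se**2)
    if (denom == 0).any():
        raise ValueError("zero combined standard error")
    return (auto.coefficients - x.coefficients) / denom
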