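"""Simplex cline regression for three-way ancestry compositions.

Individuals admixed between two proximal source populations lie on a line
segment inside the 2-simplex of their (African-like, Persian, Indian)
ancestry proportions. Fitting that line to high-coverage individuals and
extrapolating it to the simplex edges characterizes the two proximal
sources: the a_P = 0 intersection (African–Indian edge) describes the
African-side source, the a_M = 0 intersection (Persian–Indian edge) the
already-mixed Asian source.

The fit is a total-least-squares principal axis through the centroid in
composition space — symmetric in the three coordinates and free of any
ternary-plot drawing convention. Edge intersections are computed in
barycentric coordinates; uncertainties come from a leave-one-individual-out
jackknife of the endpoint components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

COMPONENTS = ("african", "persian", "indian")
HIGH_COVERAGE_SNPS = 100_000


@dataclass(frozen=True)
class Composition:
    ind_id: str
    proportions: tuple[float, float, float]  # (a_M/african, a_persian, a_indian)
    n_snps: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (3,):
            raise ValueError("compositions are three-way (african, persian, indian)")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"{self.ind_id}: proportions must sum to 1, got {p.sum()}")

    @property
    def high_coverage(self) -> bool:
        return self.n_snps > HIGH_COVERAGE_SNPS

    @property
    def feasible(self) -> bool:
        return all(p >= 0 for p in self.proportions)


@dataclass
class ClineFit:
    centroid: np.ndarray
    direction: np.ndarray  # unit vector, components sum to 0
    endpoint_african: np.ndarray | None  # a_P = 0 edge
    endpoint_asian: np.ndarray | None  # a_M = 0 edge
    n_used: int
    n_excluded_infeasible: int
    clamped: dict[str, bool] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    endpoint_se: pd.DataFrame | None = None

    def endpoints_frame(self) -> pd.DataFrame:
        rows = []
        for name, ep in (
            ("african_side", self.endpoint_african),
            ("asian_side", self.endpoint_asian),
        ):
            if ep is None:
                continue
            rows.append({"endpoint": name, **dict(zip(COMPONENTS, ep))})
        return pd.DataFrame(rows)


def filter_high_coverage(
    compositions: Sequence[Composition], threshold: int = HIGH_COVERAGE_SNPS
) -> list[Composition]:
    """Keep individuals with more than ``threshold`` covered SNPs."""
    kept = [c for c in compositions if c.n_snps > threshold]
    if len(kept) < 3:
        raise ValueError(
            f"only {len(kept)} individuals above {threshold} SNPs; "
            "need >= 3 to fit a cline"
        )
    return kept


def _edge_intersection(
    centroid: np.ndarray,
    direction: np.ndarray,
    zero_coord: int,
    clamped: dict[str, bool],
    warnings: list[str],
    name: str,
) -> np.ndarray | None:
    """Intersect the line with the simplex edge {x_zero_coord = 0, x >= 0}."""
    v = direction[zero_coord]
    if abs(v) < 1e-12:
        warnings.append(f"line parallel to the {name} edge; no intersection")
        return None
    t_star = -centroid[zero_coord] / v
    # feasible t-interval where every coordinate stays non-negative
    lo, hi = -np.inf, np.inf
    for j in range(3):
        if abs(direction[j]) < 1e-15:
            continue
        t0 = -centroid[j] / direction[j]
        if direction[j] > 0:
            lo = max(lo, t0)
        else:
            hi = min(hi, t0)
    t = float(np.clip(t_star, lo, hi))
    clamped[name] = bool(abs(t - t_star) > 1e-9)
    if not clamped[name]:
        t = t_star
    point = centroid + t * direction
    point = np.clip(point, 0.0, None)
    if not clamped[name]:
        point[zero_coord] = 0.0  # exact by construction
    point /= point.sum()
    return point


def fit_simplex_line(
    compositions: Sequence[Composition],
    jackknife: bool = True,
) -> ClineFit:
    """Total-least-squares line through compositions, extrapolated to edges.

    Points with any negative proportion (infeasible mixture estimates) are
    excluded and counted. Requires >= 3 usable, non-identical points.
    """
    usable = [c for c in compositions if c.feasible]
    n_excl = len(compositions) - len(usable)
    if len(usable) < 3:
        raise ValueError("need >= 3 feasible compositions to fit a line")
    X = np.array([c.proportions for c in usable], dtype=float)
    fit = _fit_points(X)
    fit.n_excluded_infeasible = n_excl
    if len({tuple(np.round(c.proportions, 12)) for c in usable}) <= 2:
        fit.warnings.append("fewer than 3 distinct points; jackknife SEs unstable")
    if jackknife and len(usable) >= 4:
        fit.endpoint_se = jackknife_cline(usable)
    return fit


def _fit_points(X: np.ndarray) -> ClineFit:
    centroid = X.mean(axis=0)
    centred = X - centroid
    if np.allclose(centred, 0.0):
        raise ValueError("all compositions identical; line undefined")
    # principal axis = top right-singular vector (total least squares)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    direction = direction - direction.mean()  # stay inside the simplex plane
    direction /= np.linalg.norm(direction)
    # orient from the Asian corner toward the African corner for stable signs
    if direction[0] < 0:
        direction = -direction
    clamped: dict[str, bool] = {}
    warnings: list[str] = []
    ep_af = _edge_intersection(centroid, direction, 1, clamped, warnings, "african_side")
    ep_as = _edge_intersection(centroid, direction, 0, clamped, warnings, "asian_side")
    return ClineFit(
        centroid=centroid,
        direction=direction,
        endpoint_african=ep_af,
        endpoint_asian=ep_as,
        n_used=len(X),
        n_excluded_infeasible=0,
        clamped=clamped,
        warnings=warnings,
    )


def jackknife_cline(compositions: Sequence[Composition]) -> pd.DataFrame:
    """Leave-one-individual-out SEs of each endpoint component."""
    usable = [c for c in compositions if c.feasible]
    n = len(usable)
    if n < 4:
        raise ValueError("jackknife needs >= 4 compositions")
    X = np.array([c.proportions for c in usable], dtype=float)
    reps_af, reps_as = [], []
    dropped = 0
    for i in range(n):
        sub = np.delete(X, i, axis=0)
        try:
            f = _fit_points(sub)
        except ValueError:
            dropped += 1
            continue
        if f.endpoint_african is not None:
            reps_af.append(f.endpoint_african)
        if f.endpoint_asian is not None:
            reps_as.append(f.endpoint_asian)
    rows = []
    for name, reps in (("african_side", reps_af), ("asian_side", reps_as)):
        if len(reps) < 2:
            continue
        R = np.array(reps)
        nn = len(R)
        se = np.sqrt((nn - 1) / nn * ((R - R.mean(axis=0)) ** 2).sum(axis=0))
        rows.append(
            {
                "endpoint": name,
                **{f"se_{c}": se[j] for j, c in enumerate(COMPONENTS)},
                "n_replicates": nn,
                "n_dropped": dropped,
            }
        )
    return pd.DataFrame(rows)
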