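"""Synthetic genotype data with known admixture truth.

The generator produces everything the inference chain consumes, with the
ground truth recorded alongside:

* Reference allele frequencies under the Balding–Nichols model: an ancestral
  frequency p ~ Uniform(0.05, 0.95) per SNP, and each population's frequency
  drawn Beta(p(1-F)/F, (1-p)(1-F)/F) with drift parameter F. Populations may
  share an intermediate "clade" ancestor (itself Balding–Nichols drifted from
  the ancestral frequency), which gives reference ("right") panels
  differential relatedness to the admixture sources — without this structure
  every source is equally related to every right population and mixture
  weights are unidentifiable.
* Admixed cohorts under a one-pulse tract model: per haploid genome,
  recombination breakpoints are Poisson with rate g per Morgan (g generations
  since admixture; rate (2/3)g on X, which recombines only in females) and
  each tract's source is drawn independently with the chromosome-set ancestry
  proportions. Sex-specific contributions f_k (female side) and m_k (male
  side) per source give autosomal proportions C_A = (m+f)/2 and X proportions
  C_X = (2f+m)/3. Ancestry covariance between positions at genetic distance d
  decays as exp(-g*d), which is what the dating stage measures.
* Genotypes sampled binomially from the tract-source frequency; optional
  pseudo-haploid representation (a single random allele per site) and
  missingness. Males carry a single X.

Default genetic map: 22 autosomes of 1.4 Morgans plus an X of 1.8 Morgans,
uniform recombination. All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genotype_io import (
    CHROM_X,
    MISSING,
    GenotypeDataset,
    IndRecord,
    SnpRecord,
    write_eigenstrat,
)

__all__ = [
    "SimPopSpec",
    "AdmixSpec",
    "GeneticMapSpec",
    "ReferenceFreqs",
    "SimTruth",
    "gen_reference_freqs",
    "sample_panel",
    "gen_admixed_cohort",
    "gen_dating_cohort",
    "combine",
    "scenario_catalogue",
    "build_scenario",
    "write_fixture_dataset",
]


@dataclass(frozen=True)
class SimPopSpec:
    """A drifted reference population."""

    name: str
    drift_F: float
    n_individuals: int = 0
    pseudo_haploid: bool = False
    clade: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.drift_F < 1.0:
            raise ValueError(f"drift_F must be in (0,1), got {self.drift_F}")
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")


@dataclass(frozen=True)
class AdmixSpec:
    """One-pulse admixed cohort with sex-specific source contributions.

    ``female_fractions[k]`` is the share of the female-side ancestors coming
    from source k (and likewise for males); each side is a composition
    summing to 1, which implies the spec-level constraint
    sum_k (f_k + m_k)/2 = 1.
    """

    source_names: tuple[str, ...]
    female_fractions: tuple[float, ...]
    male_fractions: tuple[float, ...]
    generations: int
    n_individuals: int
    name: str = "Admixed"
    pseudo_haploid: bool = False
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.female_fractions, float)
        m = np.asarray(self.male_fractions, float)
        if len(f) != len(self.source_names) or len(m) != len(self.source_names):
            raise ValueError("fraction vectors must match source_names")
        if (f < 0).any() or (m < 0).any():
            raise ValueError("sex-specific fractions must be non-negative")
        if abs((f + m).sum() / 2.0 - 1.0) > 1e-9:
            raise ValueError("sum_k (f_k + m_k)/2 must equal 1")
        if abs(f.sum() - 1.0) > 1e-9 or abs(m.sum() - 1.0) > 1e-9:
            raise ValueError(
                "female and male fractions must each sum to 1 "
                "(each side's ancestry is a composition)"
            )
        if self.generations < 1:
            raise ValueError("generations_since_admixture must be >= 1")

    @property
    def c_auto(self) -> np.ndarray:
        f = np.asarray(self.female_fractions, float)
        m = np.asarray(self.male_fractions, float)
        return (m + f) / 2.0

    @property
    def c_x(self) -> np.ndarray:
        f = np.asarray(self.female_fractions, float)
        m = np.asarray(self.male_fractions, float)
        return (2.0 * f + m) / 3.0


@dataclass(frozen=True)
class GeneticMapSpec:
    n_autosomes: int = 22
    autosome_length_M: float = 1.4
    x_length_M: float = 1.8
    include_x: bool = True

    def lengths(self) -> dict[str, float]:
        out = {str(c + 1): self.autosome_length_M for c in range(self.n_autosomes)}
        if self.include_x:
            out[CHROM_X] = self.x_length_M
        return out


@dataclass
class ReferenceFreqs:
    """Per-population allele-frequency table on a shared SNP map."""

    snps: list[SnpRecord]
    freqs: dict[str, np.ndarray]
    ancestral: np.ndarray
    map_spec: GeneticMapSpec
    specs: dict[str, SimPopSpec] = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def chrom_index(self) -> dict[str, np.ndarray]:
        chroms = np.array([s.chromosome for s in self.snps])
        return {c: np.flatnonzero(chroms == c) for c in dict.fromkeys(chroms)}

    def to_frame(self) -> pd.DataFrame:
        base = pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.snps],
                "chromosome": [s.chromosome for s in self.snps],
                "genetic_pos": [s.genetic_pos for s in self.snps],
            }
        )
        for name, f in self.freqs.items():
            base[name] = f
        return base


@dataclass
class SimTruth:
    """Tract-level local ancestry and realized proportions for a cohort."""

    source_names: tuple[str, ...]
    # (ind_id, chromosome, haplotype) -> array of (start_M, end_M, source_idx)
    tracts: dict[tuple[str, str, int], np.ndarray]
    realized: pd.DataFrame  # ind_id, chromosome_set, source, proportion
    params: dict = field(default_factory=dict)

    def realized_mean(self, chromosome_set: str = "autosomes") -> np.ndarray:
        sub = self.realized[self.realized.chromosome_set == chromosome_set]
        means = sub.groupby("source", sort=False)["proportion"].mean()
        return np.array([means.get(s, 0.0) for s in self.source_names])

    def ancestry_at(
        self, ind_id: str, chromosome: str, haplotype: int, positions: np.ndarray
    ) -> np.ndarray:
        """Source index of each genetic position (Morgans) on one haplotype."""
        tr = self.tracts[(ind_id, chromosome, haplotype)]
        idx = np.searchsorted(tr[:, 1], positions, side="right")
        idx = np.minimum(idx, len(tr) - 1)
        return tr[idx, 2].astype(int)


# -- SNP map and reference frequencies ------------------------------------


def _make_snp_map(n_snps: int, map_spec: GeneticMapSpec, rng: np.random.Generator) -> list[SnpRecord]:
    lengths = map_spec.lengths()
    total = sum(lengths.values())
    snps: list[SnpRecord] = []
    chrom_names = list(lengths)
    # proportional allocation, remainders to the longest chromosomes
    counts = {c: int(n_snps * L / total) for c, L in lengths.items()}
    short = n_snps - sum(counts.values())
    for c in sorted(chrom_names, key=lambda c: -lengths[c])[:short]:
        counts[c] += 1
    for chrom in chrom_names:
        k = counts[chrom]
        if k == 0:
            continue
        pos = np.sort(rng.uniform(0.0, lengths[chrom], size=k))
        for j, g in enumerate(pos):
            snps.append(
                SnpRecord(
                    snp_id=f"snp_{chrom}_{j}",
                    chromosome=chrom,
                    genetic_pos=float(g),
                    physical_pos=int(g * 1e8) + 1,
                )
            )
    return snps


def _balding_nichols(
    base: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    if not 0.0 < F < 1.0:
        raise ValueError(f"drift F must be in (0,1), got {F}")
    a = base * (1.0 - F) / F
    b = (1.0 - base) * (1.0 - F) / F
    return rng.beta(a, b)


def gen_reference_freqs(
    specs: Sequence[SimPopSpec],
    n_snps: int,
    map_spec: GeneticMapSpec | None = None,
    seed: int | np.random.Generator = 0,
    clade_F: float = 0.05,
) -> ReferenceFreqs:
    """Balding–Nichols reference frequencies on a fresh SNP map.

    Populations sharing a ``clade`` label drift from a common intermediate
    frequency (itself drifted from the ancestral one with ``clade_F``).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    map_spec = map_spec or GeneticMapSpec()
    snps = _make_snp_map(n_snps, map_spec, rng)
    ancestral = rng.uniform(0.05, 0.95, size=n_snps)
    clade_base: dict[str, np.ndarray] = {}
    for spec in specs:
        if spec.clade is not None and spec.clade not in clade_base:
            clade_base[spec.clade] = _balding_nichols(ancestral, clade_F, rng)
    freqs: dict[str, np.ndarray] = {}
    for spec in specs:
        base = clade_base[spec.clade] if spec.clade is not None else ancestral
        freqs[spec.name] = _balding_nichols(base, spec.drift_F, rng)
    return ReferenceFreqs(
        snps=snps,
        freqs=freqs,
        ancestral=ancestral,
        map_spec=map_spec,
        specs={s.name: s for s in specs},
    )


# -- genotype sampling -----------------------------------------------------


def _apply_missing(
    calls: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    if rate > 0:
        calls[rng.random(calls.shape) < rate] = MISSING
    return calls


def sample_panel(
    freqs: ReferenceFreqs,
    name: str,
    seed: int | np.random.Generator,
    n_individuals: int | None = None,
    pseudo_haploid: bool | None = None,
    missing_rate: float = 0.0,
) -> GenotypeDataset:
    """Sample a reference panel's genotypes from its allele frequencies."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = freqs.specs.get(name)
    n = n_individuals if n_individuals is not None else (spec.n_individuals if spec else 0)
    if n < 1:
        raise ValueError(f"panel {name!r} has no individuals to sample")
    ph = pseudo_haploid if pseudo_haploid is not None else bool(spec and spec.pseudo_haploid)
    f = freqs.freqs[name]
    on_x = np.array([s.chromosome == CHROM_X for s in freqs.snps])
    sexes = np.array(["F", "M"] * (n // 2 + 1))[:n]
    calls = np.empty((freqs.n_snps, n), dtype=np.int8)
    for i in range(n):
        hemi = on_x & (sexes[i] == "M")
        if ph:
            calls[:, i] = 2 * (rng.random(freqs.n_snps) < f)
        else:
            g = rng.binomial(2, f).astype(np.int8)
            if hemi.any():
                g[hemi] = 2 * (rng.random(hemi.sum()) < f[hemi])
            calls[:, i] = g
    calls = _apply_missing(calls, missing_rate, rng)
    inds = [IndRecord(f"{name}_{i}", sexes[i], name) for i in range(n)]
    return GenotypeDataset(
        snps=freqs.snps,
        inds=inds,
        calls=calls,
        pseudo_haploid=np.full(n, ph, dtype=bool),
    )


def _simulate_tracts(
    length_M: float, rate: float, probs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Tracts tiling [0, L]: Poisson(rate) breakpoints, iid source per tract."""
    n_break = rng.poisson(rate * length_M)
    breaks = np.sort(rng.uniform(0.0, length_M, size=n_break))
    edges = np.concatenate(([0.0], breaks, [length_M]))
    k = len(edges) - 1
    sources = rng.choice(len(probs), size=k, p=probs)
    return np.column_stack((edges[:-1], edges[1:], sources.astype(float)))


def gen_admixed_cohort(
    freqs: ReferenceFreqs,
    admix: AdmixSpec,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeDataset, SimTruth]:
    """Sample a one-pulse admixed cohort with tract-level truth recorded."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for s in admix.source_names:
        if s not in freqs.freqs:
            raise KeyError(f"source {s!r} missing from reference frequencies")
    src_freq = np.stack([freqs.freqs[s] for s in admix.source_names])
    c_auto, c_x = admix.c_auto, admix.c_x
    g = admix.generations
    lengths = freqs.map_spec.lengths()
    chrom_idx = freqs.chrom_index()
    gpos = np.array([s.genetic_pos for s in freqs.snps])

    n = admix.n_individuals
    sexes = np.array(["F", "M"] * (n // 2 + 1))[:n]
    calls = np.zeros((freqs.n_snps, n), dtype=np.int8)
    tracts: dict[tuple[str, str, int], np.ndarray] = {}
    realized_rows = []
    k_src = len(admix.source_names)

    for i in range(n):
        ind_id = f"{admix.name}_{i}"
        lens = {"autosomes": np.zeros(k_src), "X": np.zeros(k_src)}
        for chrom, L in lengths.items():
            idx = chrom_idx.get(chrom)
            is_x = chrom == CHROM_X
            n_hap = 1 if (is_x and sexes[i] == "M") else 2
            rate = (2.0 / 3.0) * g if is_x else float(g)
            probs = c_x if is_x else c_auto
            dosage = np.zeros(0 if idx is None else idx.size, dtype=np.int8)
            for hap in range(n_hap):
                tr = _simulate_tracts(L, rate, probs, rng)
                tracts[(ind_id, chrom, hap)] = tr
                cset = "X" if is_x else "autosomes"
                np.add.at(lens[cset], tr[:, 2].astype(int), tr[:, 1] - tr[:, 0])
                if idx is not None and idx.size:
                    src_at = tr[
                        np.minimum(
                            np.searchsorted(tr[:, 1], gpos[idx], side="right"),
                            len(tr) - 1,
                        ),
                        2,
                    ].astype(int)
                    p = src_freq[src_at, idx]
                    dosage = dosage + (rng.random(idx.size) < p).astype(np.int8)
            if idx is None or idx.size == 0:
                continue
            if is_x and sexes[i] == "M":
                calls[idx, i] = 2 * dosage  # hemizygous: {0,2}
            elif admix.pseudo_haploid:
                # one random allele of the diploid genotype
                pick = rng.random(idx.size) < dosage / 2.0
                calls[idx, i] = 2 * pick.astype(np.int8)
            else:
                calls[idx, i] = dosage
        for cset in ("autosomes", "X"):
            tot = lens[cset].sum()
            if tot > 0:
                for s_i, s_name in enumerate(admix.source_names):
                    realized_rows.append(
                        (ind_id, cset, s_name, lens[cset][s_i] / tot)
                    )
    calls = _apply_missing(calls, admix.missing_rate, rng)
    # pseudo-haploid autosomal representation leaves male X untouched ({0,2})
    ph_flags = np.full(n, admix.pseudo_haploid, dtype=bool)
    inds = [IndRecord(f"{admix.name}_{i}", sexes[i], admix.name) for i in range(n)]
    ds = GenotypeDataset(freqs.snps, inds, calls, ph_flags)
    truth = SimTruth(
        source_names=admix.source_names,
        tracts=tracts,
        realized=pd.DataFrame(
            realized_rows, columns=["ind_id", "chromosome_set", "source", "proportion"]
        ),
        params={
            "c_auto": c_auto.tolist(),
            "c_x": c_x.tolist(),
            "female_fractions": list(admix.female_fractions),
            "male_fractions": list(admix.male_fractions),
            "generations": g,
        },
    )
    return ds, truth


def gen_dating_cohort(
    freqs: ReferenceFreqs,
    alpha: float,
    g: int,
    n_individuals: int,
    seed: int | np.random.Generator = 0,
    source_names: tuple[str, str] | None = None,
    name: str = "Dated",
    pseudo_haploid: bool = False,
) -> tuple[GenotypeDataset, SimTruth]:
    """Two-way, sex-balanced admixed cohort for ancestry-decay dating."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    if source_names is None:
        source_names = tuple(freqs.freqs)[:2]
    if len(source_names) != 2:
        raise ValueError("dating cohorts use exactly two source populations")
    admix = AdmixSpec(
        source_names=tuple(source_names),
        female_fractions=(alpha, 1.0 - alpha),
        male_fractions=(alpha, 1.0 - alpha),
        generations=g,
        n_individuals=n_individuals,
        name=name,
        pseudo_haploid=pseudo_haploid,
    )
    return gen_admixed_cohort(freqs, admix, seed)


def combine(*datasets: GenotypeDataset) -> GenotypeDataset:
    """Column-concatenate cohorts sharing the same SNP map."""
    first = datasets[0]
    for ds in datasets[1:]:
        if ds.snps is not first.snps and len(ds.snps) != len(first.snps):
            raise ValueError("datasets must share a SNP map")
    return GenotypeDataset(
        snps=first.snps,
        inds=[i for ds in datasets for i in ds.inds],
        calls=np.hstack([ds.calls for ds in datasets]),
        pseudo_haploid=np.concatenate([ds.pseudo_haploid for ds in datasets]),
    )


# -- scenario catalogue ----------------------------------------------------


def scenario_catalogue() -> dict:
    path = Path(__file__).with_name("scenarios.yaml")
    return yaml.safe_load(path.read_text())


def build_scenario(
    scenario: str,
    seed: int = 0,
    n_snps: int | None = None,
    n_admixed: int | None = None,
    **overrides,
) -> tuple[GenotypeDataset, SimTruth, dict]:
    """Materialize a catalogued scenario: reference panels + admixed cohort.

    Returns the combined dataset, the cohort truth, and the resolved
    scenario parameters.
    """
    catalogue = scenario_catalogue()
    if scenario not in catalogue:
        raise KeyError(
            f"unknown scenario {scenario!r}; available: {sorted(catalogue)}"
        )
    cfg = dict(catalogue[scenario])
    cfg.update(overrides)
    if n_snps is not None:
        cfg["n_snps"] = n_snps
    rng = np.random.default_rng(seed)
    specs = [
        SimPopSpec(
            name=pname,
            drift_F=p["drift_F"],
            n_individuals=p.get("n", 20),
            clade=p.get("clade"),
        )
        for pname, p in cfg["populations"].items()
    ]
    map_spec = GeneticMapSpec(**cfg.get("map", {}))
    freqs = gen_reference_freqs(
        specs, cfg["n_snps"], map_spec, rng, clade_F=cfg.get("clade_F", 0.05)
    )
    panels = [sample_panel(freqs, s.name, rng) for s in specs if s.n_individuals > 0]
    a = cfg["admixed"]
    admix = AdmixSpec(
        source_names=tuple(a["sources"]),
        female_fractions=tuple(a["female_fractions"]),
        male_fractions=tuple(a["male_fractions"]),
        generations=a["generations"],
        n_individuals=n_admixed if n_admixed is not None else a["n"],
        name=a.get("name", "Admixed"),
        pseudo_haploid=a.get("pseudo_haploid", False),
        missing_rate=a.get("missing_rate", 0.0),
    )
    target_ds, truth = gen_admixed_cohort(freqs, admix, rng)
    ds = combine(*panels, target_ds)
    meta = {
        "scenario": scenario,
        "seed": seed,
        "target": admix.name,
        "sources": list(admix.source_names),
        "rights": cfg.get("rights", []),
        "c_auto": admix.c_auto.tolist(),
        "c_x": admix.c_x.tolist(),
        "generations": admix.generations,
        "n_snps": cfg["n_snps"],
        "n_admixed": admix.n_individuals,
    }
    return ds, truth, meta


def write_fixture_dataset(
    out_dir: str | Path, scenario: str, seed: int = 0, **overrides
) -> Path:
    """Write a scenario as an EIGENSTRAT triplet plus a truth TSV; returns prefix."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds, truth, meta = build_scenario(scenario, seed, **overrides)
    prefix = out_dir / scenario
    write_eigenstrat(ds, prefix)
    rows = [("param", k, repr(v)) for k, v in meta.items()]
    for cset, cvec in (("autosomes", meta["c_auto"]), ("X", meta["c_x"])):
        for s, c in zip(meta["sources"], cvec):
            rows.append((f"C_{cset}", s, f"{c:.6f}"))
    mean_a = truth.realized_mean("autosomes")
    mean_x = truth.realized_mean("X")
    for s, ra, rx in zip(meta["sources"], mean_a, mean_x):
        rows.append(("realized_autosomes", s, f"{ra:.6f}"))
        rows.append(("realized_X", s, f"{rx:.6f}"))
    pd.DataFrame(rows, columns=["kind", "key", "value"]).to_csv(
        prefix.with_suffix(".truth.tsv"), sep="\t", index=False
    )
    return prefix
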