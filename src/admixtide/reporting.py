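"""Haplogroup tallies, summary tables and pipeline orchestration.

Uniparental markers give an independent line of evidence on sex-biased
admixture: mtDNA haplogroups trace the female line, Y haplogroups the male
line. This module tallies haplogroup labels into origin classes (the labels
themselves come from upstream callers and are taken as given) and turns the
counts into integer percentage tables, rounding half-up.

``run_pipeline`` drives the whole inference chain on one configuration:
simulate (optional) -> f4 statistics -> mixture fits on autosomes and X
(with source cycling and the mixed-source grid) -> sex-bias inference ->
per-individual compositions and the simplex cline -> ancestry-decay dating
-> TSV reports. Every stage is deterministic given the configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cline import Composition, fit_simplex_line
from .dating import ancestry_decay_curve, fit_decay, to_calendar
from .genotype_io import GenotypeDataset, assign_blocks, group_freqs, read_eigenstrat
from .qpadm import mixed_source_grid, qpadm_cycle, qpadm_fit
from .sexbias import AncestryEstimate, mc_sex_fractions, xa_z_score
from .simulate import build_scenario

logger = logging.getLogger("admixtide")

ORIGIN_CLASSES = ("Africa", "Southwest Asian", "South or East Asia", "Other")

#: default haplogroup -> origin-class prefix rules (longest prefix wins).
#: mtDNA L* lineages and Y E1 are characteristically sub-Saharan African;
#: Y J/G2/R1a and mtDNA R0+16189 are Southwest Asian; mtDNA M30d1 South Asian.
DEFAULT_HAPLOGROUP_ORIGINS: dict[str, str] = {
    "L": "Africa",
    "E1": "Africa",
    "M30d1": "South or East Asia",
    "M": "South or East Asia",
    "R0+16189": "Southwest Asian",
    "J": "Southwest Asian",
    "G2": "Southwest Asian",
    "R1a": "Southwest Asian",
}


@dataclass
class HaplogroupCounts:
    cohort: str
    marker: str  # 'mtDNA' or 'Y'
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("haplogroup counts must be non-negative")
        if sum(self.counts.values()) <= 0:
            raise ValueError(f"{self.cohort}/{self.marker}: zero total count")


def classify_haplogroup(
    label: str, mapping: dict[str, str] | None = None
) -> str:
    """Origin class of a haplogroup label by longest-prefix rule."""
    mapping = mapping if mapping is not None else DEFAULT_HAPLOGROUP_ORIGINS
    best = ""
    for prefix in mapping:
        if label.startswith(prefix) and len(prefix) > len(best):
            best = prefix
    return mapping[best] if best else "Other"


def tally_haplogroups(
    cohort: str, marker: str, labels, mapping: dict[str, str] | None = None
) -> HaplogroupCounts:
    counts: dict[str, int] = {}
    for lab in labels:
        cls = classify_haplogroup(lab, mapping)
        counts[cls] = counts.get(cls, 0) + 1
    return HaplogroupCounts(cohort, marker, counts)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def haplogroup_percent_table(counts: list[HaplogroupCounts]) -> pd.DataFrame:
    """Integer percentage of each origin class per cohort/marker."""
    rows = []
    for hc in counts:
        total = sum(hc.counts.values())
        classes = [c for c in ORIGIN_CLASSES if c in hc.counts]
        classes += [c for c in hc.counts if c not in classes]
        for cls in classes:
            rows.append(
                {
                    "cohort": hc.cohort,
                    "marker": hc.marker,
                    "origin": cls,
                    "count": hc.counts.get(cls, 0),
                    "percent": _round_half_up(100.0 * hc.counts.get(cls, 0) / total),
                }
            )
    return pd.DataFrame(rows)


# -- pipeline --------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run (YAML-serializable)."""

    out_dir: str = "admixtide_out"
    seed: int = 0
    # input: either a catalogued scenario to simulate, or an EIGENSTRAT prefix
    scenario: str | None = None
    prefix: str | None = None
    n_snps: int | None = None
    n_admixed: int | None = None
    target: str = "Coastal"
    sources: list = dc_field(default_factory=list)
    rights: list = dc_field(default_factory=list)
    block_span_cM: float = 5.0
    min_ind_snps: int = 15_000
    high_coverage_snps: int = 100_000
    fit_threshold: float = 0.05
    grid: list = dc_field(default_factory=lambda: list(np.round(np.arange(0, 1.01, 0.1), 2)))
    mc_draws: int = 100_000
    sample_date_AD: float = 1400.0
    dating_refs: list = dc_field(default_factory=list)  # defaults to first two sources

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class Pipeline:
    """Lazy, stage-by-stage runner; every stage writes its TSV under out_dir."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._cache: dict = {}
        logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")

    # -- data ---------------------------------------------------------------

    @property
    def dataset(self) -> GenotypeDataset:
        if "ds" not in self._cache:
            cfg = self.cfg
            if cfg.scenario:
                ds, truth, meta = build_scenario(
                    cfg.scenario, cfg.seed, n_snps=cfg.n_snps, n_admixed=cfg.n_admixed
                )
                self._cache.update(ds=ds, truth=truth, meta=meta)
                if not cfg.sources:
                    cfg.sources = meta["sources"]
                if not cfg.rights:
                    cfg.rights = meta["rights"]
                cfg.target = meta["target"]
            elif cfg.prefix:
                self._cache["ds"] = read_eigenstrat(cfg.prefix)
            else:
                raise ValueError("config needs either 'scenario' or 'prefix'")
            self._validate_groups()
            logger.info(
                "dataset: %d SNPs x %d individuals (seed %d, admixtide %s)",
                self._cache["ds"].n_snps,
                self._cache["ds"].n_inds,
                cfg.seed,
                __version__,
            )
        return self._cache["ds"]

    def _validate_groups(self) -> None:
        ds = self._cache["ds"]
        have = set(ds.groups)
        want = {self.cfg.target, *self.cfg.sources, *self.cfg.rights}
        missing = want - have
        if missing:
            raise ValueError(f"config references groups absent from dataset: {sorted(missing)}")

    def blocks(self, chromosome_set: str):
        key = f"blocks_{chromosome_set}"
        if key not in self._cache:
            self._cache[key] = assign_blocks(
                self.dataset, self.cfg.block_span_cM, chromosome_set
            )
        return self._cache[key]

    # -- stages -------------------------------------------------------------

    def run_fstats(self) -> pd.DataFrame:
        from .fstats import f4_vector

        cfg = self.cfg
        ds = self.dataset
        base = cfg.rights[0]
        quads = [
            (pop, base, rj, base)
            for pop in [cfg.target, *cfg.sources]
            for rj in cfg.rights[1:]
        ]
        vec = f4_vector(ds, quads, self.blocks("autosomes"))
        frame = vec.to_frame()
        frame.to_csv(self.out / "fstats.tsv", sep="\t", index=False)
        return frame

    def run_qpadm(self) -> dict:
        if "qpadm" not in self._cache:
            cfg = self.cfg
            ds = self.dataset
            fits = {}
            for cset in ("autosomes", "X"):
                fits[cset] = qpadm_fit(
                    ds, cfg.target, cfg.sources, cfg.rights, self.blocks(cset)
                )
            rows = []
            for cset, fit in fits.items():
                for j, s in enumerate(fit.source_labels):
                    rows.append(
                        {
                            "chromosome_set": cset,
                            "source": s,
                            "weight": fit.weights[j],
                            "se": fit.weight_se[j],
                            "fit_p": fit.fit_p,
                            "n_snps": fit.n_snps,
                            "n_blocks": fit.n_blocks,
                            "feasible": fit.feasible,
                        }
                    )
            pd.DataFrame(rows).to_csv(self.out / "qpadm.tsv", sep="\t", index=False)
            self._cache["qpadm"] = fits
        return self._cache["qpadm"]

    def run_cycle(self):
        cfg = self.cfg
        table = qpadm_cycle(
            self.dataset,
            cfg.target,
            cfg.sources,
            cfg.rights,
            self.blocks("autosomes"),
            fit_threshold=cfg.fit_threshold,
        )
        table.fits.to_csv(self.out / "cycling.tsv", sep="\t", index=False)
        return table

    def run_grid(self) -> pd.DataFrame:
        cfg = self.cfg
        if len(cfg.sources) < 3:
            raise ValueError("mixed-source grid needs African, Persian and Indian sources")
        grid = mixed_source_grid(
            self.dataset,
            cfg.target,
            cfg.sources[0],
            cfg.sources[1],
            cfg.sources[2],
            cfg.rights,
            cfg.grid,
            self.blocks("autosomes"),
        )
        grid.to_csv(self.out / "grid.tsv", sep="\t", index=False)
        return grid

    def run_sexbias(self):
        fits = self.run_qpadm()
        auto = AncestryEstimate.from_fit(fits["autosomes"])
        x = AncestryEstimate.from_fit(fits["X"])
        res = mc_sex_fractions(auto, x, n_draws=self.cfg.mc_draws, seed=self.cfg.seed)
        z = xa_z_score(auto, x)
        tab = res.table.copy()
        tab["z_auto_vs_x"] = z
        tab.to_csv(self.out / "sexbias.tsv", sep="\t", index=False)
        return res

    def individual_compositions(self) -> list[Composition]:
        """Fit each target individual as its own one-column mixture target."""
        cfg = self.cfg
        ds = self.dataset
        auto = ds.snp_mask("autosomes")
        blocks = self.blocks("autosomes")
        out = []
        for i in ds.group_indices(cfg.target):
            n_called = int(((ds.calls[:, i] >= 0) & auto).sum())
            if n_called < cfg.min_ind_snps:
                continue
            p, n = group_freqs(ds, cfg.target, indices=np.array([i]))
            fit = qpadm_fit(ds, (p, n), cfg.sources, cfg.rights, blocks)
            out.append(
                Composition(ds.inds[i].ind_id, tuple(fit.weights), n_snps=n_called)
            )
        return out

    def run_cline(self):
        if len(self.cfg.sources) != 3:
            raise ValueError("cline analysis needs exactly three sources")
        comps = self.individual_compositions()
        kept = [c for c in comps if c.n_snps > self.cfg.high_coverage_snps]
        if len(kept) < 3:
            logger.warning(
                "only %d individuals above the %d-SNP coverage threshold; "
                "fitting the cline on all %d individuals",
                len(kept),
                self.cfg.high_coverage_snps,
                len(comps),
            )
            kept = comps
        fit = fit_simplex_line(kept)
        frame = fit.endpoints_frame()
        frame.to_csv(self.out / "cline.tsv", sep="\t", index=False)
        if fit.endpoint_se is not None:
            fit.endpoint_se.to_csv(self.out / "cline_se.tsv", sep="\t", index=False)
        return fit

    def run_dating(self):
        cfg = self.cfg
        refs = cfg.dating_refs or cfg.sources[:2]
        fits = self.run_qpadm()
        alpha = float(fits["autosomes"].weights[0])
        curve = ancestry_decay_curve(
            self.dataset, cfg.target, refs[0], refs[1], alpha, min_snps=0
        )
        est = fit_decay(curve)
        cal = to_calendar(est, cfg.sample_date_AD, seed=cfg.seed)
        pd.DataFrame(
            {"d_M": curve.d, "cov": curve.cov, "pairs": curve.pairs}
        ).to_csv(self.out / "decay_curve.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "generations": est.generations,
                    "se": est.generations_se,
                    "amplitude": est.amplitude,
                    "offset": est.offset,
                    "reliable": est.reliable,
                    "date_mean_AD": cal.mean_AD,
                    "date_lo_AD": cal.lo_AD,
                    "date_hi_AD": cal.hi_AD,
                }
            ]
        ).to_csv(self.out / "dating.tsv", sep="\t", index=False)
        return est, cal


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the per-stage results keyed by stage name."""
    pipe = Pipeline(config)
    results: dict = {"dataset": pipe.dataset}
    for stage in ("fstats", "qpadm", "cycle", "grid", "sexbias", "cline", "dating"):
        runner = getattr(pipe, f"run_{stage}")
        try:
            results[stage] = runner()
            logger.info("stage %s complete", stage)
        except ValueError as exc:
            logger.warning("stage %s skipped: %s", stage, exc)
            results[stage] = None
    return results
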