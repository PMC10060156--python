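"""EIGENSTRAT genotype I/O, group bookkeeping and jackknife block assignment.

The package works on the classic three-file EIGENSTRAT representation:

* ``.geno`` — one line per SNP, one character per individual. We store and
  round-trip the digit as the alternate-allele dosage (0/1/2, ``9`` missing).
  Every statistic downstream is unpolarized, so the ref/alt orientation of
  the digit never affects a result.
* ``.snp``  — six whitespace-separated columns: snp id, chromosome,
  genetic position (Morgans, per the format standard), physical position
  (1-based), ref allele, alt allele.
* ``.ind``  — individual id, sex (``M``/``F``/``U``), group label.

Pseudo-haploid individuals (the standard representation for low-coverage
ancient DNA, where each site carries a single randomly drawn allele) are
flagged per individual; their calls are restricted to {0, 2, missing} and
they contribute a single allele copy to frequency estimates. Males are
hemizygous on X and likewise contribute one copy there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

MISSING = -1  # internal missing code; '9' on disk

AUTOSOMES = tuple(str(c) for c in range(1, 23))
CHROM_X = "X"
ALLOWED_CHROMS = frozenset(AUTOSOMES) | {CHROM_X}

#: chromosome-set selectors accepted throughout the package
CHROMOSOME_SETS = ("autosomes", "X")


class FormatError(ValueError):
    """Malformed or mutually inconsistent EIGENSTRAT files."""


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chromosome: str
    genetic_pos: float  # Morgans
    physical_pos: int
    ref_allele: str = "A"
    alt_allele: str = "G"


@dataclass(frozen=True)
class IndRecord:
    ind_id: str
    sex: str = "U"  # 'F', 'M', 'U'
    group: str = "Unknown"


@dataclass
class GenotypeDataset:
    """Individuals x SNPs alternate-allele dosage matrix with metadata.

    ``calls`` has shape (n_snps, n_inds), dtype int8, values {0,1,2,MISSING}.
    """

    snps: list[SnpRecord]
    inds: list[IndRecord]
    calls: np.ndarray
    pseudo_haploid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.snps), len(self.inds)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.inds)} individuals"
            )
        if self.pseudo_haploid is None:
            self.pseudo_haploid = np.zeros(len(self.inds), dtype=bool)
        self.pseudo_haploid = np.asarray(self.pseudo_haploid, dtype=bool)
        ids = [i.ind_id for i in self.inds]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate individual ids")
        for s in self.snps:
            if s.chromosome not in ALLOWED_CHROMS:
                raise FormatError(f"unknown chromosome label {s.chromosome!r}")
        ph = self.pseudo_haploid
        if ph.any():
            bad = (self.calls[:, ph] == 1).any()
            if bad:
                raise FormatError("pseudo-haploid individual carries a heterozygous call")

    # -- convenience views ------------------------------------------------

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_inds(self) -> int:
        return len(self.inds)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.snps])

    @property
    def genetic_pos(self) -> np.ndarray:
        return np.array([s.genetic_pos for s in self.snps], dtype=float)

    @property
    def groups(self) -> np.ndarray:
        return np.array([i.group for i in self.inds])

    @property
    def sexes(self) -> np.ndarray:
        return np.array([i.sex for i in self.inds])

    def group_indices(self, group: str) -> np.ndarray:
        idx = np.flatnonzero(self.groups == group)
        if idx.size == 0:
            raise KeyError(f"group {group!r} not present in dataset")
        return idx

    def snp_mask(self, chromosome_set: str) -> np.ndarray:
        """Boolean mask selecting autosomal or X SNPs."""
        chroms = self.chromosomes
        if chromosome_set == "autosomes":
            return chroms != CHROM_X
        if chromosome_set == "X":
            return chroms == CHROM_X
        raise ValueError(f"chromosome_set must be one of {CHROMOSOME_SETS}")

    def subset_inds(self, indices: Sequence[int]) -> "GenotypeDataset":
        indices = np.asarray(indices, dtype=int)
        return GenotypeDataset(
            snps=self.snps,
            inds=[self.inds[i] for i in indices],
            calls=self.calls[:, indices].copy(),
            pseudo_haploid=self.pseudo_haploid[indices].copy(),
        )

    def with_group(self, ind_id: str, group: str) -> "GenotypeDataset":
        inds = [replace(i, group=group) if i.ind_id == ind_id else i for i in self.inds]
        return GenotypeDataset(self.snps, inds, self.calls, self.pseudo_haploid)


@dataclass
class BlockAssignment:
    """Contiguous genetic-distance jackknife blocks.

    ``block_id`` is -1 for SNPs outside the requested chromosome set and a
    dense 0..n_blocks-1 index otherwise. Blocks are half-open genetic
    intervals [start, start+span) restarting on every chromosome.
    """

    block_id: np.ndarray
    block_span: float  # cM
    chromosome_set: str
    n_blocks: int
    block_chrom: np.ndarray = None  # type: ignore[assignment]  # chromosome of each block

    def counts(self, retained: np.ndarray | None = None) -> np.ndarray:
        """SNPs per block, optionally restricted to a retained-SNP mask."""
        ids = self.block_id
        if retained is not None:
            ids = ids[retained & (self.block_id >= 0)]
        else:
            ids = ids[ids >= 0]
        return np.bincount(ids, minlength=self.n_blocks)


# -- EIGENSTRAT reading / writing -----------------------------------------

_SEX_MAP = {"M": "M", "F": "F", "U": "U"}


def read_eigenstrat(prefix: str | Path) -> GenotypeDataset:
    """Read a ``.geno``/``.snp``/``.ind`` triplet sharing ``prefix``."""
    prefix = Path(prefix)
    geno_p, snp_p, ind_p = (prefix.with_suffix(s) for s in (".geno", ".snp", ".ind"))
    for p in (geno_p, snp_p, ind_p):
        if not p.exists():
            raise FileNotFoundError(p)

    snps: list[SnpRecord] = []
    last_pos: dict[str, float] = {}
    for lineno, line in enumerate(snp_p.read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 4:
            raise FormatError(f"{snp_p}:{lineno}: expected >=4 columns, got {len(parts)}")
        snp_id, chrom, gpos, ppos = parts[0], parts[1], float(parts[2]), int(parts[3])
        if chrom in ("23", "chrX"):
            chrom = CHROM_X
        if chrom not in ALLOWED_CHROMS:
            raise FormatError(f"{snp_p}:{lineno}: unknown chromosome label {chrom!r}")
        if chrom in last_pos and gpos < last_pos[chrom]:
            raise FormatError(
                f"{snp_p}:{lineno}: genetic position decreases within chromosome {chrom}"
            )
        last_pos[chrom] = gpos
        ref, alt = (parts[4], parts[5]) if len(parts) >= 6 else ("A", "G")
        snps.append(SnpRecord(snp_id, chrom, gpos, ppos, ref, alt))

    inds: list[IndRecord] = []
    pseudo: list[bool] = []
    for lineno, line in enumerate(ind_p.read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 3:
            raise FormatError(f"{ind_p}:{lineno}: expected 3 columns")
        sex = _SEX_MAP.get(parts[1].upper(), "U")
        group = parts[2]
        # convention: a trailing '_PH' on the group label marks pseudo-haploid
        ph = group.endswith("_PH")
        inds.append(IndRecord(parts[0], sex, group[:-3] if ph else group))
        pseudo.append(ph)

    lines = geno_p.read_text().splitlines()
    lines = [ln for ln in lines if ln]
    if len(lines) != len(snps):
        raise FormatError(
            f"{geno_p}: {len(lines)} genotype rows but {snp_p} has {len(snps)} SNPs"
        )
    calls = np.full((len(snps), len(inds)), MISSING, dtype=np.int8)
    for i, ln in enumerate(lines):
        if len(ln) != len(inds):
            raise FormatError(
                f"{geno_p}:{i + 1}: row has {len(ln)} genotypes, expected {len(inds)}"
            )
        row = np.frombuffer(ln.encode(), dtype=np.uint8) - ord("0")
        bad = ~np.isin(row, (0, 1, 2, 9))
        if bad.any():
            raise FormatError(f"{geno_p}:{i + 1}: invalid genotype character")
        out = row.astype(np.int8)
        out[row == 9] = MISSING
        calls[i] = out
    return GenotypeDataset(snps, inds, calls, np.array(pseudo, dtype=bool))


def write_eigenstrat(ds: GenotypeDataset, prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write ``ds`` as an EIGENSTRAT triplet; inverse of :func:`read_eigenstrat`."""
    if ds.n_inds == 0:
        raise FormatError("refusing to write a dataset with no individuals")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    geno_p, snp_p, ind_p = (prefix.with_suffix(s) for s in (".geno", ".snp", ".ind"))

    with snp_p.open("w") as fh:
        for s in ds.snps:
            fh.write(
                f"{s.snp_id}\t{s.chromosome}\t{s.genetic_pos:.8f}\t{s.physical_pos}"
                f"\t{s.ref_allele}\t{s.alt_allele}\n"
            )
    with ind_p.open("w") as fh:
        for ind, ph in zip(ds.inds, ds.pseudo_haploid):
            group = ind.group + ("_PH" if ph else "")
            fh.write(f"{ind.ind_id}\t{ind.sex}\t{group}\n")
    out = ds.calls.astype(np.int16).copy()
    out[out == MISSING] = 9
    chars = (out + ord("0")).astype(np.uint8)
    with geno_p.open("wb") as fh:
        for row in chars:
            fh.write(row.tobytes() + b"\n")
    return geno_p, snp_p, ind_p


# -- allele counts ---------------------------------------------------------


def allele_counts(
    ds: GenotypeDataset,
    group: str,
    indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (alt allele copies, total called copies) for one group.

    Diploid individuals contribute 2 copies per called site, pseudo-haploid
    individuals 1 copy, and males contribute 1 copy at X-linked SNPs
    regardless of the diploid flag. Missing calls are excluded.
    """
    idx = ds.group_indices(group) if indices is None else np.asarray(indices, int)
    calls = ds.calls[:, idx].astype(np.float64)
    called = calls >= 0
    # copies per (snp, ind) cell
    copies = np.where(ds.pseudo_haploid[idx], 1.0, 2.0)[None, :]
    on_x = (ds.chromosomes == CHROM_X)[:, None]
    male = (ds.sexes[idx] == "M")[None, :]
    copies = np.where(on_x & male, 1.0, copies)
    # dosage fraction in [0,1]; single-copy cells code alt presence as 2
    frac = calls / 2.0
    alt = np.where(called, frac * copies, 0.0).sum(axis=1)
    tot = np.where(called, copies, 0.0).sum(axis=1)
    return alt, tot


def group_freqs(
    ds: GenotypeDataset, group: str, indices: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (p-hat, called copies); p-hat is NaN where no copies were called."""
    alt, tot = allele_counts(ds, group, indices)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    return p, tot


# -- jackknife block assignment -------------------------------------------


def assign_blocks(
    ds: GenotypeDataset,
    span_cM: float = 5.0,
    chromosome_set: str = "autosomes",
) -> BlockAssignment:
    """Partition SNPs of a chromosome set into contiguous ``span_cM`` blocks.

    Blocks restart at every chromosome boundary; the final block of a
    chromosome may be shorter than the nominal span.
    """
    if span_cM <= 0:
        raise ValueError("block span must be positive")
    mask = ds.snp_mask(chromosome_set)
    chroms = ds.chromosomes
    gpos = ds.genetic_pos
    block_id = np.full(ds.n_snps, -1, dtype=np.int64)
    block_chrom: list[str] = []
    span_M = span_cM / 100.0
    next_block = 0
    order = AUTOSOMES if chromosome_set == "autosomes" else (CHROM_X,)
    for chrom in order:
        sel = np.flatnonzero(mask & (chroms == chrom))
        if sel.size == 0:
            continue
        pos = gpos[sel]
        local = np.floor((pos - pos[0]) / span_M).astype(np.int64)
        # densify: empty windows do not consume block ids
        uniq, dense = np.unique(local, return_inverse=True)
        block_id[sel] = next_block + dense
        next_block += uniq.size
        block_chrom.extend([chrom] * uniq.size)
    return BlockAssignment(
        block_id=block_id,
        block_span=span_cM,
        chromosome_set=chromosome_set,
        n_blocks=next_block,
        block_chrom=np.array(block_chrom),
    )
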