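"""Genomes, haplotypes and populations.

Positions are stored in Morgans internally; physical coordinates only
appear at the I/O boundary, where they are rescaled linearly onto the
genetic map.  Founder populations are fully homozygous diploids: each
individual carries two identical haplotypes per chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Chromosome",
    "Genome",
    "Individual",
    "Population",
    "simulate_founders",
    "load_founders",
    "write_founders",
    "subset_markers",
    "dosage_matrix",
]


@dataclass(frozen=True)
class Chromosome:
    """A single chromosome of the genetic map.

    Parameters
    ----------
    name
        Chromosome label.
    length_m
        Genetic length in Morgans (strictly positive).
    positions
        Sorted marker positions in Morgans, all within ``[0, length_m]``.
    """

    name: str
    length_m: float
    positions: np.ndarray

    def __post_init__(self) -> None:
        if not self.length_m > 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.size:
            if pos.min() < 0 or pos.max() > self.length_m:
                raise ValueError(
                    f"chromosome {self.name}: positions outside [0, {self.length_m}]"
                )
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"chromosome {self.name}: positions not strictly increasing"
                )

    @property
    def n_snp(self) -> int:
        return int(self.positions.size)


@dataclass
class Genome:
    """Ordered collection of chromosomes plus optional marker identifiers."""

    chromosomes: tuple[Chromosome, ...]
    marker_ids: tuple[str, ...] | None = None
    _offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.chromosomes = tuple(self.chromosomes)
        counts = [c.n_snp for c in self.chromosomes]
        self._offsets = np.concatenate([[0], np.cumsum(counts)])
        if self.marker_ids is not None:
            self.marker_ids = tuple(self.marker_ids)
            if len(self.marker_ids) != self.n_snp:
                raise ValueError("marker_ids length does not match marker count")

    @property
    def n_chr(self) -> int:
        return len(self.chromosomes)

    @property
    def n_snp(self) -> int:
        return int(self._offsets[-1])

    @property
    def n_snp_per_chrom(self) -> tuple[int, ...]:
        return tuple(c.n_snp for c in self.chromosomes)

    def chrom_slice(self, l: int) -> slice:
        """Column slice of chromosome ``l`` in concatenated marker order."""
        return slice(int(self._offsets[l]), int(self._offsets[l + 1]))

    @property
    def positions(self) -> np.ndarray:
        """All marker positions (Morgans), concatenated in genome order."""
        if self.n_snp == 0:
            return np.empty(0)
        return np.concatenate([c.positions for c in self.chromosomes])

    def default_marker_ids(self) -> tuple[str, ...]:
        if self.marker_ids is not None:
            return self.marker_ids
        ids = []
        for c in self.chromosomes:
            ids.extend(f"{c.name}_m{h}" for h in range(c.n_snp))
        return tuple(ids)


@dataclass
class Individual:
    """One diploid individual.

    ``haplotypes`` is a ``(2, n_snp)`` binary array over the concatenated
    marker order of the genome; the two rows are the homologous copies.
    """

    id: str
    haplotypes: np.ndarray
    generation: int = 0
    parents: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        hap = np.asarray(self.haplotypes, dtype=np.uint8)
        if hap.ndim != 2 or hap.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, n_snp)")
        if not np.isin(hap, (0, 1)).all():
            raise ValueError("haplotype entries must be binary")
        self.haplotypes = hap

    def chromosome_haplotypes(self, genome: Genome, l: int) -> np.ndarray:
        return self.haplotypes[:, genome.chrom_slice(l)]

    @property
    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0, dtype=np.int64)


@dataclass
class Population:
    """A generation of individuals sharing one genome.

    Haplotypes are stored densely as a ``(n, 2, n_snp)`` array for speed;
    :meth:`individual` materialises a lightweight per-individual view.
    """

    genome: Genome
    haplotypes: np.ndarray
    ids: list[str]
    generation: int = 0
    parents: list[tuple[str, str] | None] | None = None

    def __post_init__(self) -> None:
        hap = np.asarray(self.haplotypes, dtype=np.uint8)
        if hap.ndim != 3 or hap.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_snp)")
        if hap.shape[2] != self.genome.n_snp:
            raise ValueError("haplotype columns do not match genome marker count")
        if hap.shape[0] < 1:
            raise ValueError("a population needs at least one individual")
        if len(self.ids) != hap.shape[0]:
            raise ValueError("ids length does not match individual count")
        self.haplotypes = hap
        if self.parents is None:
            self.parents = [None] * hap.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    def individual(self, s: int) -> Individual:
        return Individual(
            id=self.ids[s],
            haplotypes=self.haplotypes[s],
            generation=self.generation,
            parents=self.parents[s] if self.parents else None,
        )

    def dosages(self) -> np.ndarray:
        return dosage_matrix(self)


def dosage_matrix(pop: Population) -> np.ndarray:
    """``n x n_snp`` allele-dose matrix (0/1/2), genome marker order."""
    return pop.haplotypes.sum(axis=1, dtype=np.int64)


def _uniform_maf(lo: float, hi: float) -> Callable[[np.random.Generator, int], np.ndarray]:
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"invalid maf_law bounds ({lo}, {hi}); need 0 < lo <= hi <= 0.5")
    return lambda rng, size: rng.uniform(lo, hi, size)


def simulate_founders(
    n_ind: int,
    n_chr: int,
    n_snp: int,
    maf_law: tuple[float, float] | Callable[[np.random.Generator, int], np.ndarray] = (0.05, 0.5),
    seed: int | None = None,
) -> tuple[Genome, Population]:
    """Generate a synthetic fully homozygous founder population.

    Chromosomes are each 1 Morgan long with ``n_snp`` markers split as
    evenly as possible between them and placed uniformly at random.  Per
    marker an alternative-allele frequency ``f`` is drawn from ``maf_law``
    (a ``(lo, hi)`` pair for a uniform law, or a callable
    ``maf_law(rng, size) -> frequencies``) and each founder is homozygous
    alternative with probability ``f``.  Markers are mutually independent
    (no founder linkage disequilibrium).
    """
    if n_ind < 2:
        raise ValueError("n_ind must be >= 2")
    if n_chr < 1:
        raise ValueError("n_chr must be >= 1")
    if n_snp < n_chr:
        raise ValueError("n_snp must be >= n_chr")
    freq_fn = _uniform_maf(*maf_law) if isinstance(maf_law, tuple) else maf_law
    rng = np.random.default_rng(seed)

    base, rem = divmod(n_snp, n_chr)
    chroms = []
    for l in range(n_chr):
        m = base + (1 if l < rem else 0)
        pos = np.sort(rng.uniform(0.0, 1.0, m))
        # duplicate uniform draws are measure-zero but would break the
        # strict-sorting invariant; nudge by the minimal increment
        for h in range(1, m):
            if pos[h] <= pos[h - 1]:
                pos[h] = np.nextafter(pos[h - 1], np.inf)
        chroms.append(Chromosome(name=f"chr{l + 1}", length_m=1.0, positions=pos))
    genome = Genome(tuple(chroms))

    freqs = np.asarray(freq_fn(rng, genome.n_snp), dtype=float)
    if freqs.shape != (genome.n_snp,) or np.any(freqs <= 0) or np.any(freqs > 0.5):
        raise ValueError("maf_law must return frequencies in (0, 0.5]")
    alt = rng.random((n_ind, genome.n_snp)) < freqs  # homozygous alt with prob f
    hap = alt.astype(np.uint8)
    haplotypes = np.stack([hap, hap], axis=1)
    ids = [f"F{str(s).zfill(len(str(n_ind - 1)))}" for s in range(n_ind)]
    pop = Population(genome=genome, haplotypes=haplotypes, ids=ids, generation=0)
    return genome, pop


def subset_markers(pop: Population, n_keep: int, seed: int | None = None) -> Population:
    """Random marker subset (uniform, without replacement), order preserved."""
    if n_keep <= 0:
        raise ValueError("n_keep must be > 0")
    genome = pop.genome
    if n_keep > genome.n_snp:
        raise ValueError("n_keep exceeds marker count")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(genome.n_snp, size=n_keep, replace=False))
    all_ids = genome.default_marker_ids()
    chroms = []
    for l, c in enumerate(genome.chromosomes):
        sl = genome.chrom_slice(l)
        local = keep[(keep >= sl.start) & (keep < sl.stop)] - sl.start
        chroms.append(Chromosome(name=c.name, length_m=c.length_m, positions=c.positions[local]))
    new_genome = Genome(tuple(chroms), marker_ids=tuple(all_ids[h] for h in keep))
    return Population(
        genome=new_genome,
        haplotypes=pop.haplotypes[:, :, keep],
        ids=list(pop.ids),
        generation=pop.generation,
        parents=list(pop.parents) if pop.parents else None,
    )


# ---------------------------------------------------------------------------
# I/O: CSV dosage matrix + marker map + chromosome table, and VCF founders.
# ---------------------------------------------------------------------------

def write_founders(pop: Population, geno_file, map_file, chrom_file) -> None:
    """Write a population as a dosage CSV plus map and chromosome tables.

    The files round-trip exactly through :func:`load_founders`: the map is
    written with physical positions equal to the Morgan positions and
    physical length equal to the Morgan length, so the linear rescaling is
    the identity.
    """
    genome = pop.genome
    ids = genome.default_marker_ids()
    dos = dosage_matrix(pop)
    pd.DataFrame(dos, index=pd.Index(pop.ids, name="id"), columns=list(ids)).to_csv(geno_file)
    rows = []
    for l, c in enumerate(genome.chromosomes):
        sl = genome.chrom_slice(l)
        for h, p in enumerate(c.positions):
            rows.append({"marker": ids[sl.start + h], "chrom": c.name, "phys_pos": p})
    pd.DataFrame(rows, columns=["marker", "chrom", "phys_pos"]).to_csv(map_file, index=False)
    pd.DataFrame(
        {
            "chrom": [c.name for c in genome.chromosomes],
            "phys_len": [c.length_m for c in genome.chromosomes],
            "morgan_len": [c.length_m for c in genome.chromosomes],
        }
    ).to_csv(chrom_file, index=False)


def _morgan_positions(phys_pos: np.ndarray, phys_len: float, morgan_len: float) -> np.ndarray:
    """Linear rescaling of physical positions onto [0, morgan_len]."""
    if np.any(phys_pos < 0) or np.any(phys_pos > phys_len):
        raise ValueError("physical position outside chromosome length")
    return phys_pos / phys_len * morgan_len


def _deduplicate_sorted(pos: np.ndarray, chrom: str) -> np.ndarray:
    """Perturb exact ties by the minimal representable increment."""
    pos = pos.copy()
    for h in range(1, pos.size):
        if pos[h] <= pos[h - 1]:
            if pos[h] < pos[h - 1]:
                raise ValueError(f"chromosome {chrom}: unsorted positions after rescaling")
            pos[h] = np.nextafter(pos[h - 1], np.inf)
            logger.warning("chromosome %s: tied map position perturbed at index %d", chrom, h)
    return pos


def _resolve_het(dosages: np.ndarray, mode: str, rng: np.random.Generator | None) -> np.ndarray:
    het = dosages == 1
    if not het.any():
        return dosages
    if mode == "strict":
        raise ValueError("heterozygous founder genotype in strict mode")
    if mode != "lenient":
        raise ValueError(f"unknown mode {mode!r}")
    rng = rng if rng is not None else np.random.default_rng()
    n = int(het.sum())
    dosages = dosages.copy()
    dosages[het] = rng.choice([0, 2], size=n)
    logger.warning("rounded %d heterozygous founder calls to random homozygotes", n)
    return dosages


def load_founders(
    genotype_file,
    chrom_table,
    marker_map=None,
    mode: str = "strict",
    seed: int | None = None,
) -> tuple[Genome, Population]:
    """Load a homozygous founder population from VCF or a CSV dosage matrix.

    Parameters
    ----------
    genotype_file
        Path to a VCF (biallelic SNPs, GT field) or a CSV dosage matrix
        (first column individual id, header row marker ids, values 0/2).
    chrom_table
        CSV or DataFrame with columns ``chrom, phys_len, morgan_len``; its
        row order fixes the chromosome order.
    marker_map
        CSV or DataFrame with columns ``marker, chrom, phys_pos``.
        Required for CSV genotypes; ignored for VCF (coordinates are taken
        from the VCF itself).
    mode
        ``"strict"`` rejects heterozygous founders; ``"lenient"`` rounds
        dosage 1 to a random homozygote and logs.
    """
    chrom_df = chrom_table if isinstance(chrom_table, pd.DataFrame) else pd.read_csv(chrom_table)
    chrom_df = chrom_df.astype({"chrom": str})
    rng = np.random.default_rng(seed)

    path = str(genotype_file)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        sample_ids, marker, chrom, phys, dosages = _read_vcf(genotype_file)
    else:
        if marker_map is None:
            raise ValueError("marker_map is required for CSV genotype input")
        geno = pd.read_csv(genotype_file, index_col=0)
        map_df = marker_map if isinstance(marker_map, pd.DataFrame) else pd.read_csv(marker_map)
        map_df = map_df.astype({"marker": str, "chrom": str})
        missing = set(geno.columns) - set(map_df["marker"])
        if missing:
            raise ValueError(f"markers absent from map: {sorted(missing)[:5]}...")
        map_df = map_df.set_index("marker").loc[list(geno.columns)]
        sample_ids = [str(i) for i in geno.index]
        marker = np.asarray(geno.columns, dtype=object)
        chrom = map_df["chrom"].to_numpy()
        phys = map_df["phys_pos"].to_numpy(dtype=float)
        dosages = geno.to_numpy(dtype=np.int64)

    unknown = set(chrom) - set(chrom_df["chrom"])
    if unknown:
        raise ValueError(f"unknown chromosome(s) in map: {sorted(unknown)}")
    bad = (dosages < 0) | (dosages > 2)
    if bad.any():
        raise ValueError("dosages must be in {0, 1, 2}")
    dosages = _resolve_het(dosages, mode, rng)

    chroms, col_order, marker_ids = [], [], []
    for _, row in chrom_df.iterrows():
        mask = chrom == row["chrom"]
        idx = np.flatnonzero(mask)
        pos_m = _morgan_positions(phys[idx], float(row["phys_len"]), float(row["morgan_len"]))
        order = np.argsort(pos_m, kind="stable")
        idx, pos_m = idx[order], pos_m[order]
        pos_m = _deduplicate_sorted(pos_m, str(row["chrom"]))
        chroms.append(Chromosome(name=str(row["chrom"]), length_m=float(row["morgan_len"]), positions=pos_m))
        col_order.extend(idx.tolist())
        marker_ids.extend(marker[idx].tolist())

    genome = Genome(tuple(chroms), marker_ids=tuple(str(m) for m in marker_ids))
    hap = (dosages[:, col_order] // 2).astype(np.uint8)
    haplotypes = np.stack([hap, hap], axis=1)
    pop = Population(genome=genome, haplotypes=haplotypes, ids=sample_ids, generation=0)
    return genome, pop


def _read_vcf(path) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    marker, chrom, phys, rows = [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"non-biallelic site at {v.CHROM}:{v.POS}")
        gts = np.array(v.genotypes, dtype=object)
        a0 = np.array([g[0] for g in gts], dtype=np.int64)
        a1 = np.array([g[1] for g in gts], dtype=np.int64)
        if (a0 < 0).any() or (a1 < 0).any():
            raise ValueError(f"missing genotype at {v.CHROM}:{v.POS}")
        marker.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chrom.append(v.CHROM)
        phys.append(float(v.POS))  # 1-based VCF coordinate kept as-is
        rows.append(a0 + a1)
    if not rows:
        raise ValueError("no variants in VCF")
    return (
        sample_ids,
        np.asarray(marker, dtype=object),
        np.asarray(chrom, dtype=object),
        np.asarray(phys, dtype=float),
        np.stack(rows, axis=1),
    )
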