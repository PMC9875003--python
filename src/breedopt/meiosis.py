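"""Gametogenesis: Poisson crossovers, strand choice, offspring assembly.

Crossover counts per chromosome are Poisson with rate equal to the
chromosome's length in Morgans; positions are i.i.d. uniform along the
chromosome.  There is no interference and no mutation.  A marker that
falls exactly on a crossover position is resolved deterministically (the
segment starting at that crossover wins), which only matters for
hand-crafted plans since uniform draws hit marker positions with
probability zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome, Individual

__all__ = [
    "CrossoverPlan",
    "MatingTable",
    "sample_crossovers",
    "apply_crossover_plan",
    "make_gamete",
    "make_gametes_batch",
    "cross",
]


@dataclass(frozen=True)
class CrossoverPlan:
    """Crossovers for one chromosome of one meiosis.

    ``positions`` includes the sentinels 0 and ``length_m`` at either end,
    so it has ``n_co + 2`` entries.
    """

    n_co: int
    positions: np.ndarray
    length_m: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.size != self.n_co + 2:
            raise ValueError("positions must contain n_co points plus two sentinels")
        if pos[0] != 0 or pos[-1] != self.length_m:
            raise ValueError("sentinels must be 0 and length_m")
        if np.any(np.diff(pos) < 0):
            raise ValueError("crossover positions must be sorted")

    @property
    def interior(self) -> np.ndarray:
        return self.positions[1:-1]


@dataclass
class MatingTable:
    """Rows of (mother id, father id, progeny count)."""

    mothers: list[str]
    fathers: list[str]
    n_progeny: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.mothers) != len(self.fathers):
            raise ValueError("mothers and fathers must have equal length")
        if self.n_progeny is not None:
            counts = np.asarray(self.n_progeny, dtype=np.int64)
            if counts.shape != (len(self.mothers),) or (counts < 0).any():
                raise ValueError("n_progeny must be one non-negative count per cross")
            self.n_progeny = counts

    @property
    def n_crosses(self) -> int:
        return len(self.mothers)

    @property
    def total_progeny(self) -> int:
        if self.n_progeny is None:
            raise ValueError("progeny counts not allocated yet")
        return int(self.n_progeny.sum())


def sample_crossovers(lambda_chr: float, rng: np.random.Generator) -> CrossoverPlan:
    """Draw one chromosome's crossover count and positions."""
    if not lambda_chr > 0:
        raise ValueError("lambda_chr must be > 0")
    n_co = int(rng.poisson(lambda_chr))
    if n_co:
        interior = np.sort(rng.uniform(0.0, lambda_chr, n_co))
    else:
        interior = np.empty(0)
    positions = np.concatenate([[0.0], interior, [lambda_chr]])
    return CrossoverPlan(n_co=n_co, positions=positions, length_m=lambda_chr)


def apply_crossover_plan(
    haplotypes: np.ndarray,
    marker_pos: np.ndarray,
    plan: CrossoverPlan,
    start_row: int,
) -> np.ndarray:
    """Read a gamete off a 2 x m chromosome given crossovers and start strand.

    Marker ``h`` takes the strand whose segment it falls in: segments
    alternate starting from ``start_row`` and switch at every crossover.
    A marker exactly at a crossover belongs to the segment that starts
    there.
    """
    if marker_pos.size and (marker_pos.min() < 0 or marker_pos.max() > plan.length_m):
        raise ValueError("marker position outside chromosome")
    switches = np.searchsorted(plan.interior, marker_pos, side="right")
    rows = (start_row + switches) % 2
    return haplotypes[rows, np.arange(marker_pos.size)]


def make_gamete(parent: Individual, genome: Genome, rng: np.random.Generator) -> np.ndarray:
    """Simulate one gamete (length ``n_snp`` binary vector)."""
    gamete = np.empty(genome.n_snp, dtype=np.uint8)
    for l, chrom in enumerate(genome.chromosomes):
        sl = genome.chrom_slice(l)
        plan = sample_crossovers(chrom.length_m, rng)
        start = int(rng.integers(0, 2))
        gamete[sl] = apply_crossover_plan(parent.haplotypes[:, sl], chrom.positions, plan, start)
    return gamete


def make_gametes_batch(
    haplotypes: np.ndarray,
    parent_idx: np.ndarray,
    genome: Genome,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate many gametes at once.

    ``haplotypes`` is ``(n_parents, 2, n_snp)``; ``parent_idx`` maps each
    of the ``G`` gametes to its parent.  Statistically identical to
    repeated :func:`make_gamete` calls but vectorised per chromosome.
    """
    parent_idx = np.asarray(parent_idx, dtype=np.int64)
    G = parent_idx.size
    out = np.empty((G, genome.n_snp), dtype=np.uint8)
    for l, chrom in enumerate(genome.chromosomes):
        sl = genome.chrom_slice(l)
        m = chrom.n_snp
        n_co = rng.poisson(chrom.length_m, G)
        starts = rng.integers(0, 2, G)
        total = int(n_co.sum())
        if total and m:
            cpos = rng.uniform(0.0, chrom.length_m, total)
            gamete_of = np.repeat(np.arange(G), n_co)
            # crossover at c flips all markers with pos >= c
            first_marker = np.searchsorted(chrom.positions, cpos, side="left")
            bump = np.zeros((G, m + 1), dtype=np.int64)
            np.add.at(bump, (gamete_of, first_marker), 1)
            switches = np.cumsum(bump[:, :m], axis=1)
        else:
            if total:  # keep the rng stream consistent even if m == 0
                rng.uniform(0.0, chrom.length_m, total)
            switches = np.zeros((G, m), dtype=np.int64)
        rows = (starts[:, None] + switches) % 2
        cols = np.arange(sl.start, sl.stop)
        out[:, sl] = haplotypes[parent_idx[:, None], rows, cols[None, :]]
    return out


def cross(
    parent1: Individual,
    parent2: Individual,
    n_offspring: int,
    genome: Genome,
    rng: np.random.Generator,
    id_prefix: str | None = None,
) -> list[Individual]:
    """Produce offspring by merging one gamete from each parent.

    Selfing is permitted (``parent1 is parent2`` or equal ids).
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    if parent1.haplotypes.shape[1] != genome.n_snp or parent2.haplotypes.shape[1] != genome.n_snp:
        raise ValueError("parent haplotypes do not match genome")
    gen = max(parent1.generation, parent2.generation) + 1
    prefix = id_prefix if id_prefix is not None else f"{parent1.id}x{parent2.id}"
    offspring = []
    for k in range(n_offspring):
        g1 = make_gamete(parent1, genome, rng)
        g2 = make_gamete(parent2, genome, rng)
        offspring.append(
            Individual(
                id=f"{prefix}_{k}",
                haplotypes=np.stack([g1, g2]),
                generation=gen,
                parents=(parent1.id, parent2.id),
            )
        )
    return offspring
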