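"""Trait architecture, heritability calibration and plot phenotypes.

The genetic architecture (marker effects) is sampled once per study and
then frozen; the residual variance is calibrated on the founder
generation only, so realised heritability floats in later generations as
genetic variance changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome, Population, dosage_matrix

__all__ = [
    "TraitArchitecture",
    "PhenoModel",
    "PhenoRecord",
    "sample_qtn_effects",
    "genotypic_values",
    "residual_variance",
    "make_pheno_model",
    "uniform_allocate",
    "allocate_plots",
    "simulate_phenotypes",
    "records_to_frame",
]


@dataclass(frozen=True)
class TraitArchitecture:
    """Marker effect vector with exactly ``n_qtn`` non-zero entries."""

    beta: np.ndarray
    qtn_ids: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        beta.setflags(write=False)
        qtn = np.asarray(self.qtn_ids, dtype=np.int64)
        qtn.setflags(write=False)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "qtn_ids", qtn)
        nz = np.flatnonzero(beta)
        if not np.array_equal(np.sort(qtn), nz):
            raise ValueError("qtn_ids must be exactly the non-zero entries of beta")

    @property
    def n_qtn(self) -> int:
        return int(self.qtn_ids.size)

    def to_frame(self, genome: Genome | None = None) -> pd.DataFrame:
        ids = genome.default_marker_ids() if genome is not None else range(self.beta.size)
        return pd.DataFrame({"marker": list(ids), "beta": self.beta})


@dataclass(frozen=True)
class PhenoModel:
    """Residual variance plus the heritability it was calibrated to."""

    sigma_e2: float
    target_H2: float

    def __post_init__(self) -> None:
        if self.sigma_e2 < 0:
            raise ValueError("sigma_e2 must be >= 0")


@dataclass(frozen=True)
class PhenoRecord:
    individual: str
    replicate: int
    value: float
    generation: int


def sample_qtn_effects(genome: Genome, n_qtn: int, seed: int | None = None) -> TraitArchitecture:
    """Draw QTN positions and effects.

    ``n_qtn`` markers are chosen uniformly without replacement; each gets
    effect ``a * I`` with ``a ~ Exp(rate=1)`` and sign ``I`` +1 or -1 with
    equal probability.  All other marker effects are exactly zero.
    """
    n_snp = genome.n_snp
    if not 1 <= n_qtn <= n_snp:
        raise ValueError(f"n_qtn must be in [1, {n_snp}]")
    rng = np.random.default_rng(seed)
    qtn = np.sort(rng.choice(n_snp, size=n_qtn, replace=False))
    a = rng.exponential(scale=1.0, size=n_qtn)
    sign = rng.choice([-1.0, 1.0], size=n_qtn)
    beta = np.zeros(n_snp)
    beta[qtn] = a * sign
    return TraitArchitecture(beta=beta, qtn_ids=qtn, seed=seed)


def genotypic_values(pop: Population, arch: TraitArchitecture) -> np.ndarray:
    """True genetic value per individual: dosage row times beta."""
    dos = dosage_matrix(pop)
    if dos.shape[1] != arch.beta.size:
        raise ValueError("marker count mismatch between population and architecture")
    return dos @ arch.beta


def residual_variance(founder_values: np.ndarray, target_H2: float) -> float:
    """Residual variance matching a target founder heritability.

    ``sigma_e2 = Var(G0 beta) * (1/H2 - 1)`` with the n-1 sample variance.
    """
    if not 0 < target_H2 < 1:
        raise ValueError("target_H2 must be in (0, 1)")
    vals = np.asarray(founder_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 founder values")
    var_g = float(np.var(vals, ddof=1))
    if var_g == 0:
        raise ValueError("zero genetic variance in founders: degenerate architecture")
    return var_g * (1.0 / target_H2 - 1.0)


def make_pheno_model(founder_values: np.ndarray, target_H2: float) -> PhenoModel:
    return PhenoModel(sigma_e2=residual_variance(founder_values, target_H2), target_H2=target_H2)


def uniform_allocate(n_items: int, n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Spread ``n_items`` over ``n_bins`` as evenly as possible.

    Every bin gets ``floor(n_items / n_bins)``; the remainder goes one
    each to bins sampled uniformly without replacement.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_items < 0:
        raise ValueError("n_items must be >= 0")
    base, rem = divmod(n_items, n_bins)
    counts = np.full(n_bins, base, dtype=np.int64)
    if rem:
        counts[rng.choice(n_bins, size=rem, replace=False)] += 1
    return counts


def allocate_plots(n_I: int, n_P: int, rng: np.random.Generator) -> np.ndarray:
    """Phenotyping plots per individual (may be zero when plots are scarce)."""
    if n_I < 1:
        raise ValueError("n_I must be >= 1")
    return uniform_allocate(n_P, n_I, rng)


def simulate_phenotypes(
    pop: Population,
    plot_counts: np.ndarray,
    arch: TraitArchitecture,
    pheno_model: PhenoModel,
    rng: np.random.Generator,
) -> list[PhenoRecord]:
    """Simulate one phenotype per allocated plot: ``y = G beta + e``."""
    plot_counts = np.asarray(plot_counts, dtype=np.int64)
    if plot_counts.shape != (pop.n_individuals,):
        raise ValueError("plot_counts not aligned to population")
    g = genotypic_values(pop, arch)
    sd = float(np.sqrt(pheno_model.sigma_e2))
    records: list[PhenoRecord] = []
    for s in range(pop.n_individuals):
        k = int(plot_counts[s])
        if k == 0:
            continue
        e = rng.normal(0.0, sd, size=k) if sd > 0 else np.zeros(k)
        for r in range(k):
            records.append(
                PhenoRecord(
                    individual=pop.ids[s],
                    replicate=r + 1,
                    value=float(g[s] + e[r]),
                    generation=pop.generation,
                )
            )
    return records


def records_to_frame(records: list[PhenoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual": [r.individual for r in records],
            "generation": [r.generation for r in records],
            "replicate": [r.replicate for r in records],
            "value": [r.value for r in records],
        }
    )
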