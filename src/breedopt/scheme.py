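"""Budget-constrained breeding campaigns.

Derives per-generation resources from the constraints (total budget,
unit costs, cycle count) and the four decision variables (initial and
later selection intensity, budget split, phenotyping period), then runs
the phenotype -> predict -> select -> mate -> cross loop and reports the
mean true genotypic value of the final generation.

Rounding follows one documented rule: "nearest" means half away from
zero; floor/ceil are used only where explicitly required.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.linear_model import Ridge, RidgeCV

from .genome import Genome, Population, dosage_matrix
from .meiosis import MatingTable, make_gametes_batch
from .trait import (
    PhenoModel,
    TraitArchitecture,
    allocate_plots,
    genotypic_values,
    simulate_phenotypes,
    uniform_allocate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Constraints",
    "SchemeParams",
    "ResourcePlan",
    "BreedingResult",
    "MarkerModel",
    "n_selected",
    "derive_resources",
    "finalize_progeny_allocation",
    "fit_genomic_prediction",
    "weighted_distance",
    "order_matings",
    "allocate_progeny",
    "run_breeding_scheme",
]

#: floor of any pairwise distance used in the 1/dist mating objective;
#: clonal parents would otherwise make it undefined
MIN_MATING_DISTANCE = 1e-12


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass(frozen=True)
class Constraints:
    """Breeder-fixed campaign constraints."""

    B: float
    C_p: float
    C_n: float
    n_gen: int

    def __post_init__(self) -> None:
        if not (self.B > 0 and self.C_p > 0 and self.C_n > 0):
            raise ValueError("B, C_p and C_n must be > 0")
        if self.n_gen < 1:
            raise ValueError("n_gen must be >= 1")


@dataclass(frozen=True)
class SchemeParams:
    """The four optimisable decision variables."""

    i_init: float
    i: float
    b_rep: float
    pheno_p: int

    def __post_init__(self) -> None:
        if not 0 < self.i_init <= 1:
            raise ValueError("i_init must be in (0, 1]")
        if not 0 < self.i <= 1:
            raise ValueError("i must be in (0, 1]")
        if not 0 < self.b_rep < 1:
            raise ValueError("b_rep must be in (0, 1)")
        if int(self.pheno_p) != self.pheno_p or self.pheno_p < 1:
            raise ValueError("pheno_p must be an integer >= 1")
        object.__setattr__(self, "pheno_p", int(self.pheno_p))

    @classmethod
    def from_array(cls, z) -> "SchemeParams":
        z = np.asarray(z, dtype=float)
        return cls(i_init=z[0], i=z[1], b_rep=z[2], pheno_p=int(round(z[3])))


@dataclass
class ResourcePlan:
    """Per-generation resource vectors; index ``t`` runs 1..n_gen (0 unused).

    ``n_new_t[1]`` is deferred (-1) until the first generation's cross
    count is known, see :func:`finalize_progeny_allocation`.
    """

    n_new_tot: int
    n_P_tot: int
    n_P_t: np.ndarray
    n_new_t: np.ndarray
    pheno_generations: list[int]
    B_eff: float
    n_S_t: np.ndarray | None = None
    n_I_t: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def finalized(self) -> bool:
        return bool(self.n_new_t[1] >= 0)


def n_selected(n_I: int, intensity: float) -> int:
    """Selected-parent count: round half-up, clamped to [1, n_I]."""
    if n_I < 1:
        raise ValueError("n_I must be >= 1")
    if not 0 < intensity <= 1:
        raise ValueError("intensity must be in (0, 1]")
    return int(np.clip(_round_half_away(n_I * intensity), 1, n_I))


def derive_resources(
    constraints: Constraints, params: SchemeParams, rng: np.random.Generator
) -> ResourcePlan:
    """Translate (constraints, decision variables) into per-generation plots
    and new-individual counts.

    ``n_new_tot = round(B * b_rep / C_n)``; the leftover budget buys
    ``n_P_tot = floor((B - n_new_tot * C_n) / C_p)`` phenotyping plots.
    Phenotyping happens at generations ``1, 1 + pheno_p, 1 + 2*pheno_p, ...``
    and plots are spread evenly over those generations (remainder one each
    to randomly chosen ones).  If the first generation ends up with fewer
    than 3 plots it is raised to 3 (the prediction model needs data); the
    raise is compensated by removing plots from the later phenotyping
    generations with the most plots so the budget bound still holds.
    """
    B, C_p, C_n, n_gen = constraints.B, constraints.C_p, constraints.C_n, constraints.n_gen
    notes: list[str] = []

    n_new_tot = _round_half_away(B * params.b_rep / C_n)
    if n_new_tot * C_n > B:
        n_new_tot = int(np.floor(B / C_n))
        notes.append("n_new_tot clamped down to fit the budget")
        logger.warning("b_rep=%s exceeds budget granularity; clamped n_new_tot", params.b_rep)
    n_P_tot = int(np.floor((B - n_new_tot * C_n) / C_p))

    pheno_gens = list(range(1, n_gen + 1, params.pheno_p))
    assert len(pheno_gens) == int(np.ceil(n_gen / params.pheno_p))
    n_P_t = np.zeros(n_gen + 1, dtype=np.int64)
    n_P_t[pheno_gens] = uniform_allocate(n_P_tot, len(pheno_gens), rng)

    if n_P_t[1] < 3:
        deficit = 3 - int(n_P_t[1])
        n_P_t[1] = 3
        donors = sorted(pheno_gens[1:], key=lambda t: (-n_P_t[t], t))
        for t in itertools.cycle(donors) if donors else ():
            if deficit == 0 or n_P_t[list(pheno_gens[1:])].sum() == 0:
                break
            if n_P_t[t] > 0:
                n_P_t[t] -= 1
                deficit -= 1
        if deficit:
            notes.append(f"n_P_1 raised to 3 without full compensation (+{deficit} plots)")
            logger.warning("n_P_1 raised to 3; %d plots above plan", deficit)

    n_new_t = np.full(n_gen + 1, -1, dtype=np.int64)
    n_new_t[0] = 0
    B_eff = n_new_tot * C_n + n_P_tot * C_p
    return ResourcePlan(
        n_new_tot=n_new_tot,
        n_P_tot=n_P_tot,
        n_P_t=n_P_t,
        n_new_t=n_new_t,
        pheno_generations=pheno_gens,
        B_eff=B_eff,
        notes=notes,
    )


def finalize_progeny_allocation(plan: ResourcePlan, n_C1: int, rng: np.random.Generator) -> None:
    """Fix ``n_new_1 = n_C_1`` and split the rest evenly over later cycles.

    Founders are homozygous, so extra offspring from the same first-
    generation cross would be genetic copies; one progeny per cross is
    enough.  The remaining ``n_new_tot - n_new_1`` individuals are spread
    over generations 2..n_gen with the remainder going one each to
    randomly chosen generations.
    """
    n_gen = plan.n_P_t.size - 1
    n_new_1 = min(int(n_C1), plan.n_new_tot)
    if n_new_1 < n_C1:
        plan.notes.append(f"n_new_1 capped at n_new_tot={plan.n_new_tot} (< n_C_1={n_C1})")
    plan.n_new_t[1] = n_new_1
    remaining = plan.n_new_tot - n_new_1
    if n_gen > 1:
        plan.n_new_t[2:] = uniform_allocate(remaining, n_gen - 1, rng)
    elif remaining:
        plan.notes.append(f"{remaining} budgeted individuals unused (single-cycle campaign)")


@dataclass
class MarkerModel:
    """Ridge marker-effect model: ``y_hat = X @ beta + intercept``."""

    beta: np.ndarray
    intercept: float
    alpha: float | None = None

    def predict(self, dosages: np.ndarray) -> np.ndarray:
        return np.asarray(dosages, dtype=float) @ self.beta + self.intercept


_ALPHA_GRID = np.logspace(-3, 5, 9)


def fit_genomic_prediction(
    train_dosages: np.ndarray,
    train_phenos: np.ndarray,
    sample_weight: np.ndarray | None = None,
    alpha: float | str = "gcv",
) -> MarkerModel:
    """Ridge regression of phenotype on marker dosages.

    The intercept is unpenalised (markers are centred internally by the
    estimator).  The penalty is chosen by generalised cross-validation
    unless a fixed ``alpha`` is given.  Replicated plots may be passed
    either as repeated rows or, equivalently for a fixed penalty, as one
    row per individual with ``sample_weight`` set to the replicate count
    and the phenotype averaged.
    """
    X = np.asarray(train_dosages, dtype=float)
    y = np.asarray(train_phenos, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("train_dosages and train_phenos are not aligned")
    if y.size < 3:
        raise ValueError("need at least 3 phenotype records")
    if np.ptp(y) == 0:
        return MarkerModel(beta=np.zeros(X.shape[1]), intercept=float(y[0]))
    if alpha == "gcv":
        est = RidgeCV(alphas=_ALPHA_GRID, fit_intercept=True)
    else:
        est = Ridge(alpha=float(alpha), fit_intercept=True, solver="cholesky")
    est.fit(X, y, sample_weight=sample_weight)
    chosen = float(getattr(est, "alpha_", alpha if alpha != "gcv" else np.nan))
    return MarkerModel(beta=est.coef_.copy(), intercept=float(est.intercept_), alpha=chosen)


def weighted_distance(dosage_a: np.ndarray, dosage_b: np.ndarray, beta_hat: np.ndarray) -> float:
    """Euclidean distance of effect-weighted dosage profiles."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape or a.shape != np.asarray(beta_hat).shape:
        raise ValueError("dosage and effect vectors must have equal length")
    return float(np.linalg.norm(beta_hat * (a - b)))


def _tour_cost(tour: np.ndarray, W: np.ndarray) -> float:
    return float(W[tour, np.roll(tour, -1)].sum())


def _tsp_order(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Short cyclic order under edge weights W: exact for n <= 8,
    nearest-neighbour plus 2-opt above."""
    n = W.shape[0]
    if n <= 3:
        return np.arange(n)
    if n <= 8:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(1, n)):
            tour = np.array((0,) + perm)
            cost = _tour_cost(tour, W)
            if cost < best_cost:
                best, best_cost = tour, cost
        return best
    # nearest neighbour construction
    start = int(rng.integers(n))
    unvisited = np.ones(n, dtype=bool)
    unvisited[start] = False
    tour = [start]
    for _ in range(n - 1):
        cand = np.where(unvisited, W[tour[-1]], np.inf)
        nxt = int(np.argmin(cand))
        tour.append(nxt)
        unvisited[nxt] = False
    tour = np.array(tour)
    # 2-opt: repeatedly apply the best segment reversal (vectorised scan)
    for _ in range(4 * n):
        t_next = np.roll(tour, -1)
        d_cur = W[tour, t_next]
        # reversing tour[i..j] replaces edges (i-1,i) and (j,j+1)
        gain_best, move = 0.0, None
        new_head = W[tour[:, None], tour[None, :]]  # W[tour[i-1], tour[j]]
        for i in range(1, tour.size - 1):
            j = np.arange(i + 1, tour.size)
            delta = (
                new_head[i - 1, j]
                + W[tour[i], t_next[j]]
                - d_cur[i - 1]
                - d_cur[j]
            )
            k = int(np.argmin(delta))
            if delta[k] < gain_best - 1e-15:
                gain_best, move = float(delta[k]), (i, int(j[k]))
        if move is None:
            break
        i, j = move
        tour[i : j + 1] = tour[i : j + 1][::-1]
    return tour


def order_matings(
    selected_ids: list[str],
    selected_dosages: np.ndarray,
    beta_hat: np.ndarray,
    rng: np.random.Generator,
) -> MatingTable:
    """Build the mating table for the selected parents.

    Four or more parents: a travelling-salesperson order over inverse
    effect-weighted distances, pairing consecutive parents plus the
    wrap-around (``n_C = n_S`` crosses).  Two or three parents: all
    pairwise couples.  One parent: selfing.
    """
    n_S = len(selected_ids)
    if n_S < 1:
        raise ValueError("need at least one selected parent")
    if n_S == 1:
        return MatingTable(mothers=[selected_ids[0]], fathers=[selected_ids[0]])
    if n_S <= 3:
        pairs = list(itertools.combinations(range(n_S), 2))
        return MatingTable(
            mothers=[selected_ids[a] for a, _ in pairs],
            fathers=[selected_ids[b] for _, b in pairs],
        )
    weighted = np.asarray(selected_dosages, dtype=float) * np.asarray(beta_hat, dtype=float)
    D = squareform(pdist(weighted))
    W = 1.0 / np.clip(D, MIN_MATING_DISTANCE, None)
    np.fill_diagonal(W, 0.0)
    tour = _tsp_order(W, rng)
    nxt = np.roll(tour, -1)
    return MatingTable(
        mothers=[selected_ids[s] for s in tour],
        fathers=[selected_ids[s] for s in nxt],
    )


def allocate_progeny(n_C: int, n_new: int, rng: np.random.Generator) -> np.ndarray:
    """Progeny per cross: even split, remainder to random crosses."""
    if n_C < 1:
        raise ValueError("n_C must be >= 1")
    return uniform_allocate(n_new, n_C, rng)


@dataclass
class BreedingResult:
    """Outcome of one simulated campaign."""

    u: float
    trajectory: list[float]
    plan: ResourcePlan
    seed: int | None
    final_population: Population
    terminated_early: bool = False


def run_breeding_scheme(
    constraints: Constraints,
    params: SchemeParams,
    genome: Genome,
    founders: Population,
    arch: TraitArchitecture,
    pheno_model: PhenoModel,
    seed: int | None = None,
) -> BreedingResult:
    """Simulate one full breeding campaign and return its objective value.

    For each cycle ``t = 1..n_gen``: phenotype the current generation (if
    plots are scheduled), refit the marker model on all records collected
    since generation 1, select the top ``n_S_t`` by predicted value (ties
    broken by position), mate them, and cross to produce the next
    generation, which replaces the current one entirely.  ``u`` is the
    mean true genotypic value of the generation produced by cycle
    ``n_gen``.
    """
    rng = np.random.default_rng(seed)
    n_gen = constraints.n_gen
    plan = derive_resources(constraints, params, rng)
    plan.n_S_t = np.zeros(n_gen + 1, dtype=np.int64)
    plan.n_I_t = np.zeros(n_gen + 1, dtype=np.int64)

    pop = founders
    beta = arch.beta
    trajectory = [float(np.mean(dosage_matrix(pop) @ beta))]
    train_X: list[np.ndarray] = []
    train_y: list[float] = []
    train_w: list[int] = []
    model: MarkerModel | None = None
    terminated_early = False

    for t in range(1, n_gen + 1):
        n_I = pop.n_individuals
        plan.n_I_t[t] = n_I
        dos = dosage_matrix(pop)

        if plan.n_P_t[t] > 0:
            counts = allocate_plots(n_I, int(plan.n_P_t[t]), rng)
            records = simulate_phenotypes(pop, counts, arch, pheno_model, rng)
            # compress replicates: one weighted row per phenotyped individual
            by_ind: dict[str, list[float]] = {}
            for rec in records:
                by_ind.setdefault(rec.individual, []).append(rec.value)
            id_to_row = {pid: s for s, pid in enumerate(pop.ids)}
            for pid, vals in by_ind.items():
                train_X.append(dos[id_to_row[pid]])
                train_y.append(float(np.mean(vals)))
                train_w.append(len(vals))
            model = fit_genomic_prediction(
                np.asarray(train_X, dtype=float),
                np.asarray(train_y),
                sample_weight=np.asarray(train_w, dtype=float),
            )

        if model is not None:
            preds = model.predict(dos)
            beta_hat = model.beta
        else:  # no phenotyping budget at all: selection is uninformed
            preds = np.zeros(n_I)
            beta_hat = np.zeros(genome.n_snp)

        intensity = params.i_init if t == 1 else params.i
        n_S = n_selected(n_I, intensity)
        plan.n_S_t[t] = n_S
        order = np.argsort(-preds, kind="stable")  # ties fall back to id order
        sel = np.sort(order[:n_S])
        table = order_matings([pop.ids[s] for s in sel], dos[sel], beta_hat, rng)

        if t == 1:
            finalize_progeny_allocation(plan, table.n_crosses, rng)
        n_new = int(plan.n_new_t[t])
        if n_new == 0:
            terminated_early = True
            logger.warning("cycle %d has no new individuals; campaign ends early", t)
            break
        table.n_progeny = allocate_progeny(table.n_crosses, n_new, rng)

        id_to_sel = {pop.ids[s]: k for k, s in enumerate(sel)}
        mother_idx = np.repeat([id_to_sel[m] for m in table.mothers], table.n_progeny)
        father_idx = np.repeat([id_to_sel[f] for f in table.fathers], table.n_progeny)
        sel_haps = pop.haplotypes[sel]
        g_m = make_gametes_batch(sel_haps, mother_idx, genome, rng)
        g_f = make_gametes_batch(sel_haps, father_idx, genome, rng)
        new_haps = np.stack([g_m, g_f], axis=1)
        parents = [
            (pop.ids[sel[mother_idx[k]]], pop.ids[sel[father_idx[k]]]) for k in range(n_new)
        ]
        pop = Population(
            genome=genome,
            haplotypes=new_haps,
            ids=[f"g{t}_i{k}" for k in range(n_new)],
            generation=t,
            parents=parents,
        )
        trajectory.append(float(np.mean(dosage_matrix(pop) @ beta)))

    return BreedingResult(
        u=trajectory[-1],
        trajectory=trajectory,
        plan=plan,
        seed=seed,
        final_population=pop,
        terminated_early=terminated_early,
    )
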