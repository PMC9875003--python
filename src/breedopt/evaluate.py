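"""Scenario definitions, optimiser benchmarking and comparison reports.

Eight study scenarios combine heritability (0.3 / 0.7), cycle count
(5 / 10) and budget (200 or 600 cost units per cycle) at unit costs.
Two benchmarking designs are supported: a "representative" design (few
long optimisation runs per method, many evaluation campaigns of each
method's representative run) and an "all-runs" design (many short runs,
one evaluation campaign each, all cross-method pairs compared).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bayesopt import (
    OptimisationRun,
    SearchSpace,
    default_search_space,
    run_bayes_opt,
    run_random_opt,
)
from .genome import simulate_founders
from .scheme import Constraints, SchemeParams, run_breeding_scheme
from .trait import genotypic_values, make_pheno_model, sample_qtn_effects

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "scenario_table",
    "BreedingObjective",
    "make_synthetic_objective",
    "evaluate_params",
    "pairwise_win_proportion",
    "cumulative_maxima",
    "representative_run",
    "ecdf_table",
    "ExperimentConfig",
    "run_experiment",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One constraint scenario: heritability, cycles and budget."""

    label: str
    H2: float
    n_gen: int
    B: float
    C_p: float = 1.0
    C_n: float = 1.0

    def constraints(self) -> Constraints:
        return Constraints(B=self.B, C_p=self.C_p, C_n=self.C_n, n_gen=self.n_gen)


def _build_scenarios() -> dict[str, ScenarioSpec]:
    out = {}
    labels = iter("abcdefgh")
    for h2 in (0.3, 0.7):
        for n_gen in (5, 10):
            for per_cycle in (200, 600):
                lab = next(labels)
                out[lab] = ScenarioSpec(label=lab, H2=h2, n_gen=n_gen, B=n_gen * per_cycle)
    return out


SCENARIOS: dict[str, ScenarioSpec] = _build_scenarios()


def scenario_table() -> list[ScenarioSpec]:
    return [SCENARIOS[k] for k in sorted(SCENARIOS)]


class BreedingObjective:
    """Callable objective ``g(z, seed) -> u`` wrapping one fixed study
    (founders, trait architecture, phenotype model, constraints)."""

    def __init__(self, constraints, genome, founders, arch, pheno_model):
        self.constraints = constraints
        self.genome = genome
        self.founders = founders
        self.arch = arch
        self.pheno_model = pheno_model

    def __call__(self, z, seed: int | None = None) -> float:
        params = SchemeParams.from_array(z)
        result = run_breeding_scheme(
            self.constraints, params, self.genome, self.founders,
            self.arch, self.pheno_model, seed=seed,
        )
        return result.u


def make_synthetic_objective(
    scenario: ScenarioSpec,
    n_ind: int,
    n_chr: int,
    n_snp: int,
    n_qtn: int,
    seed: int | None = None,
) -> BreedingObjective:
    """Build a study on synthetic founders for the given scenario."""
    ss = np.random.SeedSequence(seed)
    founder_seed, arch_seed = (int(c.generate_state(1)[0]) for c in ss.spawn(2))
    genome, founders = simulate_founders(n_ind, n_chr, n_snp, seed=founder_seed)
    arch = sample_qtn_effects(genome, n_qtn, seed=arch_seed)
    g0 = genotypic_values(founders, arch)
    pheno_model = make_pheno_model(g0, scenario.H2)
    return BreedingObjective(scenario.constraints(), genome, founders, arch, pheno_model)


def evaluate_params(params, objective, n_evaluation: int, seed: int | None = None) -> np.ndarray:
    """Objective samples from ``n_evaluation`` independent campaigns with
    identical parameters."""
    if n_evaluation < 1:
        raise ValueError("n_evaluation must be >= 1")
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_evaluation):
        s = int(child.generate_state(1)[0])
        try:
            out.append(float(objective(params, s)))
        except Exception:  # noqa: BLE001
            logger.warning("evaluation campaign failed (seed %d); recorded as NaN", s)
            out.append(np.nan)
    return np.asarray(out)


def pairwise_win_proportion(samples_a: np.ndarray, samples_b: np.ndarray) -> float:
    """Fraction of ordered pairs (a, b) with a strictly greater than b."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(np.mean(a[:, None] > b[None, :]))


def cumulative_maxima(run: OptimisationRun) -> np.ndarray:
    """Per-iteration running maximum of observed objective values."""
    if not run.observations:
        raise ValueError("run has no observations")
    iters = sorted({o.iteration for o in run.observations})
    cur, out = -np.inf, []
    for it in iters:
        cur = max(cur, max(o.y for o in run.observations if o.iteration == it))
        out.append(cur)
    return np.asarray(out)


def representative_run(runs: list[OptimisationRun]) -> int:
    """Index of the run whose cumulative-maxima curve is MSE-closest to the
    across-run average curve (ties go to the lowest index)."""
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    curves = [cumulative_maxima(r) for r in runs]
    lengths = {c.size for c in curves}
    if len(lengths) != 1:
        raise ValueError("runs have unequal iteration counts")
    stack = np.vstack(curves)
    avg = stack.mean(axis=0)
    mse = np.mean((stack - avg) ** 2, axis=1)
    return int(np.argmin(mse))


def ecdf_table(samples: np.ndarray) -> list[tuple[float, float]]:
    """Right-continuous ECDF as (value, quantile) rows; quantile at max = 1."""
    x = np.sort(np.asarray(samples, dtype=float))
    if x.size == 0:
        raise ValueError("samples must be non-empty")
    values, counts = np.unique(x, return_counts=True)
    quant = np.cumsum(counts) / x.size
    return list(zip(values.tolist(), quant.tolist()))


@dataclass
class ExperimentConfig:
    """Configuration of one benchmarking batch."""

    scenarios: list[str]
    n_runs: int
    n_iter: int
    q: int
    n_evaluation: int
    comparison: str  # "representative" | "all_runs"
    founder_n_ind: int = 100
    founder_n_chr: int = 10
    founder_n_snp: int = 500
    n_qtn: int = 100
    init_n: int = 5
    filter_tol: float = 1e-3
    seed: int = 0
    focus_kwargs: dict | None = None

    def __post_init__(self) -> None:
        if self.comparison not in ("representative", "all_runs"):
            raise ValueError("comparison must be 'representative' or 'all_runs'")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenario label(s): {sorted(unknown)}")


def _scenario_experiment(config: ExperimentConfig, scenario: ScenarioSpec) -> dict:
    """Run both methods on one scenario and compare them.

    All runs of both methods share one study (founders, trait
    architecture, phenotype model) -- the founder data set is fixed input,
    exactly as a real accession panel would be -- so cross-run comparisons
    only reflect optimiser and campaign stochasticity.  Run ``k`` of each
    method uses distinct optimiser seeds.
    """
    space = default_search_space(scenario.n_gen)
    runs: dict[str, list[OptimisationRun]] = {"bayes": [], "random": []}
    failures: dict[str, int] = {"bayes": 0, "random": 0}

    root = np.random.SeedSequence([config.seed, ord(scenario.label)])
    study_seed = int(root.generate_state(1)[0])
    objective = make_synthetic_objective(
        scenario, config.founder_n_ind, config.founder_n_chr,
        config.founder_n_snp, config.n_qtn, seed=study_seed,
    )
    for k, child in enumerate(root.spawn(config.n_runs)):
        bo_seed, rand_seed = (int(c.generate_state(1)[0]) for c in child.spawn(2))
        for method, fn, opt_seed in (
            ("bayes", run_bayes_opt, bo_seed),
            ("random", run_random_opt, rand_seed),
        ):
            kwargs = dict(n_iter=config.n_iter, q=config.q, init_n=config.init_n, seed=opt_seed)
            if method == "bayes":
                kwargs.update(filter_tol=config.filter_tol, focus_kwargs=config.focus_kwargs)
            try:
                runs[method].append(fn(objective, space, **kwargs))
            except Exception:  # noqa: BLE001
                failures[method] += 1
                logger.warning("%s run %d failed on scenario %s", method, k, scenario.label)

    eval_root = np.random.SeedSequence([config.seed, ord(scenario.label), 7])
    samples: dict[str, np.ndarray] = {}
    rep_idx: dict[str, int | None] = {"bayes": None, "random": None}
    for method in ("bayes", "random"):
        if not runs[method]:
            raise RuntimeError(f"all {method} runs failed on scenario {scenario.label}")
        child = eval_root.spawn(1)[0]
        if config.comparison == "representative":
            rep = representative_run(runs[method]) if len(runs[method]) > 1 else 0
            rep_idx[method] = rep
            samples[method] = evaluate_params(
                runs[method][rep].recommendation,
                objective,
                config.n_evaluation,
                seed=int(child.generate_state(1)[0]),
            )
        else:
            vals = []
            for r, run in enumerate(runs[method]):
                vals.append(
                    evaluate_params(
                        run.recommendation, objective, config.n_evaluation,
                        seed=int(child.generate_state(1)[0]) + r,
                    )
                )
            samples[method] = np.concatenate(vals)

    keep = {m: samples[m][~np.isnan(samples[m])] for m in samples}
    win = pairwise_win_proportion(keep["bayes"], keep["random"])
    return {
        "scenario": scenario.label,
        "H2": scenario.H2,
        "n_gen": scenario.n_gen,
        "B": scenario.B,
        "comparison": config.comparison,
        "win_proportion_bayes": win,
        "n_bayes": int(keep["bayes"].size),
        "n_random": int(keep["random"].size),
        "n_comparisons": int(keep["bayes"].size * keep["random"].size),
        "n_failed_runs": failures,
        "representative": rep_idx,
        "cum_max_bayes": [cumulative_maxima(r).tolist() for r in runs["bayes"]],
        "cum_max_random": [cumulative_maxima(r).tolist() for r in runs["random"]],
        "ecdf_bayes": ecdf_table(keep["bayes"]),
        "ecdf_random": ecdf_table(keep["random"]),
        "samples_bayes": keep["bayes"].tolist(),
        "samples_random": keep["random"].tolist(),
        "runs_bayes": [r.to_dict() for r in runs["bayes"]],
        "runs_random": [r.to_dict() for r in runs["random"]],
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the configured batch and return the comparison report."""
    report = {
        "config": {
            k: v for k, v in vars(config).items() if k != "focus_kwargs"
        },
        "scenarios": {},
    }
    for label in config.scenarios:
        report["scenarios"][label] = _scenario_experiment(config, SCENARIOS[label])
    return report
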