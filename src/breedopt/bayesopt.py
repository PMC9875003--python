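"""Gaussian-process Bayesian optimisation of the scheme parameters.

A constant-mean GP with an isotropic Gaussian kernel on min-max scaled
inputs is fitted by maximum likelihood (length-scale and relative nugget
over a coarse grid followed by a local search; the constant mean and the
signal variance have closed-form profile-ML values).  Batches of ``q``
points are proposed by iterated expected-improvement maximisation under
a constant-liar update (lie = worst observed value), and proposals that
collide with existing training points are replaced by random points.
The acquisition is maximised by focus search: repeated random sampling
in a box that is halved around the incumbent each round.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky
from scipy.optimize import minimize
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "Dimension",
    "SearchSpace",
    "Observation",
    "GPModel",
    "OptimisationRun",
    "default_search_space",
    "latin_hypercube",
    "fit_gp",
    "gp_posterior",
    "expected_improvement",
    "focus_search",
    "propose_batch",
    "run_bayes_opt",
    "run_random_opt",
]


@dataclass(frozen=True)
class Dimension:
    name: str
    lower: float
    upper: float
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"dimension {self.name}: lower must be < upper")


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box, possibly with integer-valued dimensions."""

    dimensions: tuple[Dimension, ...]

    @property
    def n_dim(self) -> int:
        return len(self.dimensions)

    @property
    def lower(self) -> np.ndarray:
        return np.array([d.lower for d in self.dimensions], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.array([d.upper for d in self.dimensions], dtype=float)

    @property
    def integer_mask(self) -> np.ndarray:
        return np.array([d.integer for d in self.dimensions], dtype=bool)

    def scale(self, Z: np.ndarray) -> np.ndarray:
        """Min-max scale points onto the unit hypercube."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return (Z - self.lower) / (self.upper - self.lower)

    def round_integers(self, Z: np.ndarray) -> np.ndarray:
        Z = np.array(Z, dtype=float, copy=True)
        mask = self.integer_mask
        if Z.ndim == 1:
            Z[mask] = np.round(Z[mask])
        else:
            Z[:, mask] = np.round(Z[:, mask])
        return Z

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        Z = rng.uniform(self.lower, self.upper, size=(n, self.n_dim))
        return self.round_integers(Z)

    def contains(self, z: np.ndarray) -> bool:
        z = np.asarray(z, dtype=float)
        return bool(np.all(z >= self.lower - 1e-12) and np.all(z <= self.upper + 1e-12))


def default_search_space(n_gen: int) -> SearchSpace:
    """Default bounds for the four decision variables."""
    return SearchSpace(
        (
            Dimension("i_init", 0.01, 0.9),
            Dimension("i", 0.01, 0.9),
            Dimension("b_rep", 0.05, 0.95),
            Dimension("pheno_p", 1, max(n_gen, 2), integer=True),
        )
    )


@dataclass(frozen=True)
class Observation:
    z: np.ndarray
    y: float
    iteration: int
    kind: str  # initdesign | infill_ei | rand_opt | rand_replaced

    def to_dict(self) -> dict:
        return {
            "z": [float(v) for v in self.z],
            "y": float(self.y),
            "iteration": self.iteration,
            "kind": self.kind,
        }


def latin_hypercube(n: int, space: SearchSpace, rng: np.random.Generator) -> np.ndarray:
    """Latin hypercube design: one point per axis stratum per dimension,
    jittered uniformly within strata; integer dimensions rounded last."""
    if n < 1:
        raise ValueError("n must be >= 1")
    d = space.n_dim
    U = np.empty((n, d))
    for j in range(d):
        strata = rng.permutation(n)
        U[:, j] = (strata + rng.uniform(size=n)) / n
    Z = space.lower + U * (space.upper - space.lower)
    return space.round_integers(Z)


# ---------------------------------------------------------------------------
# Gaussian process
# ---------------------------------------------------------------------------

_THETA_BOUNDS = (1e-2, 10.0)
_ETA_BOUNDS = (1e-8, 10.0)


@dataclass
class GPModel:
    """Fitted GP state on unit-scaled inputs.

    ``theta`` is the kernel length-scale, ``eta`` the relative nugget
    (noise variance as a fraction of the signal variance ``sigma2``), and
    ``mean`` the constant prior mean.
    """

    space: SearchSpace
    X: np.ndarray  # scaled training inputs
    y: np.ndarray
    theta: float
    eta: float
    sigma2: float
    mean: float
    _chol: np.ndarray = field(repr=False, default=None)
    _alpha: np.ndarray = field(repr=False, default=None)

    @property
    def nugget(self) -> float:
        """Absolute noise variance."""
        return self.sigma2 * self.eta

    def with_observation(self, z_scaled: np.ndarray, y: float) -> "GPModel":
        """Append one pseudo-observation, keeping the hyperparameters."""
        X = np.vstack([self.X, np.atleast_2d(z_scaled)])
        yy = np.append(self.y, y)
        m = GPModel(
            space=self.space, X=X, y=yy,
            theta=self.theta, eta=self.eta, sigma2=self.sigma2, mean=self.mean,
        )
        m._factorize()
        return m

    def _factorize(self) -> None:
        K = _corr(self.X, self.X, self.theta)
        n = self.X.shape[0]
        jitter = 1e-10
        for _ in range(8):
            try:
                L = cholesky(K + (self.eta + jitter) * np.eye(n), lower=True)
                break
            except np.linalg.LinAlgError:
                jitter *= 100
        else:
            raise np.linalg.LinAlgError("singular GP covariance despite jitter escalation")
        self._chol = L
        self._alpha = cho_solve((L, True), self.y - self.mean)


def _corr(A: np.ndarray, B: np.ndarray, theta: float) -> np.ndarray:
    d2 = np.sum(A**2, axis=1)[:, None] + np.sum(B**2, axis=1)[None, :] - 2 * A @ B.T
    np.clip(d2, 0, None, out=d2)
    return np.exp(-d2 / (2 * theta**2))


def _profile_nll(log_params: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Negative log marginal likelihood with mean and variance profiled out."""
    theta, eta = np.exp(log_params)
    n = X.shape[0]
    K = _corr(X, X, theta) + eta * np.eye(n)
    try:
        L = cholesky(K + 1e-10 * np.eye(n), lower=True)
    except np.linalg.LinAlgError:
        return 1e10
    ones = np.ones(n)
    Ki_y = cho_solve((L, True), y)
    Ki_1 = cho_solve((L, True), ones)
    m = float(ones @ Ki_y / (ones @ Ki_1))
    r = y - m
    s2 = float(r @ cho_solve((L, True), r)) / n
    if s2 <= 0:
        return 1e10
    return 0.5 * (n * np.log(s2) + 2 * np.sum(np.log(np.diag(L))) + n)


def fit_gp(observations, space: SearchSpace) -> GPModel:
    """Fit the GP to observations (list of :class:`Observation` or
    an ``(X, y)`` pair in raw coordinates)."""
    if isinstance(observations, tuple):
        Z, y = observations
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        y = np.asarray(y, dtype=float)
    else:
        Z = np.array([o.z for o in observations], dtype=float)
        y = np.array([o.y for o in observations], dtype=float)
    if Z.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(y) == 0:
        raise ValueError("observations have identical objective values")
    X = space.scale(Z)

    theta_grid = np.exp(np.linspace(np.log(0.03), np.log(3.0), 10))
    eta_grid = np.array([1e-6, 1e-4, 1e-3, 1e-2, 3e-2, 1e-1, 3e-1, 1.0])
    grid = []
    for th in theta_grid:
        for et in eta_grid:
            grid.append((_profile_nll(np.log([th, et]), X, y), np.log([th, et])))
    grid.sort(key=lambda t: t[0])
    best_val, best = grid[0]
    for _, start in grid[:4]:  # multi-start local search from the best cells
        res = minimize(
            _profile_nll,
            start,
            args=(X, y),
            method="L-BFGS-B",
            bounds=[np.log(_THETA_BOUNDS), np.log(_ETA_BOUNDS)],
        )
        if res.fun < best_val:
            best_val, best = res.fun, res.x
    theta, eta = np.exp(best)

    n = X.shape[0]
    K = _corr(X, X, theta) + eta * np.eye(n)
    L = cholesky(K + 1e-10 * np.eye(n), lower=True)
    ones = np.ones(n)
    Ki_y = cho_solve((L, True), y)
    Ki_1 = cho_solve((L, True), ones)
    mean = float(ones @ Ki_y / (ones @ Ki_1))
    r = y - mean
    sigma2 = float(r @ cho_solve((L, True), r)) / n
    model = GPModel(
        space=space, X=X, y=y,
        theta=float(theta), eta=float(eta), sigma2=max(sigma2, 1e-12), mean=mean,
    )
    model._factorize()
    return model


def gp_posterior(model: GPModel, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and SD of the latent objective at raw-space points."""
    single = np.asarray(Z).ndim == 1
    Xq = model.space.scale(Z)
    k = _corr(Xq, model.X, model.theta)
    mu = model.mean + k @ model._alpha
    v = cho_solve((model._chol, True), k.T)
    var = model.sigma2 * np.clip(1.0 - np.sum(k * v.T, axis=1), 0.0, None)
    sd = np.sqrt(var)
    if single:
        return float(mu[0]), float(sd[0])
    return mu, sd


def _g_hat_max(model: GPModel) -> float:
    """Maximum posterior mean over the training inputs."""
    k = _corr(model.X, model.X, model.theta)
    mu = model.mean + k @ model._alpha
    return float(np.max(mu))


def ei_from_moments(mu: np.ndarray, sd: np.ndarray, g_star: float) -> np.ndarray:
    """Closed-form ``E[max(0, N(mu, sd^2) - g_star)]``; zero-SD points
    degenerate to ``max(0, mu - g_star)``."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sd = np.atleast_1d(np.asarray(sd, dtype=float))
    imp = mu - g_star
    ei = np.where(sd > 0, 0.0, np.maximum(imp, 0.0))
    ok = sd > 0
    if np.any(ok):
        u = imp[ok] / sd[ok]
        ei[ok] = imp[ok] * norm.cdf(u) + sd[ok] * norm.pdf(u)
    return np.maximum(ei, 0.0)


def expected_improvement(model: GPModel, Z: np.ndarray, g_hat_max: float | None = None) -> np.ndarray:
    """Closed-form EI against the maximum posterior mean at training inputs."""
    if g_hat_max is None:
        g_hat_max = _g_hat_max(model)
    single = np.asarray(Z).ndim == 1
    mu, sd = gp_posterior(model, np.atleast_2d(np.asarray(Z, dtype=float)))
    ei = ei_from_moments(mu, sd, g_hat_max)
    if single:
        return float(ei[0])
    return ei


def focus_search(
    acquisition,
    space: SearchSpace,
    rng: np.random.Generator,
    restarts: int = 5,
    shrink_rounds: int = 3,
    points_per_round: int = 1000,
) -> np.ndarray:
    """Maximise an acquisition by iterated sample-and-shrink.

    Each restart random-samples the current box, re-centres it on the
    incumbent and halves every dimension's range (integer dimensions
    never shrink below one unit), for ``shrink_rounds`` rounds.  Returns
    the best point seen overall.
    """
    lower0, upper0 = space.lower, space.upper
    int_mask = space.integer_mask
    best_z, best_v = None, -np.inf
    for _ in range(restarts):
        lo, hi = lower0.copy(), upper0.copy()
        for _ in range(shrink_rounds):
            Z = rng.uniform(lo, hi, size=(points_per_round, space.n_dim))
            Z = space.round_integers(Z)
            vals = np.asarray(acquisition(Z), dtype=float)
            k = int(np.argmax(vals))
            if vals[k] > best_v:
                best_v, best_z = float(vals[k]), Z[k].copy()
            centre = Z[k]
            width = (hi - lo) / 2.0
            width[int_mask] = np.maximum(width[int_mask], 1.0)
            lo = np.clip(centre - width / 2.0, lower0, upper0)
            hi = np.clip(centre + width / 2.0, lower0, upper0)
    return best_z


def propose_batch(
    model: GPModel,
    q: int,
    space: SearchSpace,
    filter_tol: float,
    rng: np.random.Generator,
    focus_kwargs: dict | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Propose ``q`` points by EI with constant-liar updates.

    After each proposal the GP is updated (same hyperparameters) with the
    lie ``L = min(observed y)``.  Proposals closer than ``filter_tol``
    (Euclidean, scaled coordinates) to any real training point are
    replaced by random points.  Returns the points and a kind tag per
    point (``infill_ei`` or ``rand_replaced``).
    """
    focus_kwargs = focus_kwargs or {}
    lie = float(np.min(model.y))
    train_X = model.X.copy()
    work = model
    proposals = []
    for _ in range(q):
        g_star = _g_hat_max(work)
        z = focus_search(
            lambda Z: expected_improvement(work, Z, g_star), space, rng, **focus_kwargs
        )
        proposals.append(z)
        work = work.with_observation(space.scale(z)[0], lie)
    kinds = []
    out = []
    for z in proposals:
        z = space.round_integers(z)
        dist = np.linalg.norm(train_X - space.scale(z), axis=1)
        if float(dist.min()) < filter_tol:
            z = space.sample_uniform(1, rng)[0]
            kinds.append("rand_replaced")
        else:
            kinds.append("infill_ei")
        out.append(z)
    return np.array(out), kinds


@dataclass
class OptimisationRun:
    """Trace of one optimisation: every evaluation plus the recommendation."""

    method: str
    seed: int | None
    observations: list[Observation]
    recommendation: np.ndarray
    recommendation_value: float
    cum_max: list[float]
    n_iter: int
    q: int
    n_failures: int = 0

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "observations": [o.to_dict() for o in self.observations],
            "recommendation": [float(v) for v in self.recommendation],
            "recommendation_value": float(self.recommendation_value),
            "cum_max": [float(v) for v in self.cum_max],
            "n_iter": self.n_iter,
            "q": self.q,
            "n_failures": self.n_failures,
        }


def _evaluate(objective, z, space, rng, iteration, kind, failures) -> Observation:
    """Evaluate with failure tolerance: a failing point is replaced by a
    random one and the run continues."""
    for attempt in range(5):
        seed = int(rng.integers(2**31 - 1))
        try:
            y = float(objective(z, seed))
            return Observation(z=np.asarray(z, dtype=float), y=y, iteration=iteration, kind=kind)
        except Exception:  # noqa: BLE001 - objective is user code
            failures.append(iteration)
            logger.warning("objective failed at %s (attempt %d); replacing point", z, attempt + 1)
            z = space.sample_uniform(1, rng)[0]
            kind = "rand_replaced"
    raise RuntimeError("objective failed repeatedly on random points")


def _cumulative_max_by_iteration(observations: list[Observation]) -> list[float]:
    iters = sorted({o.iteration for o in observations})
    cur, out = -np.inf, []
    for it in iters:
        ys = [o.y for o in observations if o.iteration == it]
        cur = max(cur, max(ys))
        out.append(cur)
    return out


def run_bayes_opt(
    objective,
    space: SearchSpace,
    n_iter: int,
    q: int,
    init_n: int = 5,
    filter_tol: float = 1e-3,
    seed: int | None = None,
    focus_kwargs: dict | None = None,
) -> OptimisationRun:
    """Full Bayesian-optimisation loop.

    ``objective(z, seed) -> float`` is evaluated on ``init_n`` Latin-
    hypercube points (iteration 0) and then on ``q`` constant-liar EI
    proposals per iteration.  The recommendation is the visited point
    with the highest posterior mean under the final model.
    """
    rng = np.random.default_rng(seed)
    failures: list[int] = []
    observations: list[Observation] = []
    for z in latin_hypercube(init_n, space, rng):
        observations.append(_evaluate(objective, z, space, rng, 0, "initdesign", failures))
    for it in range(1, n_iter + 1):
        try:
            model = fit_gp(observations, space)
            props, kinds = propose_batch(model, q, space, filter_tol, rng, focus_kwargs)
        except (np.linalg.LinAlgError, ValueError):
            logger.warning("GP fit failed at iteration %d; falling back to random points", it)
            props = space.sample_uniform(q, rng)
            kinds = ["rand_replaced"] * q
        for z, kind in zip(props, kinds):
            observations.append(_evaluate(objective, z, space, rng, it, kind, failures))

    final_model = fit_gp(observations, space)
    Zs = np.array([o.z for o in observations])
    mu, _ = gp_posterior(final_model, Zs)
    best = int(np.argmax(mu))
    return OptimisationRun(
        method="bayes",
        seed=seed,
        observations=observations,
        recommendation=observations[best].z,
        recommendation_value=float(mu[best]),
        cum_max=_cumulative_max_by_iteration(observations),
        n_iter=n_iter,
        q=q,
        n_failures=len(failures),
    )


def run_random_opt(
    objective,
    space: SearchSpace,
    n_iter: int,
    q: int,
    init_n: int = 5,
    seed: int | None = None,
) -> OptimisationRun:
    """Random-search baseline with the same evaluation budget.

    The first iteration additionally evaluates ``init_n`` random points
    so the total count matches the Bayesian run; the recommendation is
    the best *observed* point.
    """
    rng = np.random.default_rng(seed)
    failures: list[int] = []
    observations: list[Observation] = []
    for z in space.sample_uniform(init_n, rng):
        observations.append(_evaluate(objective, z, space, rng, 0, "initdesign", failures))
    for it in range(1, n_iter + 1):
        for z in space.sample_uniform(q, rng):
            observations.append(_evaluate(objective, z, space, rng, it, "rand_opt", failures))
    ys = np.array([o.y for o in observations])
    best = int(np.argmax(ys))
    return OptimisationRun(
        method="random",
        seed=seed,
        observations=observations,
        recommendation=observations[best].z,
        recommendation_value=float(ys[best]),
        cum_max=_cumulative_max_by_iteration(observations),
        n_iter=n_iter,
        q=q,
        n_failures=len(failures),
    )
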