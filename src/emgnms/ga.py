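"""Deep subject calibration by a bound-constrained real-coded genetic
algorithm.

The GA calibrates 12 parameters per muscle — the activation shape factor
A, the maximum isometric force F_O, the optimal fiber length l_o, the
active force-length spread sigma_A, and the four coefficients of each of
the fiber-length and moment-arm cubics — plus the gravity-model link
masses: M_a and M_fh for the shoulder (50 genes with 4 muscles) and M_fh
for the elbow (25 genes with 2 muscles).  The cost is the RMS error
between the measured external torque and tau^p - tau^g over the training
samples, identical to the linear method's cost.

Search bounds: A in [-3, 0); F_O in F_O' x [0.7, 4]; l_o, geometry
coefficients and masses within +/-30% of their defaults; sigma_A within
+/-10%.  The optimiser is a standard bounded real-coded GA — tournament
selection (k=2), BLX-alpha crossover, Gaussian mutation with clipping to
the bounds, one elite — run as two populations of 10 chromosomes with
periodic best-individual migration, stopping when the best cost stalls or
a generation cap is reached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data import Design
from .evaluation import e_rms, predict_external_torque
from .gravity import ArmAnthropometry
from .muscle import JointModel, MuscleTendonUnit
from .results import FitResult

__all__ = [
    "GENES_PER_MUSCLE",
    "ParameterBounds",
    "GAConfig",
    "GAResult",
    "make_bounds",
    "encode",
    "decode",
    "chromosome_length",
    "make_cost",
    "optimize_ga",
    "calibrate_ga",
]

GENES_PER_MUSCLE = 12
#: Penalty cost for chromosomes whose decoded geometry is invalid at some
#: training pose (negative fiber length, arcsin domain).
PENALTY_COST = 1e6
_A_UPPER = -1e-6  # open upper bound of A realised as 0 - epsilon
_ZERO_COEFF_EPS = 1e-6


def _muscle_gene_names(muscle: str) -> list[str]:
    return (
        [f"{muscle}.A", f"{muscle}.F_O", f"{muscle}.l_o", f"{muscle}.sigma_A"]
        + [f"{muscle}.coeff_l[{i}]" for i in range(4)]
        + [f"{muscle}.coeff_r[{i}]" for i in range(4)]
    )


def gravity_gene_names(joint: str) -> tuple[str, ...]:
    return ("M_a", "M_fh") if joint == "shoulder" else ("M_fh",)


def chromosome_length(joint: str) -> int:
    n_muscles = 4 if joint == "shoulder" else 2
    return GENES_PER_MUSCLE * n_muscles + len(gravity_gene_names(joint))


@dataclass(frozen=True)
class ParameterBounds:
    """Box search space of one joint's chromosome."""

    lower: np.ndarray
    upper: np.ndarray
    names: tuple[str, ...]
    joint: str

    def __post_init__(self) -> None:
        if not np.all(self.lower < self.upper):
            bad = [n for n, lo, up in zip(self.names, self.lower, self.upper) if lo >= up]
            raise ValueError(f"degenerate bounds for {bad}")

    @property
    def n_genes(self) -> int:
        return self.lower.size

    def contains(self, genes: np.ndarray) -> bool:
        return bool(np.all(genes >= self.lower) and np.all(genes <= self.upper))

    def clip(self, genes: np.ndarray) -> np.ndarray:
        return np.clip(genes, self.lower, self.upper)


def _pct_interval(value: float, pct: float) -> tuple[float, float]:
    if value == 0.0:
        warnings.warn(
            "default coefficient is exactly 0: +/-% bound degenerate, widened to +/-eps",
            stacklevel=3,
        )
        return (-_ZERO_COEFF_EPS, _ZERO_COEFF_EPS)
    lo, hi = value * (1 - pct), value * (1 + pct)
    return (min(lo, hi), max(lo, hi))


def make_bounds(model: JointModel, anthro: ArmAnthropometry) -> ParameterBounds:
    """Search bounds around the default parameter values."""
    lower, upper, names = [], [], []
    for mtu in model.muscles:
        per = [
            (-3.0, _A_UPPER),
            (0.7 * mtu.F_O, 4.0 * mtu.F_O),
            _pct_interval(mtu.l_o, 0.30),
            _pct_interval(mtu.sigma_A, 0.10),
        ]
        per += [_pct_interval(c, 0.30) for c in mtu.coeff_l]
        per += [_pct_interval(c, 0.30) for c in mtu.coeff_r]
        for lo, hi in per:
            lower.append(lo)
            upper.append(hi)
        names.extend(_muscle_gene_names(mtu.name))
    for gname in gravity_gene_names(model.joint):
        lo, hi = _pct_interval(getattr(anthro, gname), 0.30)
        lower.append(lo)
        upper.append(hi)
        names.append(gname)
    return ParameterBounds(
        lower=np.array(lower), upper=np.array(upper),
        names=tuple(names), joint=model.joint,
    )


def encode(model: JointModel, anthro: ArmAnthropometry) -> np.ndarray:
    """Flatten a joint model + gravity masses into a chromosome."""
    genes: list[float] = []
    for mtu in model.muscles:
        genes += [mtu.A, mtu.F_O, mtu.l_o, mtu.sigma_A]
        genes += list(mtu.coeff_l) + list(mtu.coeff_r)
    genes += [getattr(anthro, g) for g in gravity_gene_names(model.joint)]
    return np.array(genes, dtype=float)


def decode(
    genes: np.ndarray, template: JointModel, anthro: ArmAnthropometry
) -> tuple[JointModel, ArmAnthropometry]:
    """Rebuild a joint model and anthropometry from a chromosome.

    Non-optimised fields (muscle names, pennation angle at l_o) come from
    the template; ``decode(encode(m, a)) == (m, a)`` gene-for-gene.
    """
    genes = np.asarray(genes, dtype=float)
    expected = chromosome_length(template.joint)
    if genes.size != expected:
        raise ValueError(
            f"{template.joint} chromosome needs {expected} genes, got {genes.size}"
        )
    muscles = []
    for i, mtu in enumerate(template.muscles):
        block = genes[i * GENES_PER_MUSCLE : (i + 1) * GENES_PER_MUSCLE]
        muscles.append(
            MuscleTendonUnit(
                name=mtu.name,
                A=float(min(block[0], 0.0)),
                F_O=float(block[1]),
                l_o=float(block[2]),
                sigma_A=float(block[3]),
                phi_o=mtu.phi_o,
                coeff_l=tuple(block[4:8]),
                coeff_r=tuple(block[8:12]),
            )
        )
    grav = genes[GENES_PER_MUSCLE * len(template.muscles) :]
    if template.joint == "shoulder":
        new_anthro = anthro.with_masses(M_a=grav[0], M_fh=grav[1])
    else:
        new_anthro = anthro.with_masses(M_fh=grav[0])
    return replace(template, muscles=tuple(muscles)), new_anthro


def make_cost(design: Design, template: JointModel, anthro: ArmAnthropometry):
    """RMS-torque cost of a chromosome on the training design.

    Chromosomes whose decoded geometry is invalid at a training pose get a
    large penalty rather than raising, so the population size stays fixed.
    """
    tau_m = design.tau_m(template.joint)

    def cost(genes: np.ndarray) -> float:
        try:
            model, a = decode(genes, template, anthro)
            pred = predict_external_torque(model, a, design)
        except ValueError:
            return PENALTY_COST
        return e_rms(tau_m, pred)

    return cost


def _feasible_scale(values: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                    target: float) -> float:
    """Largest-range clamp of ``target`` so that ``target * values`` stays
    inside [lower, upper] elementwise (values may have either sign)."""
    lo_f, hi_f = 0.0, np.inf
    for v, lo, up in zip(values, lower, upper):
        if v == 0.0:
            continue
        a, b = sorted((lo / v, up / v))
        lo_f, hi_f = max(lo_f, a), min(hi_f, b)
    if lo_f > hi_f:  # inconsistent box: keep the identity gauge
        return 1.0
    return float(np.clip(target, lo_f, hi_f))


def fix_gauge(genes: np.ndarray, bounds: ParameterBounds,
              defaults: np.ndarray) -> np.ndarray:
    """Resolve the exact scale degeneracies of a chromosome.

    The torque model determines only the products F_O * r(theta) and the
    ratio l(theta) / l_o: jointly rescaling the moment-arm coefficients by
    lambda and F_O by 1/lambda (or l_o and the fiber-length coefficients
    by the same lambda) leaves every prediction unchanged.  This picks,
    per muscle, the representative on each ridge closest (in least
    squares) to the default chromosome, clipped to the search bounds — a
    canonical-gauge report of parameters the data cannot distinguish.
    """
    out = genes.copy()
    n_muscles = (genes.size - len(gravity_gene_names(bounds.joint))) // GENES_PER_MUSCLE
    for i in range(n_muscles):
        o = i * GENES_PER_MUSCLE
        # moment-arm scale against F_O
        r = out[o + 8 : o + 12]
        r_def = defaults[o + 8 : o + 12]
        denom = float(r @ r)
        if denom > 0:
            lam = _feasible_scale(
                np.concatenate([r, [1.0 / out[o + 1]]]),
                np.concatenate([bounds.lower[o + 8 : o + 12], [1.0 / bounds.upper[o + 1]]]),
                np.concatenate([bounds.upper[o + 8 : o + 12], [1.0 / bounds.lower[o + 1]]]),
                float(r_def @ r) / denom,
            )
            out[o + 8 : o + 12] = lam * r
            out[o + 1] = out[o + 1] / lam
        # fiber-length scale against l_o
        c = out[o + 4 : o + 8]
        c_def = defaults[o + 4 : o + 8]
        denom = float(c @ c)
        if denom > 0:
            lam = _feasible_scale(
                np.concatenate([c, [out[o + 2]]]),
                np.concatenate([bounds.lower[o + 4 : o + 8], [bounds.lower[o + 2]]]),
                np.concatenate([bounds.upper[o + 4 : o + 8], [bounds.upper[o + 2]]]),
                float(c_def @ c) / denom,
            )
            out[o + 4 : o + 8] = lam * c
            out[o + 2] = lam * out[o + 2]
    # guard against last-ulp rounding outside the box
    return bounds.clip(out)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.  ``seed`` is mandatory: every stochastic
    result is reported with the seed that produced it."""

    seed: int
    pop_size: int = 10
    n_populations: int = 2
    max_generations: int = 500
    stall_generations: int = 50
    fitness_tol: float = 1e-5      # N*m improvement below which the run stalls
    crossover_rate: float = 0.9
    blx_alpha: float = 0.5
    mutation_rate: float = 0.1     # per-gene probability
    mutation_sigma_frac: float = 0.1  # mutation s.d. as a fraction of gene range
    migration_interval: int = 10
    include_default: bool = True   # seed population 0 with the default chromosome
    polish: bool = True            # bounded local descent from the final best

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be at least 4")
        if self.fitness_tol < 0:
            raise ValueError("fitness_tol must be non-negative")


@dataclass(frozen=True)
class GAResult:
    best_genes: np.ndarray
    best_cost: float
    trace: np.ndarray              # best cost after each generation (index 0 = init)
    stop_reason: str               # "fitness_variation" | "max_generations"
    n_generations: int
    n_evaluations: int


def _polish(cost_fn, bounds: ParameterBounds, starts: list[np.ndarray],
            incumbent: np.ndarray, cost0: float) -> tuple[np.ndarray, float]:
    """Memetic finishing step: bounded quasi-Newton descent from each start
    (the GA's best individual and the normative default chromosome), in
    bound-normalised coordinates — the raw genes span many orders of
    magnitude.  Keeps the incumbent if no descent improves on it."""
    from scipy.optimize import minimize

    span = bounds.upper - bounds.lower
    best, best_cost = incumbent, cost0
    for start in starts:
        x0 = (bounds.clip(start) - bounds.lower) / span
        res = minimize(
            lambda x: cost_fn(bounds.lower + x * span),
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * bounds.n_genes,
        )
        if res.fun < best_cost:
            best = bounds.clip(bounds.lower + res.x * span)
            best_cost = float(res.fun)
    return best, best_cost


def optimize_ga(cost_fn, bounds: ParameterBounds, config: GAConfig,
                initial: np.ndarray | None = None) -> GAResult:
    """Minimise ``cost_fn`` over the box ``bounds``.

    ``initial`` optionally injects one chromosome (e.g. the defaults) into
    the first population.  The best-cost trace is non-increasing: each
    population keeps one elite, and the global best is tracked across
    populations.
    """
    rng = np.random.default_rng(config.seed)
    d = bounds.n_genes
    span = bounds.upper - bounds.lower
    n_eval = 0

    def evaluate(pop: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += pop.shape[0]
        return np.array([cost_fn(ind) for ind in pop])

    pops, costs = [], []
    for p in range(config.n_populations):
        pop = bounds.lower + span * rng.random((config.pop_size, d))
        if p == 0 and config.include_default and initial is not None:
            pop[0] = bounds.clip(initial)
        pops.append(pop)
        costs.append(evaluate(pop))

    def global_best() -> tuple[np.ndarray, float]:
        bi = [int(np.argmin(c)) for c in costs]
        bp = int(np.argmin([c[i] for c, i in zip(costs, bi)]))
        return pops[bp][bi[bp]].copy(), float(costs[bp][bi[bp]])

    best_genes, best_cost = global_best()
    trace = [best_cost]
    stop_reason = "max_generations"
    gen = 0
    for gen in range(1, config.max_generations + 1):
        for p in range(config.n_populations):
            pop, cost = pops[p], costs[p]
            elite = int(np.argmin(cost))
            children = [pop[elite].copy()]
            while len(children) < config.pop_size:
                # tournament selection, k = 2
                parents = []
                for _ in range(2):
                    i, j = rng.integers(0, config.pop_size, size=2)
                    parents.append(pop[i] if cost[i] <= cost[j] else pop[j])
                p1, p2 = parents
                if rng.random() < config.crossover_rate:
                    lo = np.minimum(p1, p2)
                    hi = np.maximum(p1, p2)
                    spread = hi - lo
                    child = rng.uniform(
                        lo - config.blx_alpha * spread,
                        hi + config.blx_alpha * spread,
                    )
                else:
                    child = p1.copy()
                mutate = rng.random(d) < config.mutation_rate
                child = child + mutate * rng.normal(
                    0.0, config.mutation_sigma_frac * span
                )
                children.append(bounds.clip(child))
            pops[p] = np.array(children)
            costs[p] = evaluate(pops[p])
        if (
            config.n_populations > 1
            and config.migration_interval > 0
            and gen % config.migration_interval == 0
        ):
            for p in range(config.n_populations):
                q = (p + 1) % config.n_populations
                worst = int(np.argmax(costs[q]))
                src = int(np.argmin(costs[p]))
                pops[q][worst] = pops[p][src].copy()
                costs[q][worst] = costs[p][src]
        cand_genes, cand_cost = global_best()
        if cand_cost < best_cost:
            best_genes, best_cost = cand_genes, cand_cost
        trace.append(best_cost)
        s = config.stall_generations
        if gen >= s and trace[-1 - s] - trace[-1] <= config.fitness_tol:
            stop_reason = "fitness_variation"
            break
    return GAResult(
        best_genes=best_genes,
        best_cost=best_cost,
        trace=np.array(trace),
        stop_reason=stop_reason,
        n_generations=gen,
        n_evaluations=n_eval,
    )


def calibrate_ga(
    design: Design,
    model: JointModel,
    anthro: ArmAnthropometry,
    config: GAConfig,
) -> FitResult:
    """Full GA calibration of one joint on a training design."""
    bounds = make_bounds(model, anthro)
    cost = make_cost(design, model, anthro)
    default_genes = encode(model, anthro)
    initial = default_genes if config.include_default else None
    result = optimize_ga(cost, bounds, config, initial=initial)
    best_genes, best_cost = result.best_genes, result.best_cost
    if config.polish:
        starts = [
            result.best_genes,
            fix_gauge(result.best_genes, bounds, default_genes),
            default_genes,
        ]
        best_genes, best_cost = _polish(cost, bounds, starts, best_genes, best_cost)
    best = fix_gauge(best_genes, bounds, default_genes)
    fitted_model, fitted_anthro = decode(best, model, anthro)
    return FitResult(
        method="ga",
        joint=model.joint,
        model=fitted_model,
        anthro=fitted_anthro,
        train_trial_ids=design.trial_ids,
        seed=config.seed,
        details={
            "best_cost": best_cost,
            "ga_cost": result.best_cost,
            "trace": result.trace,
            "stop_reason": result.stop_reason,
            "n_generations": result.n_generations,
            "n_evaluations": result.n_evaluations,
            "best_genes": best,
            "gene_names": bounds.names,
        },
    )
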