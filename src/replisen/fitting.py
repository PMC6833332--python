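"""Fit the compartment model to marker data.

The 13 tunable quantities (four rate-ladder endpoint pairs, the two scalar
rates ``m_GS`` and ``m_AD``, and the three staining fractions) are searched
with a genetic algorithm over a normalised genome — rates on a log10 scale
inside box bounds, fractions linear in [0, 1] — and the best candidates are
refined with box-constrained quasi-Newton descent, which doubles as the
local-minimum check (the projected-gradient norm at termination is
reported).

The discrepancy measure is a range-normalised mean squared error: for each
marker the residuals are divided by that marker's observed range before
squaring, making percentage channels (0-100) and PD (a handful of
doublings) commensurate, and the per-marker means are combined with
user-controllable weights. Replicates enter as individual records. Because
the model's PD starts at zero while a culture sampled mid-life reports
cumulative doublings, PD observations are by default aligned by subtracting
the mean observed PD at the earliest sampled time (``subtract-first``); a
free additive offset or no alignment are available.

Front door: :class:`SenescenceMarkerModel` (construct from a
:class:`~replisen.data.Dataset` or CSV) whose :meth:`~SenescenceMarkerModel.fit`
returns a :class:`SenescenceFit` results object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .data import Dataset, MARKERS
from .errors import ConfigError, DataError
from .markers import MarkerParams, marker_readouts
from .model import ModelParameters, simulate

__all__ = [
    "CostSpec",
    "GAConfig",
    "FitResult",
    "cost",
    "baseline_variance",
    "fit_ga",
    "refine_gradient",
    "holdout_analysis",
    "HoldoutReport",
    "SenescenceMarkerModel",
    "SenescenceFit",
    "encode",
    "decode",
]

_PD_MODES = ("subtract-first", "free-offset", "none")


@dataclass(frozen=True)
class CostSpec:
    """Weights and PD alignment for the model-data discrepancy."""

    weights: dict = field(default_factory=lambda: {m: 1.0 for m in MARKERS})
    pd_offset_mode: str = "subtract-first"

    def __post_init__(self):
        if self.pd_offset_mode not in _PD_MODES:
            raise ConfigError(f"pd_offset_mode must be one of {_PD_MODES}")
        for m, w in self.weights.items():
            if m not in MARKERS:
                raise ConfigError(f"weight for unknown marker {m!r}")
            if w <= 0:
                raise ConfigError(f"weight for {m} must be positive, got {w}")

    def weight(self, marker: str) -> float:
        return float(self.weights.get(marker, 1.0))


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (conventional defaults, fully exposed)."""

    population_size: int = 200
    generations: int = 300
    tournament_size: int = 3
    crossover_prob: float = 0.7
    mutation_sigma: float = 0.10  # fraction of the unit gene range
    mutation_prob: float = 0.15
    elitism: int = 2
    rate_bounds: tuple[float, float] = (1e-5, 1e-1)  # h^-1, log-uniform

    def __post_init__(self):
        lo, hi = self.rate_bounds
        if not (0 < lo < hi):
            raise ConfigError(f"infeasible rate bounds {self.rate_bounds}")
        if self.population_size < 2 or self.generations < 0:
            raise ConfigError("population_size must be >= 2 and generations >= 0")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ConfigError("elitism must be in [0, population_size)")


# ---------------------------------------------------------------------------
# genome <-> parameters
#
# 13 genes in [0,1]: genes 0-9 are rates on a log10 scale between the rate
# bounds (div_first, div_last, sen_first, sen_last, arr_first, arr_last,
# apo_first, apo_last, m_GS, m_AD); genes 10-12 are the staining fractions.
N_GENES = 13
GENE_NAMES = (
    "mP0P1", "mPN1PN", "mP0S", "mPN1S", "mP0G", "mPN1G", "mP0A", "mPN1A",
    "mGS", "mAD", "PgH2AX", "GKi67", "GgH2AX",
)


def decode(
    x: np.ndarray, n_ages: int = 50, rate_bounds: tuple[float, float] = (1e-5, 1e-1)
) -> tuple[ModelParameters, MarkerParams]:
    """Map a unit genome to model and marker parameters."""
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    lo, hi = np.log10(rate_bounds[0]), np.log10(rate_bounds[1])
    r = 10.0 ** (lo + x[:10] * (hi - lo))
    params = ModelParameters.from_endpoints(
        div=(r[0], r[1]), sen=(r[2], r[3]), arr=(r[4], r[5]), apo=(r[6], r[7]),
        m_GS=r[8], m_AD=r[9], n_ages=n_ages,
    )
    mparams = MarkerParams(frac_P_gH2AX=x[10], frac_G_Ki67=x[11], frac_G_gH2AX=x[12])
    return params, mparams


def encode(
    params: ModelParameters,
    mparams: MarkerParams,
    rate_bounds: tuple[float, float] = (1e-5, 1e-1),
) -> np.ndarray:
    """Inverse of :func:`decode` (rates clipped into the bounds)."""
    ep = params.endpoints()
    rates = np.array(
        [*ep["div"], *ep["sen"], *ep["arr"], *ep["apo"], params.m_GS, params.m_AD]
    )
    lo, hi = np.log10(rate_bounds[0]), np.log10(rate_bounds[1])
    rates = np.clip(rates, rate_bounds[0], rate_bounds[1])
    x = np.empty(N_GENES)
    x[:10] = (np.log10(rates) - lo) / (hi - lo)
    x[10:] = [mparams.frac_P_gH2AX, mparams.frac_G_Ki67, mparams.frac_G_gH2AX]
    return np.clip(x, 0.0, 1.0)


# ---------------------------------------------------------------------------
# cost


class _CostEvaluator:
    """Precompiled view of a dataset for repeated cost evaluation.

    Groups records by marker, resolves the time grid once, and caches the
    per-marker observed ranges and the PD alignment.
    """

    def __init__(self, dataset: Dataset, spec: CostSpec):
        self.spec = spec
        df = dataset.frame
        times = np.sort(df["time_h"].unique())
        self.sim_times = times if times[0] == 0.0 else np.concatenate([[0.0], times])
        t_index = {t: i for i, t in enumerate(self.sim_times)}
        self.groups = []  # (marker, row time indices, obs values, range, weight)
        for marker in MARKERS:
            sub = df[df["marker"] == marker]
            if len(sub) == 0:
                continue
            obs = sub["value"].to_numpy(dtype=float)
            idx = np.array([t_index[t] for t in sub["time_h"]], dtype=int)
            if marker == "PD" and spec.pd_offset_mode == "subtract-first":
                t0 = sub["time_h"].min()
                obs = obs - sub.loc[sub["time_h"] == t0, "value"].mean()
            rng = float(obs.max() - obs.min())
            if rng <= 0:
                rng = 1.0
            self.groups.append((marker, idx, obs, rng, spec.weight(marker)))
        if not self.groups:
            raise DataError("dataset is empty")

    def __call__(self, params: ModelParameters, mparams: MarkerParams) -> float:
        traj = simulate(
            params, t_end=float(self.sim_times[-1]), output_times=self.sim_times, method="expm"
        )
        series = marker_readouts(traj, mparams)
        total = 0.0
        for marker, idx, obs, rng, w in self.groups:
            pred = series.value(marker)[idx]
            resid = pred - obs
            if marker == "PD" and self.spec.pd_offset_mode == "free-offset":
                resid = resid - resid.mean()
            total += w * float(np.mean((resid / rng) ** 2))
        return total

    def variance(self) -> float:
        """Cost of the per-marker-mean predictor, in cost units.

        The natural scale against which a fitted cost is judged: a fit with
        ``cost / variance`` near zero explains essentially all marker
        variation.
        """
        total = 0.0
        for _marker, _idx, obs, rng, w in self.groups:
            total += w * float(np.var(obs) / rng**2)
        return total


def cost(
    params: ModelParameters,
    mparams: MarkerParams,
    dataset: Dataset,
    spec: CostSpec | None = None,
) -> float:
    """Range-normalised weighted MSE between model readouts and the data."""
    return _CostEvaluator(dataset, spec or CostSpec())(params, mparams)


def baseline_variance(dataset: Dataset, spec: CostSpec | None = None) -> float:
    """Marker variance on the cost scale (see ``_CostEvaluator.variance``)."""
    return _CostEvaluator(dataset, spec or CostSpec()).variance()


# ---------------------------------------------------------------------------
# optimisation


@dataclass
class FitResult:
    """Outcome of a search step (GA or gradient refinement)."""

    params: ModelParameters
    mparams: MarkerParams
    cost: float
    genome: np.ndarray
    seed: int | None = None
    generations: int = 0
    history: list = field(default_factory=list)  # best cost per generation
    ga_config: GAConfig | None = None
    top_genomes: np.ndarray | None = None
    refine_iterations: int = 0
    gradient_norm: float | None = None
    refine_warning: str | None = None


def _prepare_initial(initial, rate_bounds) -> np.ndarray | None:
    if initial is None:
        return None
    if isinstance(initial, FitResult):
        return initial.genome
    if isinstance(initial, tuple) and len(initial) == 2:
        return encode(initial[0], initial[1], rate_bounds)
    return np.clip(np.asarray(initial, dtype=float), 0.0, 1.0)


def fit_ga(
    dataset: Dataset,
    spec: CostSpec | None = None,
    ga_config: GAConfig | None = None,
    seed: int = 0,
    n_ages: int = 50,
    initial: "FitResult | tuple[ModelParameters, MarkerParams] | np.ndarray | None" = None,
) -> FitResult:
    """Genetic-algorithm search for the 13 tunable parameters.

    Tournament selection, uniform crossover, per-gene Gaussian mutation and
    elitism over a fixed-size population of unit genomes. Deterministic for
    a fixed ``seed``. An optional ``initial`` candidate (a previous fit, a
    parameter pair, or a raw genome) is injected into the starting
    population — used to warm-start the refits inside the design and
    sensitivity loops.
    """
    spec = spec or CostSpec()
    cfg = ga_config or GAConfig()
    evaluator = _CostEvaluator(dataset, spec)
    rng = np.random.default_rng(seed)

    pop = rng.random((cfg.population_size, N_GENES))
    warm = _prepare_initial(initial, cfg.rate_bounds)
    if warm is not None:
        pop[0] = warm
    fitness = np.array([evaluator(*decode(x, n_ages, cfg.rate_bounds)) for x in pop])
    history = [float(fitness.min())]

    for _gen in range(cfg.generations):
        order = np.argsort(fitness)
        new_pop = [pop[i].copy() for i in order[: cfg.elitism]]
        while len(new_pop) < cfg.population_size:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population_size, size=cfg.tournament_size)
                parents.append(pop[contenders[np.argmin(fitness[contenders])]])
            child = parents[0].copy()
            if rng.random() < cfg.crossover_prob:
                take = rng.random(N_GENES) < 0.5
                child[take] = parents[1][take]
            mutate = rng.random(N_GENES) < cfg.mutation_prob
            child[mutate] += rng.normal(0.0, cfg.mutation_sigma, size=int(mutate.sum()))
            new_pop.append(np.clip(child, 0.0, 1.0))
        pop = np.array(new_pop)
        fitness = np.array([evaluator(*decode(x, n_ages, cfg.rate_bounds)) for x in pop])
        history.append(float(fitness.min()))

    order = np.argsort(fitness)
    best = pop[order[0]]
    params, mparams = decode(best, n_ages, cfg.rate_bounds)
    n_top = min(5, cfg.population_size)
    return FitResult(
        params=params,
        mparams=mparams,
        cost=float(fitness[order[0]]),
        genome=best.copy(),
        seed=seed,
        generations=cfg.generations,
        history=history,
        ga_config=cfg,
        top_genomes=pop[order[:n_top]].copy(),
    )


def refine_gradient(
    start: FitResult,
    dataset: Dataset,
    spec: CostSpec | None = None,
    maxiter: int = 500,
    gtol: float = 1e-8,
) -> FitResult:
    """Box-constrained quasi-Newton polish of a search result.

    Minimises the cost over the unit genome with L-BFGS-B and central
    (3-point) finite-difference gradients; bounds are never violated. The
    projected-gradient norm at termination is reported as the local-minimum
    check. If the line search fails to improve on ``start``, the start is
    returned unchanged with a warning flag.
    """
    spec = spec or CostSpec()
    cfg = start.ga_config or GAConfig()
    n_ages = start.params.n_ages
    evaluator = _CostEvaluator(dataset, spec)

    def objective(x):
        return evaluator(*decode(x, n_ages, cfg.rate_bounds))

    res = minimize(
        objective,
        np.clip(start.genome, 0.0, 1.0),
        method="L-BFGS-B",
        jac="3-point",
        bounds=[(0.0, 1.0)] * N_GENES,
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-15},
    )
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else None
    if not np.isfinite(res.fun) or res.fun > start.cost:
        return FitResult(
            params=start.params,
            mparams=start.mparams,
            cost=start.cost,
            genome=start.genome.copy(),
            seed=start.seed,
            generations=start.generations,
            history=list(start.history),
            ga_config=cfg,
            refine_iterations=int(res.nit),
            gradient_norm=grad_norm,
            refine_warning=f"refinement did not improve the cost ({res.message})",
        )
    genome = np.clip(res.x, 0.0, 1.0)
    params, mparams = decode(genome, n_ages, cfg.rate_bounds)
    return FitResult(
        params=params,
        mparams=mparams,
        cost=float(res.fun),
        genome=genome,
        seed=start.seed,
        generations=start.generations,
        history=list(start.history),
        ga_config=cfg,
        refine_iterations=int(res.nit),
        gradient_norm=grad_norm,
    )


@dataclass
class HoldoutReport:
    """Distribution of full-data error increases under random record removal."""

    increases: np.ndarray  # relative cost increase per repetition
    baseline_cost: float
    holdout_fraction: float
    n_removed: int
    seed: int

    @property
    def median(self) -> float:
        return float(np.median(self.increases))


def holdout_analysis(
    dataset: Dataset,
    holdout_fraction: float,
    reps: int,
    seed: int,
    spec: CostSpec | None = None,
    baseline: FitResult | None = None,
    ga_config: GAConfig | None = None,
    refine: bool = True,
) -> HoldoutReport:
    """Refit stability under random removal of a fraction of the records.

    Per repetition: remove ``round(fraction * n)`` records uniformly at
    random, refit (warm-started from the baseline fit), evaluate the refit's
    cost on the *full* dataset and report the relative increase over the
    baseline cost. Partitions depend only on ``seed``.
    """
    if not (0 < holdout_fraction < 1):
        raise ConfigError(f"holdout_fraction must be in (0, 1), got {holdout_fraction}")
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    spec = spec or CostSpec()
    cfg = ga_config or GAConfig()
    n = len(dataset)
    n_remove = int(round(holdout_fraction * n))

    rng = np.random.default_rng(seed)
    partitions = [rng.choice(n, size=n_remove, replace=False) for _ in range(reps)]
    child_seeds = rng.integers(0, 2**31 - 1, size=reps)

    if baseline is None:
        baseline = fit_ga(dataset, spec, cfg, seed=int(rng.integers(0, 2**31 - 1)))
        if refine:
            baseline = refine_gradient(baseline, dataset, spec)
    evaluator = _CostEvaluator(dataset, spec)
    base_cost = evaluator(baseline.params, baseline.mparams)
    # Denominator floor: on noiseless self-consistent data the baseline cost
    # is numerically zero and a raw ratio would amplify solver round-off.
    denom = max(base_cost, 1e-6 * evaluator.variance())

    increases = np.empty(reps)
    for r in range(reps):
        reduced = dataset.drop_rows(partitions[r])
        refit = fit_ga(
            reduced, spec, cfg, seed=int(child_seeds[r]),
            n_ages=baseline.params.n_ages, initial=baseline,
        )
        if refine:
            refit = refine_gradient(refit, reduced, spec)
        full_cost = evaluator(refit.params, refit.mparams)
        increases[r] = (full_cost - base_cost) / denom
    return HoldoutReport(
        increases=increases,
        baseline_cost=float(base_cost),
        holdout_fraction=holdout_fraction,
        n_removed=n_remove,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# model / results front door


class SenescenceMarkerModel:
    """Compartment senescence model bound to a marker dataset.

    Parameters
    ----------
    dataset : Dataset
        Observed marker records (the fitting target).
    cost_spec : CostSpec, optional
        Discrepancy weights and PD alignment.
    n_ages : int
        Number of proliferative doubling-age classes (division limit N).
    """

    def __init__(self, dataset: Dataset, cost_spec: CostSpec | None = None, n_ages: int = 50):
        self.dataset = dataset
        self.cost_spec = cost_spec or CostSpec()
        self.n_ages = n_ages
        self._evaluator = _CostEvaluator(dataset, self.cost_spec)

    @classmethod
    def from_csv(cls, path, cost_spec: CostSpec | None = None, n_ages: int = 50):
        from .io import read_dataset

        return cls(read_dataset(path), cost_spec=cost_spec, n_ages=n_ages)

    def cost(self, params: ModelParameters, mparams: MarkerParams) -> float:
        return self._evaluator(params, mparams)

    def marker_variance(self) -> float:
        return self._evaluator.variance()

    def fit(
        self,
        seed: int = 0,
        ga_config: GAConfig | None = None,
        refine: bool = True,
        n_refine: int = 2,
        initial=None,
    ) -> "SenescenceFit":
        """GA search followed by gradient polish of the top candidates."""
        cfg = ga_config or GAConfig()
        ga = fit_ga(self.dataset, self.cost_spec, cfg, seed=seed, n_ages=self.n_ages,
                    initial=initial)
        best = ga
        if refine:
            candidates = ga.top_genomes[: max(1, n_refine)]
            for genome in candidates:
                params, mparams = decode(genome, self.n_ages, cfg.rate_bounds)
                start = FitResult(
                    params=params, mparams=mparams,
                    cost=self._evaluator(params, mparams),
                    genome=np.asarray(genome, dtype=float),
                    seed=seed, generations=ga.generations,
                    history=list(ga.history), ga_config=cfg,
                )
                polished = refine_gradient(start, self.dataset, self.cost_spec)
                if polished.cost < best.cost:
                    best = polished
        return SenescenceFit(self, best)


class SenescenceFit:
    """Results object: fitted parameters, diagnostics, and predictions."""

    def __init__(self, model: SenescenceMarkerModel, result: FitResult):
        self.model = model
        self.result = result

    @property
    def params(self) -> ModelParameters:
        return self.result.params

    @property
    def marker_params(self) -> MarkerParams:
        return self.result.mparams

    @property
    def cost(self) -> float:
        return self.result.cost

    def simulate(self, t_end: float | None = None, output_times=None, method="adaptive"):
        if t_end is None:
            t_end = float(self.model.dataset.times.max())
        return simulate(self.params, t_end=t_end, output_times=output_times, method=method)

    def predict(self, times: Sequence[float] | None = None):
        """Marker readouts at the dataset's times (or a custom grid)."""
        if times is None:
            times = self.model.dataset.times
        t = np.asarray(times, dtype=float)
        grid = t if t[0] == 0.0 else np.concatenate([[0.0], t])
        traj = simulate(self.params, t_end=float(grid[-1]), output_times=grid, method="expm")
        series = marker_readouts(traj, self.marker_params)
        keep = np.isin(traj.times, t)
        from .markers import MarkerSeries

        return MarkerSeries(
            times=series.times[keep],
            pd=series.pd[keep],
            sa_b_gal=series.sa_b_gal[keep],
            ki67=series.ki67[keep],
            gH2AX=series.gH2AX[keep],
            tunel=series.tunel[keep],
        )

    def holdout(self, holdout_fraction: float = 0.2, reps: int = 10, seed: int = 0,
                ga_config: GAConfig | None = None, refine: bool = True) -> HoldoutReport:
        return holdout_analysis(
            self.model.dataset, holdout_fraction, reps, seed,
            spec=self.model.cost_spec, baseline=self.result,
            ga_config=ga_config or self.result.ga_config, refine=refine,
        )

    def to_dict(self) -> dict:
        """JSON-serialisable record of the fit (parameters, cost, config)."""
        ep = self.params.endpoints()
        cfg = self.result.ga_config
        return {
            "parameters": {
                "mP0P1": ep["div"][0], "mPN1PN": ep["div"][1],
                "mP0S": ep["sen"][0], "mPN1S": ep["sen"][1],
                "mP0G": ep["arr"][0], "mPN1G": ep["arr"][1],
                "mP0A": ep["apo"][0], "mPN1A": ep["apo"][1],
                "mGS": self.params.m_GS, "mAD": self.params.m_AD,
                "N": self.params.n_ages,
                "PgH2AX": self.marker_params.frac_P_gH2AX,
                "GKi67": self.marker_params.frac_G_Ki67,
                "GgH2AX": self.marker_params.frac_G_gH2AX,
            },
            "cost": self.cost,
            "seed": self.result.seed,
            "generations": self.result.generations,
            "refine_iterations": self.result.refine_iterations,
            "gradient_norm": self.result.gradient_norm,
            "refine_warning": self.result.refine_warning,
            "ga_config": asdict(cfg) if cfg else None,
        }

    def save(self, path) -> None:
        from . import __version__

        record = self.to_dict()
        record["software_version"] = __version__
        with open(path, "w") as fh:
            json.dump(record, fh, indent=2)

    def summary(self) -> str:
        """Plain-text summary table of the 13 estimates and fit diagnostics."""
        d = self.to_dict()
        p = d["parameters"]
        lines = [
            "Senescence marker model fit",
            "=" * 46,
            f"{'records':<28}{len(self.model.dataset):>18}",
            f"{'age classes (N)':<28}{p['N']:>18}",
            f"{'cost (range-norm. MSE)':<28}{d['cost']:>18.6g}",
            f"{'GA generations':<28}{d['generations']:>18}",
            f"{'refine iterations':<28}{d['refine_iterations']:>18}",
            f"{'gradient norm':<28}" + (
                f"{d['gradient_norm']:>18.3g}" if d["gradient_norm"] is not None else f"{'n/a':>18}"
            ),
            f"{'seed':<28}{str(d['seed']):>18}",
            "-" * 46,
            f"{'parameter':<16}{'estimate':>14}  {'units':<12}",
            "-" * 46,
        ]
        units = {k: "h^-1" for k in GENE_NAMES[:10]}
        units.update({k: "fraction" for k in GENE_NAMES[10:]})
        for k in GENE_NAMES:
            lines.append(f"{k:<16}{p[k]:>14.6g}  {units[k]:<12}")
        lines.append("=" * 46)
        if d["refine_warning"]:
            lines.append(f"warning: {d['refine_warning']}")
        return "\n".join(lines)
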