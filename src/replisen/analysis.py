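"""Downstream analyses: sparse-measurement design, parameter sensitivity,
and landmark times of the senescence time-course.

*Design strategies* quantify the information lost by collecting fewer
passages: the model is refitted on a reduced dataset and the refit is scored
on the **full** dataset, so the reported percentage measures how much the
omitted measurements were worth (scoring on the reduced data would instead
reward overfitting the points that remain).

*Sensitivity maps* perturb one ladder-endpoint pair (2-D grids) or one
scalar parameter (1-D scans) around a fitted optimum, holding everything
else fixed, and record the cost increase. Both raw costs and percentage
increases are reported: on noiseless self-consistent data the baseline cost
is zero and a percentage is degenerate (0 at the optimum, infinite
elsewhere), so comparisons there should use the raw cost surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset
from .errors import DataError, NoPeakError, ParameterError, ThresholdNotReachedError
from .fitting import (
    CostSpec,
    FitResult,
    GAConfig,
    _CostEvaluator,
    fit_ga,
    refine_gradient,
)
from .markers import MarkerParams
from .model import ModelParameters, Trajectory, simulate

__all__ = [
    "DesignStrategy",
    "apply_strategy",
    "design_strategy_error",
    "SensitivityGridResult",
    "SensitivityScanResult",
    "sensitivity_grid",
    "sensitivity_scan",
    "peak_growth_arrest_time",
    "time_to_senescence_fraction",
]

_KINDS = ("drop-first", "drop-last", "skip", "drop-middle-block")


@dataclass(frozen=True)
class DesignStrategy:
    """A rule for measuring fewer passages.

    kind : {"drop-first", "drop-last", "skip", "drop-middle-block"}
        drop-first/drop-last remove the k earliest/latest passages;
        skip with stride k retains every (k+1)-th passage starting from the
        first; drop-middle-block removes k consecutive passages centred on
        the design midpoint.
    k : int
        Points removed, or the skip stride.
    """

    kind: str
    k: int

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ParameterError(f"strategy kind must be one of {_KINDS}")
        if self.k < 0:
            raise ParameterError(f"k must be non-negative, got {self.k}")


def apply_strategy(dataset: Dataset, strategy: DesignStrategy) -> Dataset:
    """Reduce a dataset according to a design strategy (replicates follow
    their passage)."""
    passages = dataset.passages
    n = passages.size
    k = strategy.k
    if k == 0:
        return dataset
    if strategy.kind == "drop-first":
        keep = passages[k:]
    elif strategy.kind == "drop-last":
        keep = passages[:-k] if k < n else passages[:0]
    elif strategy.kind == "skip":
        keep = passages[:: k + 1]
    else:  # drop-middle-block
        if k >= n:
            raise DataError(f"cannot drop a block of {k} from {n} passages")
        start = (n - k) // 2
        keep = np.concatenate([passages[:start], passages[start + k:]])
    if keep.size < 2:
        raise DataError(
            f"strategy {strategy.kind} k={k} leaves {keep.size} passages; at least 2 required"
        )
    return dataset.subset_passages(keep)


def design_strategy_error(
    dataset: Dataset,
    strategy: DesignStrategy,
    spec: CostSpec | None = None,
    seed: int = 0,
    baseline: FitResult | None = None,
    ga_config: GAConfig | None = None,
    refine: bool = True,
    warm_start: bool = True,
) -> float:
    """Percent increase in full-data error when fitting to a reduced design.

    Refits the model on the reduced dataset, scores the refit on the full
    dataset, and reports ``100 * (cost_reduced_fit - cost_full_fit) /
    cost_full_fit``. The baseline full-data fit can be passed in (and is
    reused as the refit's warm start unless ``warm_start=False``).
    """
    spec = spec or CostSpec()
    cfg = ga_config or GAConfig()
    rng = np.random.default_rng(seed)
    base_seed, refit_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))

    if baseline is None:
        baseline = fit_ga(dataset, spec, cfg, seed=base_seed)
        if refine:
            baseline = refine_gradient(baseline, dataset, spec)
    evaluator = _CostEvaluator(dataset, spec)
    base_cost = evaluator(baseline.params, baseline.mparams)

    if strategy.k == 0:
        return 0.0
    reduced = apply_strategy(dataset, strategy)
    refit = fit_ga(
        reduced, spec, cfg, seed=refit_seed, n_ages=baseline.params.n_ages,
        initial=baseline if warm_start else None,
    )
    if refine:
        refit = refine_gradient(refit, reduced, spec)
    full_cost = evaluator(refit.params, refit.mparams)
    # Denominator floor guards the noiseless self-consistent regime, where
    # the baseline cost is numerically zero and a raw ratio would amplify
    # solver round-off into meaningless percentages.
    denom = max(base_cost, 1e-6 * evaluator.variance())
    return 100.0 * (full_cost - base_cost) / denom


# ---------------------------------------------------------------------------
# sensitivity


@dataclass
class SensitivityGridResult:
    """Cost surface over one ladder's (first, last) endpoint pair."""

    ladder: str
    first_values: np.ndarray  # grid along the age-0 endpoint (x axis)
    last_values: np.ndarray  # grid along the oldest-age endpoint (y axis)
    cost: np.ndarray  # shape (len(last_values), len(first_values))
    percent_increase: np.ndarray
    baseline_cost: float

    @property
    def argmin(self) -> tuple[float, float]:
        """(first, last) endpoint pair with the lowest cost on the grid."""
        iy, ix = np.unravel_index(np.nanargmin(self.cost), self.cost.shape)
        return float(self.first_values[ix]), float(self.last_values[iy])

    def to_frame(self):
        import pandas as pd

        rows = []
        for iy, last in enumerate(self.last_values):
            for ix, first in enumerate(self.first_values):
                rows.append((first, last, self.cost[iy, ix], self.percent_increase[iy, ix]))
        return pd.DataFrame(rows, columns=["first_rate", "last_rate", "cost", "percent_increase"])


@dataclass
class SensitivityScanResult:
    """1-D cost curve over one scalar parameter."""

    name: str
    values: np.ndarray
    cost: np.ndarray
    percent_increase: np.ndarray
    baseline_cost: float

    @property
    def argmin(self) -> float:
        return float(self.values[np.nanargmin(self.cost)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "value": self.values,
                "cost": self.cost,
                "percent_increase": self.percent_increase,
            }
        )


def _percent(costs: np.ndarray, base: float) -> np.ndarray:
    if base > 0:
        return 100.0 * (costs - base) / base
    out = np.full_like(costs, np.inf, dtype=float)
    out[np.isclose(costs, 0.0, atol=1e-15)] = 0.0
    return out


def _grid(optimum: float, n: int, span: float = 4.0) -> np.ndarray:
    """Log-spaced grid spanning [optimum/span, optimum*span]."""
    if optimum <= 0:
        raise ParameterError("grid construction needs a positive optimised value")
    return np.geomspace(optimum / span, optimum * span, n)


def sensitivity_grid(
    params: ModelParameters,
    mparams: MarkerParams,
    dataset: Dataset,
    ladder: str,
    first_values: np.ndarray | None = None,
    last_values: np.ndarray | None = None,
    spec: CostSpec | None = None,
    n_grid: int = 41,
) -> SensitivityGridResult:
    """Cost over a 2-D grid of one ladder's endpoints, all else fixed.

    Defaults to a 41x41 log-spaced grid spanning 1/4x to 4x the fitted
    endpoints. The grid diagonal (first == last) corresponds to an
    age-independent flat ladder. Simulation failures at extreme rates are
    recorded as NaN cells rather than raised.
    """
    ep = params.endpoints()
    if ladder not in ep:
        raise ParameterError(f"unknown ladder {ladder!r}; expected one of {list(ep)}")
    if first_values is None:
        first_values = _grid(ep[ladder][0], n_grid)
    if last_values is None:
        last_values = _grid(ep[ladder][1], n_grid)
    first_values = np.asarray(first_values, dtype=float)
    last_values = np.asarray(last_values, dtype=float)
    evaluator = _CostEvaluator(dataset, spec or CostSpec())
    base = evaluator(params, mparams)

    costs = np.empty((last_values.size, first_values.size))
    for iy, last in enumerate(last_values):
        for ix, first in enumerate(first_values):
            try:
                costs[iy, ix] = evaluator(params.replace_ladder(ladder, first, last), mparams)
            except Exception:
                costs[iy, ix] = np.nan
    return SensitivityGridResult(
        ladder=ladder,
        first_values=first_values,
        last_values=last_values,
        cost=costs,
        percent_increase=_percent(costs, base),
        baseline_cost=base,
    )


_SCAN_SCALARS = ("m_GS", "m_AD", "frac_P_gH2AX", "frac_G_Ki67", "frac_G_gH2AX")


def sensitivity_scan(
    params: ModelParameters,
    mparams: MarkerParams,
    dataset: Dataset,
    param_name: str,
    values: np.ndarray | None = None,
    spec: CostSpec | None = None,
    n_grid: int = 101,
) -> SensitivityScanResult:
    """1-D cost curve over one scalar rate or staining fraction."""
    if param_name not in _SCAN_SCALARS:
        raise ParameterError(f"param_name must be one of {_SCAN_SCALARS}")
    if values is None:
        if param_name in ("m_GS", "m_AD"):
            values = _grid(getattr(params, param_name), n_grid)
        else:
            values = np.linspace(0.0, 1.0, n_grid)
    values = np.asarray(values, dtype=float)
    evaluator = _CostEvaluator(dataset, spec or CostSpec())
    base = evaluator(params, mparams)

    costs = np.empty(values.size)
    for i, v in enumerate(values):
        try:
            if param_name in ("m_GS", "m_AD"):
                costs[i] = evaluator(params.replace_scalar(param_name, v), mparams)
            else:
                kw = {
                    "frac_P_gH2AX": mparams.frac_P_gH2AX,
                    "frac_G_Ki67": mparams.frac_G_Ki67,
                    "frac_G_gH2AX": mparams.frac_G_gH2AX,
                }
                kw[param_name] = v
                costs[i] = evaluator(params, MarkerParams(**kw))
        except Exception:
            costs[i] = np.nan
    return SensitivityScanResult(
        name=param_name,
        values=values,
        cost=costs,
        percent_increase=_percent(costs, base),
        baseline_cost=base,
    )


# ---------------------------------------------------------------------------
# landmark times


def peak_growth_arrest_time(trajectory: Trajectory) -> float:
    """Time (hours) maximising the growth-arrested fraction G/TP.

    The discrete argmax over the trajectory's output grid is sharpened by
    fitting a quadratic through the three points around it. Raises
    :class:`NoPeakError` when the maximum sits on the window boundary (the
    fraction is monotone over the window, so no interior peak exists).
    """
    frac = trajectory.G / trajectory.TP
    i = int(np.argmax(frac))
    if i == 0 or i == frac.size - 1:
        raise NoPeakError(
            "growth-arrested fraction has no interior maximum in the simulated window"
        )
    t0, t1, t2 = trajectory.times[i - 1: i + 2]
    y0, y1, y2 = frac[i - 1: i + 2]
    # vertex of the parabola through the three bracketing points
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (y1 - y0) + t1 * (y0 - y2) + t0 * (y2 - y1)) / denom
    b = (t2**2 * (y0 - y1) + t1**2 * (y2 - y0) + t0**2 * (y1 - y2)) / denom
    if a >= 0:  # degenerate (flat or convex); fall back to the grid argmax
        return float(t1)
    return float(-b / (2 * a))


def time_to_senescence_fraction(
    params: ModelParameters,
    threshold: float,
    horizon: float = 10000.0,
    initial=None,
) -> float:
    """First time at which the senescent fraction S/TP reaches ``threshold``.

    Integrates with dense output and refines the first crossing by
    bisection. Raises :class:`ThresholdNotReachedError` (carrying the final
    fraction) if the threshold is not attained within the horizon.
    """
    if not (0 <= threshold < 1):
        raise ParameterError(f"threshold must lie in [0, 1), got {threshold}")
    if threshold == 0:
        return 0.0
    traj = simulate(
        params,
        t_end=horizon,
        output_times=np.linspace(0.0, horizon, 2001),
        initial=initial,
        method="adaptive",
    )
    n = params.n_ages
    frac = traj.S / traj.TP
    above = np.nonzero(frac >= threshold)[0]
    if above.size == 0:
        raise ThresholdNotReachedError(
            f"senescent fraction reached only {frac[-1]:.4f} (< {threshold}) "
            f"within {horizon} h",
            final_fraction=float(frac[-1]),
        )
    j = int(above[0])
    if j == 0:
        return float(traj.times[0])

    def s_frac(t: float) -> float:
        x = traj.dense(t)
        tp = x[:n].sum() + x[n] + x[n + 1] + x[n + 2]
        return x[n + 2] / tp - threshold

    from scipy.optimize import brentq

    lo, hi = float(traj.times[j - 1]), float(traj.times[j])
    if s_frac(lo) >= 0:
        return lo
    return float(brentq(s_frac, lo, hi, xtol=1e-6))
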