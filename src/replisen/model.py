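"""Age-structured compartment model of a culture's transition to senescence.

A proliferating culture is split into subpopulations ``P_0 .. P_{N-1}`` by
*doubling age* — the number of mitoses a cell's lineage has completed. Each
age class can divide (two daughters enter the next class), or jump one-for-one
into the senescent (``S``), growth-arrested (``G``) or apoptotic (``A``)
pools. Division out of the oldest class ``P_{N-1}`` lands in ``S`` (the
Hayflick-like division limit ``N``), growth-arrested cells convert to
senescent at a scalar rate ``m_GS``, and apoptotic cells are cleared into a
dead pool ``D`` at ``m_AD``. Transition rates out of ``P_i`` depend linearly
on the doubling age ``i`` ("rate ladders").

The resulting ODE system is linear and time-invariant, so besides the
adaptive Runge-Kutta path (:func:`simulate`) a matrix-exponential propagator
is available, exact for this system and much faster on coarse output grids.

State vector layout used throughout: ``[P_0 .. P_{N-1}, G, A, S, D]``.
The live total is ``TP = sum(P) + G + A + S``; dead cells are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .errors import IntegrationError, ParameterError

__all__ = [
    "RateLadder",
    "ModelParameters",
    "PopulationState",
    "Trajectory",
    "linear_rate_ladder",
    "transition_matrix",
    "derivative",
    "simulate",
    "population_doublings",
]

#: A rate ladder is a 1-D float array of length N, one rate (per hour) per
#: doubling age, constrained to lie on a straight line over the age index.
RateLadder = np.ndarray


def linear_rate_ladder(m_first: float, m_last: float, n_ages: int) -> RateLadder:
    """Build the linear rate ladder through ``(0, m_first)`` and ``(N-1, m_last)``.

    Parameters
    ----------
    m_first, m_last : float
        Non-negative rates (per hour) at doubling age 0 and ``n_ages - 1``.
    n_ages : int
        Number of proliferative age classes N (>= 2).

    Returns
    -------
    numpy.ndarray
        ``values[i] = m_first + i * (m_last - m_first) / (n_ages - 1)``.
    """
    if n_ages < 2:
        raise ParameterError(f"rate ladder needs at least 2 age classes, got {n_ages}")
    if m_first < 0 or m_last < 0:
        raise ParameterError(
            f"rate ladder endpoints must be non-negative, got ({m_first}, {m_last})"
        )
    i = np.arange(n_ages, dtype=float)
    return m_first + i * (m_last - m_first) / (n_ages - 1)


def _as_ladder(values: Sequence[float] | np.ndarray, n_ages: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size != n_ages:
        raise ParameterError(f"{name} must have length {n_ages}, got shape {arr.shape}")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ParameterError(f"{name} entries must be finite and non-negative")
    return arr


@dataclass(frozen=True)
class ModelParameters:
    """The transition-rate parameterisation of the compartment model.

    Four rate ladders (division, jump-to-senescence, growth arrest,
    apoptosis), two scalar rates and the division limit N. The 13 tunable
    quantities are the four ladder endpoint pairs plus ``m_GS`` and ``m_AD``
    together with the three marker fractions kept in
    :class:`~replisen.markers.MarkerParams`.
    """

    div_ladder: RateLadder
    sen_ladder: RateLadder
    arr_ladder: RateLadder
    apo_ladder: RateLadder
    m_GS: float
    m_AD: float
    n_ages: int = 50

    def __post_init__(self):
        n = self.n_ages
        if n < 1:
            raise ParameterError(f"n_ages must be positive, got {n}")
        for name in ("div_ladder", "sen_ladder", "arr_ladder", "apo_ladder"):
            object.__setattr__(self, name, _as_ladder(getattr(self, name), n, name))
        if self.m_GS < 0 or self.m_AD < 0:
            raise ParameterError("m_GS and m_AD must be non-negative")

    @classmethod
    def from_endpoints(
        cls,
        div: tuple[float, float],
        sen: tuple[float, float],
        arr: tuple[float, float],
        apo: tuple[float, float],
        m_GS: float,
        m_AD: float,
        n_ages: int = 50,
    ) -> "ModelParameters":
        """Construct all four ladders from their (first, last) endpoint pairs."""
        return cls(
            div_ladder=linear_rate_ladder(*div, n_ages),
            sen_ladder=linear_rate_ladder(*sen, n_ages),
            arr_ladder=linear_rate_ladder(*arr, n_ages),
            apo_ladder=linear_rate_ladder(*apo, n_ages),
            m_GS=m_GS,
            m_AD=m_AD,
            n_ages=n_ages,
        )

    def endpoints(self) -> dict[str, tuple[float, float]]:
        """Ladder endpoint pairs keyed by ladder name (div/sen/arr/apo)."""
        return {
            "div": (float(self.div_ladder[0]), float(self.div_ladder[-1])),
            "sen": (float(self.sen_ladder[0]), float(self.sen_ladder[-1])),
            "arr": (float(self.arr_ladder[0]), float(self.arr_ladder[-1])),
            "apo": (float(self.apo_ladder[0]), float(self.apo_ladder[-1])),
        }

    def replace_ladder(self, which: str, m_first: float, m_last: float) -> "ModelParameters":
        """Return a copy with one ladder rebuilt from new endpoints."""
        if which not in ("div", "sen", "arr", "apo"):
            raise ParameterError(f"unknown ladder {which!r}")
        kw = {
            "div_ladder": self.div_ladder,
            "sen_ladder": self.sen_ladder,
            "arr_ladder": self.arr_ladder,
            "apo_ladder": self.apo_ladder,
            "m_GS": self.m_GS,
            "m_AD": self.m_AD,
            "n_ages": self.n_ages,
        }
        kw[which + "_ladder"] = linear_rate_ladder(m_first, m_last, self.n_ages)
        return ModelParameters(**kw)

    def replace_scalar(self, name: str, value: float) -> "ModelParameters":
        if name not in ("m_GS", "m_AD"):
            raise ParameterError(f"unknown scalar rate {name!r}")
        kw = {
            "div_ladder": self.div_ladder,
            "sen_ladder": self.sen_ladder,
            "arr_ladder": self.arr_ladder,
            "apo_ladder": self.apo_ladder,
            "m_GS": self.m_GS,
            "m_AD": self.m_AD,
            "n_ages": self.n_ages,
        }
        kw[name] = value
        return ModelParameters(**kw)


@dataclass
class PopulationState:
    """Compartment contents at one instant.

    ``P`` holds the N proliferative age classes; ``G``, ``A``, ``S`` the
    growth-arrested, apoptotic and senescent pools and ``D`` the dead pool,
    which is excluded from the live total.
    """

    P: np.ndarray
    G: float = 0.0
    A: float = 0.0
    S: float = 0.0
    D: float = 0.0

    def __post_init__(self):
        self.P = np.atleast_1d(np.asarray(self.P, dtype=float))

    @classmethod
    def seed(cls, n_ages: int, total: float = 1.0) -> "PopulationState":
        """All cells in the youngest proliferative class ``P_0``."""
        P = np.zeros(n_ages)
        P[0] = total
        return cls(P=P)

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "PopulationState":
        x = np.asarray(x, dtype=float)
        return cls(P=x[:-4].copy(), G=float(x[-4]), A=float(x[-3]), S=float(x[-2]), D=float(x[-1]))

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.P, [self.G, self.A, self.S, self.D]])

    @property
    def live_total(self) -> float:
        """TP = sum(P) + G + A + S (dead cells excluded)."""
        return float(self.P.sum() + self.G + self.A + self.S)


def transition_matrix(params: ModelParameters) -> np.ndarray:
    """Generator matrix M of the linear system x' = M x.

    Rows/columns follow the ``[P_0..P_{N-1}, G, A, S, D]`` layout. Division
    carries the mitosis factor 2 into the next age class (and into S from the
    oldest class); all other transitions move cells one-for-one.
    """
    n = params.n_ages
    div, sen, arr, apo = (
        params.div_ladder,
        params.sen_ladder,
        params.arr_ladder,
        params.apo_ladder,
    )
    g, a, s, d = n, n + 1, n + 2, n + 3
    M = np.zeros((n + 4, n + 4))
    exit_rates = div + sen + arr + apo
    M[np.arange(n), np.arange(n)] = -exit_rates
    if n > 1:
        M[np.arange(1, n), np.arange(n - 1)] = 2.0 * div[:-1]
    M[g, :n] = arr
    M[a, :n] = apo
    M[s, :n] = sen
    M[s, n - 1] += 2.0 * div[n - 1]
    M[s, g] = params.m_GS
    M[g, g] = -params.m_GS
    M[a, a] = -params.m_AD
    M[d, a] = params.m_AD
    return M


def derivative(state: PopulationState, params: ModelParameters) -> PopulationState:
    """Instantaneous rates of change (per hour) at ``state``.

    Implements the transition rules: division moves a cell out of ``P_i`` at
    rate ``div[i]`` and puts two daughters into ``P_{i+1}`` (into ``S`` for
    ``i = N-1``); jumps into ``S``/``G``/``A`` move one-for-one at the
    ladder rates; ``G -> S`` at ``m_GS``; ``A -> D`` at ``m_AD``.
    """
    if state.P.size != params.n_ages:
        raise ParameterError(
            f"state has {state.P.size} age classes but parameters have {params.n_ages}"
        )
    rates = transition_matrix(params) @ state.to_vector()
    return PopulationState.from_vector(rates)


@dataclass
class Trajectory:
    """Time-indexed solution of the compartment model.

    ``states`` is an ``(n_times, N+4)`` matrix in the standard layout.
    ``dense`` (when available) is the solver's dense-output interpolant,
    usable for root finding between output times.
    """

    times: np.ndarray
    states: np.ndarray
    n_ages: int
    dense: Callable[[float], np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or self.states.shape != (self.times.size, self.n_ages + 4):
            raise ParameterError("trajectory times/states shape mismatch")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ParameterError("trajectory times must be strictly increasing")

    @property
    def P(self) -> np.ndarray:
        return self.states[:, : self.n_ages]

    @property
    def P_total(self) -> np.ndarray:
        return self.P.sum(axis=1)

    @property
    def G(self) -> np.ndarray:
        return self.states[:, self.n_ages]

    @property
    def A(self) -> np.ndarray:
        return self.states[:, self.n_ages + 1]

    @property
    def S(self) -> np.ndarray:
        return self.states[:, self.n_ages + 2]

    @property
    def D(self) -> np.ndarray:
        return self.states[:, self.n_ages + 3]

    @property
    def TP(self) -> np.ndarray:
        """Live total per time point; dead pool excluded."""
        return self.P_total + self.G + self.A + self.S

    def state(self, i: int) -> PopulationState:
        return PopulationState.from_vector(self.states[i])

    def to_frame(self):
        """Summary table: time_h, P_total, G, A, S, D, TP, PD."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.times,
                "P_total": self.P_total,
                "G": self.G,
                "A": self.A,
                "S": self.S,
                "D": self.D,
                "TP": self.TP,
                "PD": population_doublings(self),
            }
        )


def simulate(
    params: ModelParameters,
    t_end: float,
    output_times: Sequence[float] | np.ndarray | None = None,
    initial: PopulationState | None = None,
    method: str = "adaptive",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the compartment model from ``t=0`` to ``t_end``.

    Parameters
    ----------
    params : ModelParameters
    t_end : float
        End of the integration window (hours), > 0.
    output_times : array-like, optional
        Instants (within ``[0, t_end]``) at which the state is reported.
        Defaults to 1001 equispaced points.
    initial : PopulationState, optional
        Defaults to a unit seed population entirely in ``P_0``.
    method : {"adaptive", "expm"}
        ``"adaptive"`` uses an adaptive explicit Runge-Kutta pair with dense
        output; ``"expm"`` propagates with the matrix exponential, which is
        exact for this linear system (no dense interpolant is attached).
    rtol, atol : float
        Adaptive solver tolerances.
    """
    if t_end <= 0:
        raise ParameterError(f"t_end must be positive, got {t_end}")
    if output_times is None:
        output_times = np.linspace(0.0, t_end, 1001)
    t_out = np.asarray(output_times, dtype=float)
    if t_out.ndim != 1 or t_out.size == 0:
        raise ParameterError("output_times must be a non-empty 1-D sequence")
    if np.any(t_out < 0) or np.any(t_out > t_end * (1 + 1e-12)):
        raise ParameterError("output_times must lie within [0, t_end]")
    if np.any(np.diff(t_out) <= 0):
        raise ParameterError("output_times must be strictly increasing")

    if initial is None:
        initial = PopulationState.seed(params.n_ages)
    x0 = initial.to_vector()
    if x0.size != params.n_ages + 4:
        raise ParameterError("initial state does not match n_ages")

    M = transition_matrix(params)

    if method == "expm":
        states = np.empty((t_out.size, x0.size))
        x = x0
        t_prev = 0.0
        cache: dict[float, np.ndarray] = {}
        for k, t in enumerate(t_out):
            dt = t - t_prev
            if dt > 0:
                key = round(dt, 12)
                if key not in cache:
                    cache[key] = expm(M * dt)
                x = cache[key] @ x
            t_prev = t
            states[k] = x
        if not np.all(np.isfinite(states)):
            bad = int(np.argmax(~np.isfinite(states).all(axis=1)))
            raise IntegrationError(
                f"non-finite state at t={t_out[bad]:.6g} h", time=float(t_out[bad])
            )
        return Trajectory(times=t_out, states=states, n_ages=params.n_ages)

    if method != "adaptive":
        raise ParameterError(f"unknown integration method {method!r}")

    sol = solve_ivp(
        lambda t, x: M @ x,
        (0.0, float(t_end)),
        x0,
        method="RK45",
        t_eval=t_out,
        dense_output=True,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"integration failed near t={t_fail:.6g} h: {sol.message}", time=t_fail)
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        bad = int(np.argmax(~np.isfinite(states).all(axis=1)))
        raise IntegrationError(f"non-finite state at t={t_out[bad]:.6g} h", time=float(t_out[bad]))
    return Trajectory(times=t_out, states=states, n_ages=params.n_ages, dense=sol.sol)


def population_doublings(trajectory: Trajectory) -> np.ndarray:
    """Cumulative population doublings PD(t) = log2(TP(t) / TP(0)).

    Computed on the live total (dead pool excluded); PD(0) = 0.
    """
    tp = trajectory.TP
    if tp[0] <= 0:
        raise ParameterError("population doublings undefined: initial live total is zero")
    return np.log2(tp / tp[0])
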