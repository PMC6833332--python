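"""Synthetic marker datasets with the replicative life-course study design.

The generator emulates the structure of the fibroblast experiment the model
was built for: 16 passages sampled from p5 to p20 over roughly 2400 h of
continuous culture, five markers per passage, triplicate measurements, and
PD reported cumulatively from the seed stock (so the first sampled passage
already sits at PD 5). Measurement noise is additive Gaussian per replicate,
truncated to the physical range of each channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MARKERS, PERCENT_MARKERS, Dataset
from .errors import ParameterError
from .markers import MarkerParams, marker_readouts
from .model import ModelParameters, simulate

__all__ = ["DesignSpec", "generate_dataset", "DEFAULT_NOISE"]

#: Default replicate noise: 3 percentage points for the stains (plausible
#: microscopy counting noise at ~300 cells per field) and 0.2 doublings for PD.
DEFAULT_NOISE = {
    "SA-b-Gal": 3.0,
    "Ki-67": 3.0,
    "gH2AX": 3.0,
    "TUNEL": 3.0,
    "PD": 0.2,
}


def _default_times() -> np.ndarray:
    return np.arange(16, dtype=float) * 160.0


@dataclass
class DesignSpec:
    """Sampling design of a synthetic experiment.

    passage_times : hours of each sampled passage (default 16 points,
        0-2400 h at 160 h spacing, i.e. the p5-p20 span).
    first_passage : passage number of the first sample (default 5).
    replicates : measurements per (passage, marker) (default 3).
    noise : per-marker replicate standard deviation (percentage points for
        the stains, doublings for PD).
    pd_offset : doublings already accumulated before the first sample
        (default 5.0, mimicking a culture sampled from passage 5 onwards).
    seed : RNG seed for the noise draws.
    """

    passage_times: np.ndarray = field(default_factory=_default_times)
    first_passage: int = 5
    replicates: int = 3
    noise: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    pd_offset: float = 5.0
    seed: int = 0

    def __post_init__(self):
        self.passage_times = np.asarray(self.passage_times, dtype=float)
        if self.passage_times.ndim != 1 or self.passage_times.size < 2:
            raise ParameterError("passage_times must be a 1-D sequence of >= 2 times")
        if np.any(np.diff(self.passage_times) <= 0):
            raise ParameterError("passage_times must be strictly increasing")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        for m in MARKERS:
            self.noise.setdefault(m, 0.0)
            if self.noise[m] < 0:
                raise ParameterError(f"noise sd for {m} must be >= 0")


def generate_dataset(
    params: ModelParameters,
    mparams: MarkerParams,
    design: DesignSpec | None = None,
    seed: int | None = None,
) -> Dataset:
    """Simulate the model and emit a noisy replicated dataset.

    The model is integrated from the seed state, the five readouts are
    evaluated at the passage times, and each replicate receives independent
    Gaussian noise. Percentage channels are truncated to [0, 100] and PD to
    >= 0. Deterministic for a fixed seed (``seed`` overrides
    ``design.seed``).
    """
    if design is None:
        design = DesignSpec()
    rng = np.random.default_rng(design.seed if seed is None else seed)

    t_grid = design.passage_times
    if t_grid[0] > 0:
        t_grid = np.concatenate([[0.0], t_grid])
    traj = simulate(params, t_end=float(t_grid[-1]), output_times=t_grid, method="expm")
    series = marker_readouts(traj, mparams)
    at = np.isin(traj.times, design.passage_times)

    rows = []
    for marker in MARKERS:
        clean = series.value(marker)[at].copy()
        if marker == "PD":
            clean = clean + design.pd_offset
        sd = design.noise[marker]
        for p_idx, (t, mu) in enumerate(zip(design.passage_times, clean)):
            passage = design.first_passage + p_idx
            for rep in range(1, design.replicates + 1):
                v = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                if marker in PERCENT_MARKERS:
                    v = min(max(v, 0.0), 100.0)
                else:
                    v = max(v, 0.0)
                rows.append((t, passage, marker, rep, v))
    frame = pd.DataFrame(rows, columns=["time_h", "passage", "marker", "replicate", "value"])
    return Dataset(frame)
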