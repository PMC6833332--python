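"""Map population trajectories onto the five experimental readouts.

The experiments report the percentage of cells staining positive for
SA-β-Gal, Ki-67, γH2AX and TUNEL, plus cumulative population doublings (PD).
Each stain is a constant mixture of the model's live pools:

* SA-β-Gal is the senescent fraction ``S/TP``;
* TUNEL is the apoptotic fraction ``A/TP``;
* Ki-67 covers all proliferative cells plus a fitted fraction of the
  growth-arrested pool;
* γH2AX covers all senescent and apoptotic cells plus fitted fractions of
  the proliferative and growth-arrested pools.

Dead cells are invisible to every marker (they detach and leave the imaged
field), so all readouts are fractions of the live total ``TP``. Internally
fractions are used; the public series carry percentages (0-100) to match how
the assays are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .model import Trajectory, population_doublings

__all__ = ["MarkerParams", "MarkerSeries", "marker_readouts"]


@dataclass(frozen=True)
class MarkerParams:
    """Fitted staining fractions linking populations to markers.

    frac_P_gH2AX : fraction of proliferative cells staining γH2AX-positive.
    frac_G_Ki67  : fraction of growth-arrested cells staining Ki-67-positive.
    frac_G_gH2AX : fraction of growth-arrested cells staining γH2AX-positive.
    """

    frac_P_gH2AX: float
    frac_G_Ki67: float
    frac_G_gH2AX: float

    def __post_init__(self):
        for name in ("frac_P_gH2AX", "frac_G_Ki67", "frac_G_gH2AX"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class MarkerSeries:
    """Model-predicted readouts on a time grid.

    ``pd`` is in doublings; the four stain channels are percentages in
    [0, 100].
    """

    times: np.ndarray
    pd: np.ndarray
    sa_b_gal: np.ndarray
    ki67: np.ndarray
    gH2AX: np.ndarray
    tunel: np.ndarray

    def value(self, marker: str) -> np.ndarray:
        from .data import MARKER_ATTR

        return getattr(self, MARKER_ATTR[marker])

    def to_frame(self):
        """Long-format table: time_h, marker, value (PD in doublings)."""
        import pandas as pd

        from .data import MARKERS

        rows = []
        for marker in MARKERS:
            vals = self.value(marker)
            for t, v in zip(self.times, vals):
                rows.append((t, marker, v))
        return pd.DataFrame(rows, columns=["time_h", "marker", "value"])


def marker_readouts(trajectory: Trajectory, mparams: MarkerParams) -> MarkerSeries:
    """Evaluate the five readouts along a trajectory.

    Raises
    ------
    DataError
        If the live total is zero at any requested time (the stains are
        fractions of the live population).
    """
    tp = trajectory.TP
    if np.any(tp <= 0):
        bad = float(trajectory.times[int(np.argmax(tp <= 0))])
        raise DataError(f"live total is zero at t={bad:.6g} h; marker fractions undefined")
    p = trajectory.P_total
    g, a, s = trajectory.G, trajectory.A, trajectory.S
    return MarkerSeries(
        times=trajectory.times.copy(),
        pd=population_doublings(trajectory),
        sa_b_gal=100.0 * s / tp,
        tunel=100.0 * a / tp,
        ki67=100.0 * (p + mparams.frac_G_Ki67 * g) / tp,
        gH2AX=100.0 * (s + a + mparams.frac_P_gH2AX * p + mparams.frac_G_gH2AX * g) / tp,
    )
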