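"""Observed marker datasets: the fitting target.

A dataset is a long-format table with one row per (time, passage, marker,
replicate) measurement. Marker names are fixed: ``PD`` (population
doublings), and the four stains ``SA-b-Gal``, ``Ki-67``, ``gH2AX``,
``TUNEL`` (percent positive, 0-100).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["MARKERS", "PERCENT_MARKERS", "MARKER_ATTR", "Dataset"]

MARKERS = ("PD", "SA-b-Gal", "Ki-67", "gH2AX", "TUNEL")
PERCENT_MARKERS = ("SA-b-Gal", "Ki-67", "gH2AX", "TUNEL")

#: attribute name on MarkerSeries for each marker
MARKER_ATTR = {
    "PD": "pd",
    "SA-b-Gal": "sa_b_gal",
    "Ki-67": "ki67",
    "gH2AX": "gH2AX",
    "TUNEL": "tunel",
}

_COLUMNS = ["time_h", "passage", "marker", "replicate", "value"]


class Dataset:
    """Validated collection of marker measurements.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``time_h, passage, marker, replicate, value``. Percentage
        markers must lie in [0, 100] and PD values must be >= 0; every
        marker present needs at least two distinct time points.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise DataError(f"dataset missing columns: {missing}")
        df = frame.loc[:, _COLUMNS].reset_index(drop=True).copy()
        try:
            df["time_h"] = df["time_h"].astype(float)
            df["passage"] = df["passage"].astype(int)
            df["replicate"] = df["replicate"].astype(int)
            df["value"] = df["value"].astype(float)
            df["marker"] = df["marker"].astype(str)
        except (TypeError, ValueError) as exc:
            raise DataError(f"dataset has non-numeric entries: {exc}") from exc
        if len(df) == 0:
            raise DataError("dataset is empty")

        unknown = df.loc[~df["marker"].isin(MARKERS)]
        if len(unknown):
            rows = list(unknown.index[:5] + 1)
            names = sorted(unknown["marker"].unique())
            raise DataError(f"unknown marker names {names} (e.g. data row(s) {rows})")
        if df["value"].isna().any() or not np.all(np.isfinite(df["value"])):
            rows = list(df.index[~np.isfinite(df["value"])][:5] + 1)
            raise DataError(f"non-finite values at data row(s) {rows}")
        pct = df["marker"].isin(PERCENT_MARKERS)
        bad = pct & ((df["value"] < 0) | (df["value"] > 100))
        if bad.any():
            rows = list(df.index[bad][:5] + 1)
            raise DataError(f"percentage marker outside [0, 100] at data row(s) {rows}")
        bad_pd = (df["marker"] == "PD") & (df["value"] < 0)
        if bad_pd.any():
            rows = list(df.index[bad_pd][:5] + 1)
            raise DataError(f"negative PD value at data row(s) {rows}")
        for marker, sub in df.groupby("marker"):
            if sub["time_h"].nunique() < 2:
                raise DataError(f"marker {marker!r} has fewer than 2 distinct time points")
        self._frame = df

    # -- accessors ---------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def markers(self) -> list[str]:
        return [m for m in MARKERS if m in set(self._frame["marker"])]

    @property
    def times(self) -> np.ndarray:
        """Sorted unique measurement times (hours)."""
        return np.sort(self._frame["time_h"].unique())

    @property
    def passages(self) -> np.ndarray:
        return np.sort(self._frame["passage"].unique())

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        a = self._frame.sort_values(_COLUMNS).reset_index(drop=True)
        b = other._frame.sort_values(_COLUMNS).reset_index(drop=True)
        return a.equals(b)

    def n_series(self) -> int:
        """Number of distinct (passage, marker) measurement series."""
        return len(self._frame.groupby(["passage", "marker"]))

    def subset_passages(self, keep: np.ndarray | list[int]) -> "Dataset":
        """Restrict to the given passages (replicate rows follow)."""
        keep = set(int(p) for p in keep)
        sub = self._frame[self._frame["passage"].isin(keep)]
        if len(sub) == 0:
            raise DataError("passage subset leaves an empty dataset")
        return Dataset(sub)

    def drop_rows(self, index: np.ndarray) -> "Dataset":
        """Remove rows by positional index (used by the holdout analysis)."""
        mask = np.ones(len(self._frame), dtype=bool)
        mask[np.asarray(index, dtype=int)] = False
        return Dataset(self._frame.loc[mask])
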