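"""Replicated time-course container shared by all analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["TimeCourse"]


@dataclass
class TimeCourse:
    """Replicated expression-vs-time measurements for one (cell line, gene).

    Parameters
    ----------
    label : tuple
        ``(cell_line, gene)`` identifier.
    times : ndarray, shape (T,)
        Sampling times in hours, strictly increasing.
    values : ndarray, shape (T, R)
        One column per replicate; missing observations are ``NaN``.
    meta : dict
        Free-form provenance (detrending record, generator truth, ...).
    """

    label: tuple
    times: np.ndarray
    values: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.values.ndim != 2:
            raise ValueError("values must be a (time, replicate) matrix")
        if self.values.shape[0] != self.times.size:
            raise ValueError(
                f"values has {self.values.shape[0]} rows for {self.times.size} times"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        present = np.isfinite(self.values)
        finite_or_nan = present | np.isnan(self.values)
        if not finite_or_nan.all():
            raise ValueError("present values must be finite (use NaN for missing)")
        if self.times.size and not present.any(axis=1).all():
            empty = self.times[~present.any(axis=1)]
            raise ValueError(f"time points with no observations: {empty.tolist()}")

    # -- basic geometry -------------------------------------------------

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of observed entries, shape (T, R)."""
        return np.isfinite(self.values)

    def counts(self) -> np.ndarray:
        """Number of present replicates at each time point."""
        return self.present.sum(axis=1)

    def observations(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to paired ``(t, y)`` arrays of the present observations."""
        mask = self.present
        t_idx, _ = np.nonzero(mask)
        return self.times[t_idx], self.values[mask]

    def observation_time_index(self) -> np.ndarray:
        """Time-point index of each flattened observation."""
        t_idx, _ = np.nonzero(self.present)
        return t_idx

    @property
    def n_obs(self) -> int:
        return int(self.present.sum())

    def with_values(self, values: np.ndarray, **meta: Any) -> "TimeCourse":
        """Copy with a replaced value matrix and merged metadata."""
        merged = dict(self.meta)
        merged.update(meta)
        return TimeCourse(self.label, self.times.copy(), np.asarray(values, float), merged)
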