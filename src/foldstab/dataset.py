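"""In-memory containers for equilibrium unfolding data.

One :class:`UnfoldingSeries` is a single temperature ramp at a fixed
denaturant concentration; an :class:`UnfoldingDataset` is one variant's
(replicate's) collection of such series across the denaturant grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import InvalidParameterError

MIN_POINTS_PER_SERIES = 10
MIN_DENATURANT_LEVELS = 5


@dataclass
class UnfoldingSeries:
    """Signal vs temperature at one denaturant concentration.

    ``mask`` flags points to *include* (True); at least 10 unmasked points are
    required and temperatures must be strictly increasing.
    """

    denaturant: float
    temperature: np.ndarray  # Kelvin
    signal: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.temperature.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.temperature.shape == self.signal.shape == self.mask.shape):
            raise InvalidParameterError("temperature/signal/mask shapes differ")
        if self.denaturant < 0:
            raise InvalidParameterError("denaturant must be >= 0 M")
        if np.any(np.diff(self.temperature) <= 0):
            raise InvalidParameterError("temperatures must be strictly increasing")
        if int(self.mask.sum()) < MIN_POINTS_PER_SERIES:
            raise InvalidParameterError(
                f"fewer than {MIN_POINTS_PER_SERIES} unmasked points in series"
            )

    @property
    def n_unmasked(self) -> int:
        return int(self.mask.sum())


@dataclass
class UnfoldingDataset:
    """One variant's melting series at >= 5 distinct denaturant levels."""

    variant_label: str
    series: Sequence[UnfoldingSeries] = field(default_factory=list)
    replicate_id: int = 0

    def __post_init__(self) -> None:
        levels = {s.denaturant for s in self.series}
        if len(levels) < MIN_DENATURANT_LEVELS:
            raise InvalidParameterError(
                f"dataset needs >= {MIN_DENATURANT_LEVELS} distinct denaturant "
                f"levels, got {len(levels)}"
            )

    @property
    def denaturant_levels(self) -> np.ndarray:
        return np.array(sorted({s.denaturant for s in self.series}))

    @property
    def n_points(self) -> int:
        return int(sum(s.n_unmasked for s in self.series))


@dataclass(frozen=True)
class MaskWindow:
    """Rectangular exclusion window in (temperature K, denaturant M) space.

    ``None`` bounds are open; points falling inside every given bound are
    excluded. Used e.g. to drop aggregation-contaminated regions such as
    high-temperature low-denaturant readings.
    """

    t_min: Optional[float] = None
    t_max: Optional[float] = None
    d_min: Optional[float] = None
    d_max: Optional[float] = None

    def excludes(self, temperature: np.ndarray, denaturant: float) -> np.ndarray:
        inside = np.ones(np.shape(temperature), dtype=bool)
        if self.t_min is not None:
            inside &= temperature >= self.t_min
        if self.t_max is not None:
            inside &= temperature <= self.t_max
        if self.d_min is not None:
            inside &= denaturant >= self.d_min
        if self.d_max is not None:
            inside &= denaturant <= self.d_max
        return inside


def apply_masks(
    dataset: UnfoldingDataset, windows: Sequence[MaskWindow]
) -> UnfoldingDataset:
    """Return a copy of ``dataset`` with points inside any window masked out."""
    new_series = []
    for s in dataset.series:
        mask = s.mask.copy()
        for w in windows:
            mask &= ~w.excludes(s.temperature, s.denaturant)
        new_series.append(replace(s, mask=mask))
    return replace(dataset, series=new_series)
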