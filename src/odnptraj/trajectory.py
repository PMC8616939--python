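"""Core trajectory container.

A :class:`Trajectory` holds one or more named, uniformly sampled channels —
atomic spin densities (atomic units), hydrogen-bond lengths (Å), angles
(degrees) — on a common femtosecond time base, as extracted from an MD run
or produced by the synthetic generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: relative tolerance for uniform-spacing validation of the time base
_SPACING_RTOL = 1e-9

#: recognised unit tags for channel header suffixes
KNOWN_UNITS = ("au", "A", "deg", "ps", "fs")


class TrajectoryError(ValueError):
    """Raised for malformed trajectory data (spacing, length, units)."""


@dataclass
class Channel:
    """A single named observable with a unit tag."""

    name: str
    values: np.ndarray
    unit: str = "au"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise TrajectoryError(f"channel {self.name!r} must be 1-D")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise TrajectoryError(
                f"channel {self.name!r} has non-finite value at index {bad}"
            )


@dataclass
class Trajectory:
    """Uniformly sampled multi-channel time series.

    Parameters
    ----------
    times
        Sample times in femtoseconds, strictly increasing and uniformly
        spaced to within ``1e-9`` relative tolerance.
    channels
        Mapping of channel name to :class:`Channel`.
    meta
        Free-form provenance strings (generator parameters, source file, ...).
    """

    times: np.ndarray
    channels: dict[str, Channel]
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 4:
            raise TrajectoryError("need at least 4 uniformly spaced samples")
        diffs = np.diff(self.times)
        if np.any(diffs <= 0):
            idx = int(np.flatnonzero(diffs <= 0)[0]) + 1
            raise TrajectoryError(f"times not strictly increasing at index {idx}")
        dt = diffs[0]
        rel = np.abs(diffs - dt) / dt
        if np.any(rel > _SPACING_RTOL):
            idx = int(np.flatnonzero(rel > _SPACING_RTOL)[0]) + 1
            raise TrajectoryError(
                f"non-uniform sampling at index {idx}: "
                f"dt={diffs[idx - 1]:.12g} fs vs {dt:.12g} fs"
            )
        for name, ch in self.channels.items():
            if ch.values.size != self.times.size:
                raise TrajectoryError(
                    f"channel {name!r} length {ch.values.size} != "
                    f"time base length {self.times.size}"
                )

    @property
    def dt(self) -> float:
        """Sampling interval in fs."""
        return float(self.times[1] - self.times[0])

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        """Total span of the time base in fs."""
        return float(self.times[-1] - self.times[0])

    def channel(self, name: str) -> Channel:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"no channel {name!r}; available: {sorted(self.channels)}"
            ) from None

    def values(self, name: str) -> np.ndarray:
        return self.channel(name).values

    @classmethod
    def from_arrays(
        cls,
        times: np.ndarray,
        data: dict[str, np.ndarray],
        units: dict[str, str] | None = None,
        meta: dict[str, str] | None = None,
    ) -> "Trajectory":
        units = units or {}
        channels = {
            name: Channel(name, vals, units.get(name, "au"))
            for name, vals in data.items()
        }
        return cls(times=np.asarray(times, float), channels=channels,
                   meta=dict(meta or {}))
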