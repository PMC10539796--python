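"""In-memory containers for 2D spectra, hypercomplex raw data and 1D traces."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .axes import FrequencyAxis

__all__ = ["Spectrum2D", "RawFID2D", "Trace1D", "extract_row"]


@dataclass
class Spectrum2D:
    """Real 2D frequency-domain spectrum.

    ``data`` is indexed ``[f1][f2]`` — rows are the indirect (13C)
    dimension, columns the direct (1H) dimension.
    """

    data: np.ndarray
    f1_axis: FrequencyAxis
    f2_axis: FrequencyAxis
    label: str = "other"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("Spectrum2D data must be 2-dimensional")
        expected = (self.f1_axis.n_points, self.f2_axis.n_points)
        if self.data.shape != expected:
            raise ValueError(
                f"data shape {self.data.shape} does not match axes {expected}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("spectrum intensities must all be finite")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class RawFID2D:
    """Hypercomplex time-domain data of a 2D experiment.

    ``data`` is complex, indexed ``[t1 slot][t2 point]`` with States-style
    interleaving along t1: even slots hold the cosine-modulated component,
    odd slots the sine-modulated one, so ``data.shape[0] == 2 * n_t1``.
    """

    data: np.ndarray
    f1_axis: FrequencyAxis   # calibration of the eventual f1 grid (n_points = n_t1)
    f2_axis: FrequencyAxis   # calibration of the eventual f2 grid (n_points = n_t2)
    label: str = "other"
    t1_interleaving: str = "states"
    n_t2_acquired: Optional[int] = None   # nonzero t2 points (acquisition-time cap)
    acquisition: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValueError("RawFID2D data must be 2-dimensional")
        if self.data.shape[0] != 2 * self.f1_axis.n_points:
            raise ValueError(
                "RawFID2D expects 2*n_t1 interleaved rows "
                f"(got {self.data.shape[0]} rows for n_t1={self.f1_axis.n_points})"
            )
        if self.data.shape[1] != self.f2_axis.n_points:
            raise ValueError("t2 length does not match the f2 axis")
        if self.t1_interleaving != "states":
            raise ValueError("only States-style t1 interleaving is supported")
        if self.n_t2_acquired is None:
            self.n_t2_acquired = self.data.shape[1]

    @property
    def n_t1(self) -> int:
        return self.f1_axis.n_points

    @property
    def n_t2(self) -> int:
        return self.data.shape[1]

    @property
    def t2_aq_s(self) -> float:
        """t2 acquisition time in seconds (= n_t2_acquired / sw_hz)."""
        return self.n_t2_acquired / self.f2_axis.sw_hz


@dataclass
class Trace1D:
    """A 1D trace (one row of a 2D spectrum, or a simulated 1D spectrum)."""

    intensities: np.ndarray
    axis: FrequencyAxis
    origin: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 1:
            raise ValueError("Trace1D intensities must be 1-dimensional")
        if self.intensities.size != self.axis.n_points:
            raise ValueError("trace length does not match its axis")


def extract_row(spec: Spectrum2D, f1_ppm: float) -> Trace1D:
    """Extract the matrix row nearest to a 13C chemical shift, verbatim.

    The row is never interpolated; ``origin`` records both the requested
    and the actual grid ppm (they differ by at most half the f1 digital
    resolution).
    """
    idx = float(spec.f1_axis.ppm_to_index(f1_ppm))   # raises if out of range
    row = int(round(idx))
    row = min(max(row, 0), spec.f1_axis.n_points - 1)
    actual = float(spec.f1_axis.index_to_ppm(row))
    return Trace1D(
        intensities=spec.data[row].copy(),
        axis=spec.f2_axis,
        origin={
            "spectrum_label": spec.label,
            "f1_ppm_requested": float(f1_ppm),
            "f1_ppm": actual,
            "f1_index": row,
        },
    )
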