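"""Frequency-axis calibration for one spectral dimension.

A processed NMR dimension is a uniform grid of frequency points.  By
display convention index 0 sits at the *downfield* (left, highest-ppm)
edge and the chemical shift decreases linearly with index.  The axis is
fully determined by four numbers: spectral width in ppm, spectrometer
frequency of the nucleus in MHz (which converts ppm to Hz), the chemical
shift of the first point, and the number of points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FrequencyAxis"]


@dataclass(frozen=True)
class FrequencyAxis:
    """Calibration of one spectral dimension.

    Parameters
    ----------
    sw_ppm:
        Spectral width in ppm (> 0).
    sfo_mhz:
        Spectrometer frequency of the observed nucleus in MHz; multiplying
        a ppm interval by it yields Hz.
    left_edge_ppm:
        Chemical shift of index 0, the most downfield point.
    n_points:
        Number of frequency points (>= 2).
    """

    sw_ppm: float
    sfo_mhz: float
    left_edge_ppm: float
    n_points: int

    def __post_init__(self) -> None:
        if self.sw_ppm <= 0 or self.sfo_mhz <= 0:
            raise ValueError("sw_ppm and sfo_mhz must be positive")
        if int(self.n_points) != self.n_points or self.n_points < 2:
            raise ValueError("n_points must be an integer >= 2")
        object.__setattr__(self, "n_points", int(self.n_points))

    # -- derived quantities -------------------------------------------------

    @property
    def sw_hz(self) -> float:
        """Spectral width in Hz."""
        return self.sw_ppm * self.sfo_mhz

    @property
    def hz_per_point(self) -> float:
        """Digital resolution in Hz per point."""
        return self.sw_hz / self.n_points

    @property
    def ppm_per_point(self) -> float:
        return self.sw_ppm / self.n_points

    @property
    def right_edge_ppm(self) -> float:
        """Chemical shift just past the last point (exclusive lower bound)."""
        return self.left_edge_ppm - self.sw_ppm

    @property
    def center_ppm(self) -> float:
        return self.left_edge_ppm - self.sw_ppm / 2.0

    # -- conversions --------------------------------------------------------

    def ppm_scale(self) -> np.ndarray:
        """ppm value of every grid point (decreasing)."""
        return self.left_edge_ppm - np.arange(self.n_points) * self.ppm_per_point

    def index_to_ppm(self, index):
        """ppm at a (possibly fractional) index; the linear map inverse of
        :meth:`ppm_to_index`."""
        return self.left_edge_ppm - np.asarray(index, dtype=float) * self.ppm_per_point

    def ppm_to_index(self, ppm):
        """Fractional grid index of a chemical shift.

        Raises
        ------
        ValueError
            If ``ppm`` lies outside ``[left_edge_ppm - sw_ppm, left_edge_ppm]``.
        """
        ppm_arr = np.asarray(ppm, dtype=float)
        lo, hi = self.right_edge_ppm, self.left_edge_ppm
        if np.any(ppm_arr > hi) or np.any(ppm_arr < lo):
            raise ValueError(
                f"chemical shift {ppm} ppm outside axis range "
                f"[{lo:.6g}, {hi:.6g}] ppm"
            )
        return (self.left_edge_ppm - ppm_arr) / self.sw_ppm * self.n_points

    def ppm_to_nearest_index(self, ppm) -> int:
        i = int(round(float(self.ppm_to_index(ppm))))
        return min(max(i, 0), self.n_points - 1)

    def index_to_hz(self, index):
        """Frequency offset from the axis centre in Hz (downfield positive)."""
        return (self.index_to_ppm(index) - self.center_ppm) * self.sfo_mhz

    def ppm_to_hz(self, ppm):
        return (np.asarray(ppm, dtype=float) - self.center_ppm) * self.sfo_mhz

    def hz_to_ppm(self, hz):
        return np.asarray(hz, dtype=float) / self.sfo_mhz + self.center_ppm

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sw_ppm": self.sw_ppm,
            "sfo_mhz": self.sfo_mhz,
            "left_edge_ppm": self.left_edge_ppm,
            "n_points": self.n_points,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrequencyAxis":
        missing = [k for k in ("sw_ppm", "sfo_mhz", "left_edge_ppm", "n_points") if k not in d]
        if missing:
            raise KeyError(f"axis dict missing keys: {missing}")
        return cls(d["sw_ppm"], d["sfo_mhz"], d["left_edge_ppm"], d["n_points"])

    def with_n_points(self, n_points: int) -> "FrequencyAxis":
        """Same calibration on a finer/coarser digital grid (zero filling
        changes the point count but neither the width nor the left edge)."""
        return FrequencyAxis(self.sw_ppm, self.sfo_mhz, self.left_edge_ppm, n_points)
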