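"""Spin-system simulator: CLIP, CLAP, decoupled HSQC and idealized J-res.

Each 1H-13C moiety is described declaratively (shifts, one-bond coupling,
passive couplings, amplitude, linewidths) and turned into hypercomplex
time-domain data in the weak-coupling (first-order) limit.  The t2 signal
of one system is

    amplitude * exp(-pi*lw_h*t2) * prod_k cos(pi*J_k*t2)^n_k
              * M(t2) * exp(i*Omega_H*t2)

where the mode factor M is ``cos(pi*J_CH*t2)`` for CLIP (in-phase doublet,
both components positive), ``i*sin(pi*J_CH*t2)`` for CLAP (anti-phase
doublet, components of opposite sign) and 1 for the decoupled experiment,
which instead caps the t2 acquisition time (100 ms by default — the
practical limit imposed by decoupler duty cycle).  t1 is States-style
hypercomplex with cos/sin modulation at Omega_C and Lorentzian decay.

Sign convention: with this phase choice the downfield CLAP component is
positive and the upfield one negative after processing.  That is a
simulator convention only — the pairing algorithm never relies on which
sign is up- or downfield.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .axes import FrequencyAxis
from .spectra import RawFID2D, Spectrum2D

__all__ = [
    "SpinSystemSpec",
    "AcquisitionParams",
    "simulate_hsqc",
    "simulate_jres",
    "make_zebra_fixture",
    "zebra_acquisition",
    "load_systems",
    "save_systems",
]

MODES = ("clip", "clap", "decoupled", "alpha", "beta")
DEFAULT_DECOUPLED_AQ_S = 0.1


@dataclass(frozen=True)
class SpinSystemSpec:
    """One 1H-13C moiety.

    ``passive_couplings`` is a list of ``(J_hz, n_equivalent)`` pairs and
    models homonuclear (JHH) and passive heteronuclear (e.g. JHP)
    couplings identically, as cosine amplitude modulations.
    """

    delta_h: float                 # 1H shift, ppm
    delta_c: float                 # 13C shift, ppm
    j_ch: float                    # one-bond 1JCH, Hz
    passive_couplings: Tuple[Tuple[float, int], ...] = ()
    amplitude: float = 1.0
    lw_h: float = 1.0              # 1H Lorentzian linewidth (FWHM), Hz
    lw_c: float = 2.0              # 13C linewidth, Hz

    def __post_init__(self) -> None:
        if self.j_ch <= 0:
            raise ValueError("j_ch must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.lw_h <= 0 or self.lw_c <= 0:
            raise ValueError("linewidths must be positive")
        pc = tuple((float(j), int(n)) for j, n in self.passive_couplings)
        if any(j < 0 or n < 1 for j, n in pc):
            raise ValueError("passive couplings need J >= 0 and n >= 1")
        object.__setattr__(self, "passive_couplings", pc)

    def to_dict(self) -> dict:
        return {
            "delta_h": self.delta_h,
            "delta_c": self.delta_c,
            "j_ch": self.j_ch,
            "passive": [[j, n] for j, n in self.passive_couplings],
            "amplitude": self.amplitude,
            "lw_h": self.lw_h,
            "lw_c": self.lw_c,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpinSystemSpec":
        return cls(
            delta_h=d["delta_h"],
            delta_c=d["delta_c"],
            j_ch=d["j_ch"],
            passive_couplings=tuple((j, n) for j, n in d.get("passive", [])),
            amplitude=d.get("amplitude", 1.0),
            lw_h=d.get("lw_h", 1.0),
            lw_c=d.get("lw_c", 2.0),
        )


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition grid and experiment mode.

    ``f2`` / ``f1`` carry the spectral calibration; their ``n_points``
    fields are the numbers of acquired complex time points (n_t2, n_t1).
    ``aq_override_s`` caps the t2 acquisition time; ``None`` means the
    mode default (100 ms for decoupled, no cap otherwise) and
    ``math.inf`` forces an uncapped acquisition in any mode.
    """

    f2: FrequencyAxis
    f1: FrequencyAxis
    mode: str = "clip"
    aq_override_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.f2.n_points < 8 or self.f1.n_points < 8:
            raise ValueError("need at least 8 time points per dimension")

    @property
    def n_t2_acquired(self) -> int:
        aq = self.aq_override_s
        if aq is None:
            aq = DEFAULT_DECOUPLED_AQ_S if self.mode == "decoupled" else None
        if aq is None or not np.isfinite(aq):
            return self.f2.n_points
        return min(self.f2.n_points, max(4, int(np.floor(aq * self.f2.sw_hz))))


def simulate_hsqc(
    systems: Sequence[SpinSystemSpec],
    acq: AcquisitionParams,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> RawFID2D:
    """Simulate the hypercomplex raw data of a CLIP/CLAP/decoupled HSQC.

    ``alpha`` / ``beta`` modes generate the single doublet-component
    (spin-state-selective) subspectra at Omega_H +/- J/2 with half
    amplitude; by construction clip = alpha + beta and clap = alpha - beta
    at the FID level.

    Gaussian noise of standard deviation ``noise_sigma`` is added to the
    real and imaginary parts of every time point, controlled by ``seed``.
    With a fixed seed the output is bit-reproducible.
    """
    if not systems:
        raise ValueError("need at least one spin system")
    n_t1, n_t2 = acq.f1.n_points, acq.f2.n_points
    n_acq2 = acq.n_t2_acquired
    t2 = np.arange(n_t2) / acq.f2.sw_hz
    t1 = np.arange(n_t1) / acq.f1.sw_hz

    fid = np.zeros((2 * n_t1, n_t2), dtype=np.complex128)
    for k, sys_ in enumerate(systems):
        try:
            off_h = float(acq.f2.ppm_to_hz(sys_.delta_h))
            acq.f2.ppm_to_index(sys_.delta_h)
            off_c = float(acq.f1.ppm_to_hz(sys_.delta_c))
            acq.f1.ppm_to_index(sys_.delta_c)
        except ValueError as exc:
            raise ValueError(f"system {k}: {exc}") from exc

        s2 = sys_.amplitude * np.exp(-np.pi * sys_.lw_h * t2)
        for j_p, n_p in sys_.passive_couplings:
            s2 = s2 * np.cos(np.pi * j_p * t2) ** n_p
        if acq.mode == "clip":
            s2 = s2 * np.cos(np.pi * sys_.j_ch * t2)
        elif acq.mode == "clap":
            s2 = s2 * (1j * np.sin(np.pi * sys_.j_ch * t2))
        elif acq.mode == "alpha":
            s2 = s2 * 0.5 * np.exp(1j * np.pi * sys_.j_ch * t2)
        elif acq.mode == "beta":
            s2 = s2 * 0.5 * np.exp(-1j * np.pi * sys_.j_ch * t2)
        # decoupled: no J_CH factor
        s2 = s2 * np.exp(2j * np.pi * off_h * t2)
        s2[n_acq2:] = 0.0

        e1 = np.exp(-np.pi * sys_.lw_c * t1)
        fid[0::2] += np.outer(e1 * np.cos(2 * np.pi * off_c * t1), s2)
        fid[1::2] += np.outer(e1 * np.sin(2 * np.pi * off_c * t1), s2)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        fid = fid + (
            rng.normal(0.0, noise_sigma, fid.shape)
            + 1j * rng.normal(0.0, noise_sigma, fid.shape)
        )

    return RawFID2D(
        data=fid,
        f1_axis=acq.f1,
        f2_axis=acq.f2,
        label=acq.mode if acq.mode in ("clip", "clap", "decoupled") else "other",
        n_t2_acquired=n_acq2,
        acquisition={
            "mode": acq.mode,
            "n_t1": n_t1,
            "n_t2": n_t2,
            "n_t2_acquired": n_acq2,
            "noise_sigma": noise_sigma,
            "seed": seed,
        },
    )


def _multiplet_sticks(passive: Sequence[Tuple[float, int]]):
    """Signed F1 offsets and binomial weights of a first-order multiplet.

    n equivalent partners with coupling J give n+1 lines at offsets
    (k - n/2)*J with weights C(n, k); independent couplings convolve
    (outer sum of offsets, product of weights).  Weights are normalized
    to sum to 1.
    """
    offsets = np.array([0.0])
    weights = np.array([1.0])
    for j, n in passive:
        line_off = (np.arange(n + 1) - n / 2.0) * j
        line_w = np.array([float(comb(n, k)) for k in range(n + 1)])
        offsets = (offsets[:, None] + line_off[None, :]).ravel()
        weights = (weights[:, None] * line_w[None, :]).ravel()
    # merge coincident lines for a stable stick list
    order = np.argsort(offsets)
    offsets, weights = offsets[order], weights[order]
    merged_off, merged_w = [], []
    for o, w in zip(offsets, weights):
        if merged_off and abs(o - merged_off[-1]) < 1e-9:
            merged_w[-1] += w
        else:
            merged_off.append(o)
            merged_w.append(w)
    w = np.array(merged_w)
    return np.array(merged_off), w / w.sum()


def simulate_jres(
    systems: Sequence[SpinSystemSpec],
    f2_axis: FrequencyAxis,
    f1_hz_halfwidth: float = 25.0,
    lw_hz: float = 1.0,
    n_f1: int = 256,
) -> Spectrum2D:
    """Idealized tilted J-resolved spectrum.

    Each system contributes sticks at (F2 = delta_h exactly, F1 = signed
    multiplet offsets from the *passive* couplings only) with binomial
    intensities, broadened by a separable 2D Lorentzian of FWHM ``lw_hz``.
    The one-bond coupling does not appear (13C-decoupled J-res
    convention), so the F1 = 0 Hz trace is the fully decoupled proton
    subspectrum up to lineshape.

    The F1 axis is returned as a Hz axis (``sfo_mhz = 1`` so ppm == Hz),
    running from ``+f1_hz_halfwidth`` at index 0 down to
    ``-f1_hz_halfwidth``.
    """
    f1_axis = FrequencyAxis(
        sw_ppm=2.0 * f1_hz_halfwidth, sfo_mhz=1.0,
        left_edge_ppm=f1_hz_halfwidth, n_points=n_f1,
    )
    f2_hz = f2_axis.index_to_hz(np.arange(f2_axis.n_points))
    f1_hz = f1_axis.index_to_ppm(np.arange(n_f1))   # ppm == Hz here
    gamma = lw_hz / 2.0
    data = np.zeros((n_f1, f2_axis.n_points))
    for k, sys_ in enumerate(systems):
        offs, wts = _multiplet_sticks(sys_.passive_couplings)
        if np.any(np.abs(offs) > f1_hz_halfwidth):
            raise ValueError(
                f"system {k}: multiplet offset exceeds the +/-{f1_hz_halfwidth} Hz F1 window"
            )
        center_hz = float(f2_axis.ppm_to_hz(sys_.delta_h))
        l2 = gamma**2 / ((f2_hz - center_hz) ** 2 + gamma**2)
        for o, w in zip(offs, wts):
            l1 = gamma**2 / ((f1_hz - o) ** 2 + gamma**2)
            data += sys_.amplitude * w * np.outer(l1, l2)
    return Spectrum2D(data=data, f1_axis=f1_axis, f2_axis=f2_axis, label="jres")


def make_zebra_fixture() -> List[SpinSystemSpec]:
    """Deterministic spin-system set emulating the trimethylamine region
    (3.1-3.3 ppm) of a zebra-mussel extract.

    Contents:

    * two singlets on a carbon at exactly 55.623 ppm, 0.006 ppm apart in
      1H and differing 10-fold in amplitude — unresolvable in a short-
      acquisition decoupled HSQC, resolvable after virtual decoupling;
    * three doublet-of-doublet systems with two near-equal passive
      couplings (6.5 / 6.8 Hz), appearing as 1:2:1 pseudo-triplets, one
      at delta_C 43.298 ppm and two sharing delta_C 38.426 ppm;
    * one singlet at delta_H 3.271 ppm on a nearby carbon (39.2 ppm):
      its proton sits within the broad lineshape of the 38.426 ppm dd
      protons in a short-acquisition decoupled spectrum, so it is
      confusable there, while the vd spectrum separates all of them.

    Proton shifts, passive-coupling values and amplitudes of the dd
    systems are plausible placeholders, not measured values.
    """
    dd_passive = ((6.5, 1), (6.8, 1))
    return [
        SpinSystemSpec(delta_h=3.118, delta_c=55.623, j_ch=145.0,
                       amplitude=10.0, lw_h=1.0, lw_c=2.0),
        SpinSystemSpec(delta_h=3.124, delta_c=55.623, j_ch=145.0,
                       amplitude=1.0, lw_h=1.0, lw_c=2.0),
        SpinSystemSpec(delta_h=3.252, delta_c=43.298, j_ch=142.0,
                       passive_couplings=dd_passive, amplitude=3.0,
                       lw_h=1.0, lw_c=2.0),
        SpinSystemSpec(delta_h=3.238, delta_c=38.426, j_ch=130.0,
                       passive_couplings=dd_passive, amplitude=2.5,
                       lw_h=1.0, lw_c=2.0),
        SpinSystemSpec(delta_h=3.266, delta_c=38.426, j_ch=135.0,
                       passive_couplings=dd_passive, amplitude=2.0,
                       lw_h=1.0, lw_c=2.0),
        SpinSystemSpec(delta_h=3.271, delta_c=39.200, j_ch=140.0,
                       amplitude=4.0, lw_h=1.0, lw_c=2.0),
    ]


def zebra_acquisition(mode: str, n_t2: int = 16384, n_t1: int = 256) -> AcquisitionParams:
    """Acquisition grid matching the zebra-mussel fixture: 12.0172 ppm of
    1H at 700.13 MHz (left edge 9.5 ppm) x 60 ppm of 13C at 176.05 MHz
    (left edge 79.98 ppm)."""
    return AcquisitionParams(
        f2=FrequencyAxis(12.0172, 700.13, 9.5, n_t2),
        f1=FrequencyAxis(60.0, 176.05, 79.98, n_t1),
        mode=mode,
    )


def load_systems(path) -> List[SpinSystemSpec]:
    """Read spin systems from a JSON or YAML file (list of objects with
    keys delta_h, delta_c, j_ch, passive, amplitude, lw_h, lw_c)."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        entries = yaml.safe_load(text)
    else:
        entries = json.loads(text)
    if not isinstance(entries, list):
        raise ValueError("spin-system file must contain a list of objects")
    return [SpinSystemSpec.from_dict(e) for e in entries]


def save_systems(systems: Sequence[SpinSystemSpec], path) -> None:
    Path(path).write_text(json.dumps([s.to_dict() for s in systems], indent=1))
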