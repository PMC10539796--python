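"""Shared fixtures: simulated spectra reused across test modules."""

from pathlib import Path

import numpy as np
import pytest

import vdhsqc as v


@pytest.fixture(scope="session")
def small_f2():
    return v.FrequencyAxis(12.0172, 700.13, 9.5, 4096)


@pytest.fixture(scope="session")
def small_f1():
    return v.FrequencyAxis(60.0, 176.05, 79.98, 32)


@pytest.fixture(scope="session")
def zebra_result():
    """Full-size zebra-mussel fixture run through the whole pipeline.

    Expensive (two 16384 x 256 simulations + processing), so shared
    session-wide; tests must not mutate the result.
    """
    systems = v.make_zebra_fixture()
    clip = v.simulate_hsqc(systems, v.zebra_acquisition("clip"))
    clap = v.simulate_hsqc(systems, v.zebra_acquisition("clap"))
    return v.virtual_decouple(clip, clap)


@pytest.fixture(scope="session")
def zebra_jres():
    systems = v.make_zebra_fixture()
    return v.simulate_jres(systems, v.zebra_acquisition("clip").f2)


def write_bruker_dir(spec, path: Path, nc_proc: int = None, xdim=None) -> Path:
    """Write a synthetic Bruker-style processed directory (2rr + procs +
    proc2s) from a Spectrum2D, for exercising the read-only dialect."""
    path.mkdir(parents=True, exist_ok=True)
    data = spec.data
    if nc_proc is None:
        peak = np.abs(data).max() or 1.0
        nc_proc = int(np.ceil(np.log2(peak / 2**29)))
    ints = np.round(data / 2.0**nc_proc).astype("<i4")
    xd1, xd2 = xdim or (spec.f1_axis.n_points, spec.f2_axis.n_points)
    si1, si2 = ints.shape
    blocks = ints.reshape(si1 // xd1, xd1, si2 // xd2, xd2).transpose(0, 2, 1, 3)
    (path / "2rr").write_bytes(np.ascontiguousarray(blocks).tobytes())

    def params(axis, xd):
        return (f"##$SI= {axis.n_points}\n"
                f"##$SW_p= {axis.sw_hz}\n"
                f"##$SF= {axis.sfo_mhz}\n"
                f"##$OFFSET= {axis.left_edge_ppm}\n"
                f"##$NC_proc= {nc_proc}\n"
                f"##$XDIM= {xd}\n"
                f"##$BYTORDP= 0\n##$DTYPP= 0\n")

    (path / "procs").write_text(params(spec.f2_axis, xd2))
    (path / "proc2s").write_text(params(spec.f1_axis, xd1))
    return path
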