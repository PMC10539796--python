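"""Portable spectrum containers.

Native format: one directory per object holding

* ``data.bin`` — the matrix, row-major; ``float64`` for spectra,
  ``complex128`` (interleaved re/im float64 pairs) for raw data;
* ``meta.json`` — kind, label, dtype, shape, both axes, acquisition and
  provenance metadata.

A read-only dialect for Bruker-style processed 2D data (``2rr`` integer
matrix plus ``procs`` / ``proc2s`` key-value parameter files, including
submatrix blocking via XDIM) is provided behind the same contract.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np

from .axes import FrequencyAxis
from .spectra import RawFID2D, Spectrum2D

__all__ = [
    "ContainerSchemaError",
    "write_container",
    "read_container",
    "read_bruker_processed",
]

_REQUIRED_KEYS = ("kind", "dtype", "shape", "f1_axis", "f2_axis")


class ContainerSchemaError(KeyError):
    """Raised when a container's metadata is missing required keys."""


def write_container(obj: Union[Spectrum2D, RawFID2D], path) -> None:
    """Write a spectrum or raw-data object to a container directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, Spectrum2D):
        meta = {
            "kind": "spectrum2d",
            "dtype": "float64",
            "shape": list(obj.data.shape),
            "f1_axis": obj.f1_axis.to_dict(),
            "f2_axis": obj.f2_axis.to_dict(),
            "label": obj.label,
            "provenance": obj.provenance,
        }
    elif isinstance(obj, RawFID2D):
        meta = {
            "kind": "rawfid2d",
            "dtype": "complex128",
            "shape": list(obj.data.shape),
            "f1_axis": obj.f1_axis.to_dict(),
            "f2_axis": obj.f2_axis.to_dict(),
            "label": obj.label,
            "t1_interleaving": obj.t1_interleaving,
            "n_t2_acquired": obj.n_t2_acquired,
            "acquisition": obj.acquisition,
            "provenance": obj.provenance,
        }
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    (path / "data.bin").write_bytes(np.ascontiguousarray(obj.data).tobytes())
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_container(path) -> Union[Spectrum2D, RawFID2D]:
    """Read a container directory back into its in-memory object."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no meta.json in {path}")
    meta = json.loads(meta_path.read_text())
    missing = [k for k in _REQUIRED_KEYS if k not in meta]
    if missing:
        raise ContainerSchemaError(f"container metadata missing keys: {missing}")
    shape = tuple(meta["shape"])
    dtype = np.dtype(meta["dtype"])
    data = np.frombuffer((path / "data.bin").read_bytes(), dtype=dtype)
    if data.size != shape[0] * shape[1]:
        raise ValueError(
            f"data.bin holds {data.size} values but metadata declares shape {shape}"
        )
    data = data.reshape(shape).copy()
    f1 = FrequencyAxis.from_dict(meta["f1_axis"])
    f2 = FrequencyAxis.from_dict(meta["f2_axis"])
    if meta["kind"] == "spectrum2d":
        return Spectrum2D(data=data, f1_axis=f1, f2_axis=f2,
                          label=meta.get("label", "other"),
                          provenance=meta.get("provenance", {}))
    if meta["kind"] == "rawfid2d":
        return RawFID2D(data=data, f1_axis=f1, f2_axis=f2,
                        label=meta.get("label", "other"),
                        t1_interleaving=meta.get("t1_interleaving", "states"),
                        n_t2_acquired=meta.get("n_t2_acquired"),
                        acquisition=meta.get("acquisition", {}),
                        provenance=meta.get("provenance", {}))
    raise ContainerSchemaError(f"unknown container kind {meta['kind']!r}")


# ---------------------------------------------------------------------------
# Bruker-style processed-data dialect (read-only)
# ---------------------------------------------------------------------------

def _parse_param_file(path: Path) -> dict:
    """Parse ``##$KEY= value`` lines of a JCAMP-style parameter file."""
    params = {}
    for line in path.read_text().splitlines():
        if not line.startswith("##$"):
            continue
        key, _, value = line[3:].partition("=")
        value = value.strip()
        try:
            params[key.strip()] = int(value)
        except ValueError:
            try:
                params[key.strip()] = float(value)
            except ValueError:
                params[key.strip()] = value
    return params


def _deblock(flat: np.ndarray, si1: int, si2: int, xd1: int, xd2: int) -> np.ndarray:
    """Undo Bruker submatrix storage: the matrix is stored as consecutive
    (xd1 x xd2) blocks, row-blocks first."""
    if xd1 == si1 and xd2 == si2:
        return flat.reshape(si1, si2)
    nb1, nb2 = si1 // xd1, si2 // xd2
    blocks = flat.reshape(nb1, nb2, xd1, xd2)
    return blocks.transpose(0, 2, 1, 3).reshape(si1, si2)


def _axis_from_params(p: dict, name: str) -> FrequencyAxis:
    missing = [k for k in ("SI", "SW_p", "SF", "OFFSET") if k not in p]
    if missing:
        raise ContainerSchemaError(f"{name} missing keys: {missing}")
    sf = float(p["SF"])
    return FrequencyAxis(
        sw_ppm=float(p["SW_p"]) / sf,
        sfo_mhz=sf,
        left_edge_ppm=float(p["OFFSET"]),
        n_points=int(p["SI"]),
    )


def read_bruker_processed(path, label: str = "other") -> Spectrum2D:
    """Read a Bruker-style processed 2D directory (``2rr`` + ``procs`` +
    ``proc2s``) into a :class:`Spectrum2D`.

    Intensities are the stored integers scaled by ``2**NC_proc``.  Only
    little-endian int32 data (``BYTORDP=0``, ``DTYPP=0``) is supported.
    """
    path = Path(path)
    for fname in ("2rr", "procs", "proc2s"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"{path} has no {fname} file")
    p2 = _parse_param_file(path / "procs")     # direct (f2) dimension
    p1 = _parse_param_file(path / "proc2s")    # indirect (f1) dimension
    f2 = _axis_from_params(p2, "procs")
    f1 = _axis_from_params(p1, "proc2s")
    if p2.get("BYTORDP", 0) != 0 or p2.get("DTYPP", 0) != 0:
        raise ValueError("only little-endian int32 processed data is supported")
    raw = np.frombuffer((path / "2rr").read_bytes(), dtype="<i4").astype(np.float64)
    si1, si2 = f1.n_points, f2.n_points
    if raw.size != si1 * si2:
        raise ValueError(
            f"2rr holds {raw.size} points, expected {si1}x{si2}={si1 * si2}"
        )
    xd2 = int(p2.get("XDIM", si2)) or si2
    xd1 = int(p1.get("XDIM", si1)) or si1
    data = _deblock(raw, si1, si2, xd1, xd2) * 2.0 ** int(p2.get("NC_proc", 0))
    return Spectrum2D(data=data, f1_axis=f1, f2_axis=f2, label=label,
                      provenance={"source": "bruker_processed", "path": str(path)})
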