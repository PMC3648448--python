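"""File formats: the RGLM v1 listmode container, NIfTI images, CSV tables.

RGLM v1 ("respiratory gating listmode") is a little-endian binary format:

* magic ``b"RGLM"`` + version byte ``0x01``
* ``uint32`` header length, then that many bytes of UTF-8 JSON holding the
  scanner geometry, duration, clock resolution and provenance
* fixed-width 15-byte records, time-interleaved events and triggers:
  ``uint8`` record kind (0 event, 1 respiratory trigger, 2 random trigger,
  3 hardware trigger), ``uint32`` t_ms, ``uint16`` rho, ``uint16`` theta,
  ``uint16`` z_ssrb, ``int32`` origin voxel (flat index, -1 if unknown).

An equivalent CSV dialect (columns ``kind,t_ms,rho,theta,z,origin``) is
provided for human-readable fixtures.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ParameterError
from .geometry import ScannerGeometry
from .simdata import KIND_EVENT, ListmodeStream

RGLM_MAGIC = b"RGLM\x01"
RECORD_DTYPE = np.dtype(
    [
        ("kind", "<u1"),
        ("t_ms", "<u4"),
        ("rho", "<u2"),
        ("theta", "<u2"),
        ("z", "<u2"),
        ("origin", "<i4"),
    ]
)
assert RECORD_DTYPE.itemsize == 15


def _merged_records(stream: ListmodeStream) -> np.ndarray:
    n_e, n_t = stream.n_events, len(stream.trig_t_ms)
    rec = np.zeros(n_e + n_t, dtype=RECORD_DTYPE)
    rec["kind"][:n_e] = KIND_EVENT
    rec["t_ms"][:n_e] = stream.t_ms
    rec["rho"][:n_e] = stream.rho
    rec["theta"][:n_e] = stream.theta
    rec["z"][:n_e] = stream.z
    rec["origin"][:n_e] = stream.origin
    rec["kind"][n_e:] = stream.trig_kind
    rec["t_ms"][n_e:] = stream.trig_t_ms
    rec["origin"][n_e:] = -1
    order = np.argsort(rec["t_ms"], kind="stable")
    return rec[order]


def write_rglm(stream: ListmodeStream, path: str | Path) -> None:
    header = {
        "geometry": stream.geometry.to_dict(),
        "duration_ms": int(stream.duration_ms),
        "clock_ms": int(stream.clock_ms),
        "provenance": stream.provenance,
    }
    blob = json.dumps(header).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(RGLM_MAGIC)
        fh.write(np.uint32(len(blob)).tobytes())
        fh.write(blob)
        fh.write(_merged_records(stream).tobytes())


def _stream_from_records(rec: np.ndarray, header: dict) -> ListmodeStream:
    ev = rec["kind"] == KIND_EVENT
    return ListmodeStream(
        geometry=ScannerGeometry.from_dict(header["geometry"]),
        duration_ms=int(header["duration_ms"]),
        t_ms=rec["t_ms"][ev],
        rho=rec["rho"][ev],
        theta=rec["theta"][ev],
        z=rec["z"][ev],
        origin=rec["origin"][ev],
        trig_t_ms=rec["t_ms"][~ev],
        trig_kind=rec["kind"][~ev],
        clock_ms=int(header.get("clock_ms", 1)),
        provenance=header.get("provenance", {}),
    )


def read_rglm(path: str | Path) -> ListmodeStream:
    with open(path, "rb") as fh:
        magic = fh.read(5)
        if magic != RGLM_MAGIC:
            raise ParameterError(f"{path}: not an RGLM v1 file")
        (n,) = np.frombuffer(fh.read(4), dtype="<u4")
        header = json.loads(fh.read(int(n)).decode("utf-8"))
        rec = np.frombuffer(fh.read(), dtype=RECORD_DTYPE)
    return _stream_from_records(rec, header)


def write_listmode_csv(stream: ListmodeStream, path: str | Path) -> None:
    """CSV dialect of RGLM (events + triggers, time-interleaved)."""
    rec = _merged_records(stream)
    df = pd.DataFrame(
        {
            "kind": rec["kind"],
            "t_ms": rec["t_ms"],
            "rho": rec["rho"],
            "theta": rec["theta"],
            "z": rec["z"],
            "origin": rec["origin"],
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "geometry": stream.geometry.to_dict(),
        "duration_ms": int(stream.duration_ms),
        "clock_ms": int(stream.clock_ms),
        "provenance": stream.provenance,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_listmode_csv(path: str | Path) -> ListmodeStream:
    df = pd.read_csv(path)
    header = json.loads(Path(str(path) + ".json").read_text())
    rec = np.zeros(len(df), dtype=RECORD_DTYPE)
    for col in rec.dtype.names:
        rec[col] = df[col].to_numpy()
    return _stream_from_records(rec, header)


def write_nifti(
    data: np.ndarray, voxel_size: tuple[float, float, float], path: str | Path
) -> None:
    """3D or 4D image as NIfTI-1 with voxel sizes in the header."""
    data = np.asarray(data)
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    zooms = tuple(voxel_size) + ((1.0,) if data.ndim == 4 else ())
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])
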