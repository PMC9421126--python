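"""Readers and writers for the pipeline's on-disk formats.

* FID/spectrum text dialect: a commented header (dwell time, transmitter
  frequency, point count, edit labels, domain) followed by one block per
  transient of two-column real/imaginary samples.  Mirrors the role of the
  classic raw time-domain exchange format but stays human-readable.
* NIfTI-1 volumes via nibabel.
* TSV tables via pandas.
* JSON reports (numpy types coerced).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .mrs_prep import DiffSpectrum, TransientSeries
from .types import AcquisitionSpec

__all__ = [
    "write_fid_series",
    "read_fid_series",
    "write_diff_spectrum",
    "read_diff_spectrum",
    "write_nifti",
    "read_nifti",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
]

_MAGIC = "# megabold-fid v1"


def _acq_header(acq: AcquisitionSpec) -> list[str]:
    return [
        f"# dwell_time={acq.dwell_time!r}",
        f"# transmitter_freq={acq.transmitter_freq!r}",
        f"# n_points={acq.n_points}",
        f"# n_transient_pairs={acq.n_transient_pairs}",
        f"# edit_on_ppm={acq.edit_on_ppm!r}",
        f"# edit_off_ppm={acq.edit_off_ppm!r}",
        f"# tr={acq.tr!r}",
    ]


def _parse_header(lines: list[str]) -> dict:
    meta = {}
    for ln in lines:
        if ln.startswith("# ") and "=" in ln:
            key, val = ln[2:].split("=", 1)
            meta[key.strip()] = val.strip()
    return meta


def write_fid_series(path: str | Path, series: TransientSeries) -> None:
    path = Path(path)
    out = [_MAGIC, "# domain=time"] + _acq_header(series.acq)
    out.append(f"# n_transients={series.n_transients}")
    for i in range(series.n_transients):
        out.append(f"> {i} {series.edit_labels[i]}")
        fid = series.fids[i]
        out.extend(f"{v.real:.17g} {v.imag:.17g}" for v in fid)
    path.write_text("\n".join(out) + "\n")


def read_fid_series(path: str | Path) -> TransientSeries:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _MAGIC:
        raise ValueError(f"{path}: not a megabold FID file")
    meta = _parse_header(lines)
    acq = AcquisitionSpec(
        dwell_time=float(meta["dwell_time"]),
        transmitter_freq=float(meta["transmitter_freq"]),
        n_points=int(meta["n_points"]),
        n_transient_pairs=int(meta.get("n_transient_pairs", 1)),
        edit_on_ppm=float(meta.get("edit_on_ppm", 1.9)),
        edit_off_ppm=float(meta.get("edit_off_ppm", 7.5)),
        tr=float(meta.get("tr", 2.0)),
    )
    fids, labels = [], []
    cur: list[complex] = []
    for ln in lines:
        if ln.startswith("#") or not ln.strip():
            continue
        if ln.startswith(">"):
            if cur:
                fids.append(cur)
            cur = []
            labels.append(ln.split()[2])
        else:
            re_s, im_s = ln.split()
            cur.append(complex(float(re_s), float(im_s)))
    if cur:
        fids.append(cur)
    return TransientSeries(
        fids=np.array(fids, dtype=complex),
        edit_labels=np.array(labels, dtype=object),
        acq=acq,
    )


def write_diff_spectrum(path: str | Path, diff: DiffSpectrum) -> None:
    if diff.acq is None:
        raise ValueError("diff spectrum lacks acquisition metadata")
    path = Path(path)
    out = [_MAGIC, "# domain=freq"] + _acq_header(diff.acq)
    out.append(f"# n_kept={diff.n_kept}")
    out.append(f"# n_rejected={diff.n_rejected}")
    out.append("> 0 DIFF")
    out.extend(f"{v.real:.17g} {v.imag:.17g}" for v in diff.values)
    path.write_text("\n".join(out) + "\n")


def read_diff_spectrum(path: str | Path) -> DiffSpectrum:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _MAGIC:
        raise ValueError(f"{path}: not a megabold FID file")
    meta = _parse_header(lines)
    if meta.get("domain") != "freq":
        raise ValueError(f"{path}: expected a frequency-domain file")
    acq = AcquisitionSpec(
        dwell_time=float(meta["dwell_time"]),
        transmitter_freq=float(meta["transmitter_freq"]),
        n_points=int(meta["n_points"]),
        n_transient_pairs=int(meta.get("n_transient_pairs", 1)),
        tr=float(meta.get("tr", 2.0)),
    )
    vals = [
        complex(float(a), float(b))
        for a, b in (
            ln.split() for ln in lines
            if ln and not ln.startswith(("#", ">"))
        )
    ]
    from .mrs_prep import ppm_axis

    return DiffSpectrum(
        values=np.array(vals),
        ppm_axis=ppm_axis(acq),
        n_kept=int(meta.get("n_kept", 0)),
        n_rejected=int(meta.get("n_rejected", 0)),
        acq=acq,
    )


def write_nifti(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine),
             str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n"
    )


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
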