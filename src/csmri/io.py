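"""Serialization shared by the CLI: HDF5 bundles, CSV, PNG, NIfTI, JSON.

HDF5 bundle layout (schema 1)
-----------------------------
``/image``         real 2-D phantom / reference image
``/mask``          uint8 sampling mask (zero-frequency-centred layout)
``/kspace_real``   real part of the observed k-space grid
``/kspace_imag``   imaginary part of the observed k-space grid
``/recon``         real 2-D reconstruction
``/trace``         per-iteration objective values
``/meta``          attrs: schema, noise_level, seed, dialect, fraction,
                   mask_convention ("centered"), plus solver metadata

All datasets are optional; writers only create what they have.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from csmri.phantom import SyntheticAcquisition
from csmri.sensing import SamplingMask

SCHEMA_VERSION = 1


def save_bundle(
    path: str | Path,
    image: np.ndarray | None = None,
    mask: SamplingMask | None = None,
    kspace: np.ndarray | None = None,
    recon: np.ndarray | None = None,
    trace: np.ndarray | None = None,
    meta: dict | None = None,
) -> None:
    """Write (a subset of) the bundle datasets plus metadata attributes."""
    with h5py.File(path, "w") as f:
        if image is not None:
            f.create_dataset("image", data=np.asarray(image, dtype=float))
        if mask is not None:
            f.create_dataset("mask", data=mask.grid.astype(np.uint8))
        if kspace is not None:
            k = np.asarray(kspace)
            f.create_dataset("kspace_real", data=k.real)
            f.create_dataset("kspace_imag", data=k.imag)
        if recon is not None:
            f.create_dataset("recon", data=np.asarray(recon, dtype=float))
        if trace is not None:
            f.create_dataset("trace", data=np.asarray(trace, dtype=float))
        g = f.create_group("meta")
        g.attrs["schema"] = SCHEMA_VERSION
        g.attrs["mask_convention"] = "centered"
        if mask is not None:
            g.attrs["dialect"] = mask.dialect
            g.attrs["fraction"] = mask.fraction
            g.attrs["mask_seed"] = mask.seed
        for key, value in (meta or {}).items():
            g.attrs[key] = value


def load_bundle(path: str | Path) -> dict:
    """Read every dataset present in a bundle into a plain dict."""
    out: dict = {"meta": {}}
    with h5py.File(path, "r") as f:
        for name in ("image", "mask", "recon", "trace"):
            if name in f:
                out[name] = f[name][()]
        if "kspace_real" in f:
            out["kspace"] = f["kspace_real"][()] + 1j * f["kspace_imag"][()]
        if "meta" in f:
            out["meta"] = {k: v for k, v in f["meta"].attrs.items()}
    if "mask" in out and "dialect" in out["meta"]:
        out["mask_obj"] = SamplingMask(
            grid=out["mask"].astype(bool),
            dialect=str(out["meta"]["dialect"]),
            fraction=float(out["meta"]["fraction"]),
            seed=int(out["meta"].get("mask_seed", 0)),
        )
    return out


def save_acquisition(path: str | Path, acq: SyntheticAcquisition) -> None:
    save_bundle(
        path,
        image=acq.true_image,
        mask=acq.mask,
        kspace=acq.kspace_observed,
        meta={"noise_level": acq.noise_level, "seed": acq.seed},
    )


def load_acquisition(path: str | Path) -> SyntheticAcquisition:
    data = load_bundle(path)
    for required in ("image", "mask_obj", "kspace"):
        if required not in data:
            raise ValueError(f"bundle {path} lacks {required!r}; not an acquisition")
    return SyntheticAcquisition(
        true_image=data["image"],
        mask=data["mask_obj"],
        kspace_observed=data["kspace"],
        noise_level=float(data["meta"].get("noise_level", 0.0)),
        seed=int(data["meta"].get("seed", 0)),
    )


# --------------------------------------------------------------------------
# image exports
# --------------------------------------------------------------------------

def export_png(path: str | Path, image: np.ndarray) -> None:
    """8-bit min-max scaled PNG export."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    scaled = np.zeros_like(image) if hi == lo else (image - lo) / (hi - lo)
    Image.fromarray((scaled * 255).round().astype(np.uint8)).save(path)


def export_nifti(path: str | Path, image: np.ndarray) -> None:
    """Single 2-D slice as a NIfTI volume with identity affine."""
    vol = np.asarray(image, dtype=float)[:, :, None]
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


# --------------------------------------------------------------------------
# matrices as CSV (complex entries "a+bi")
# --------------------------------------------------------------------------

def _format_complex(z: complex) -> str:
    return f"{z.real:.17g}{z.imag:+.17g}i"


def _parse_complex(token: str) -> complex:
    token = token.strip()
    if token.endswith("i"):
        return complex(token[:-1].replace("i", "j") + "j")
    return complex(float(token))


def save_matrix_csv(path: str | Path, matrix: np.ndarray) -> None:
    """One matrix row per line; entries formatted ``a+bi``."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=complex))
    lines = [",".join(_format_complex(z) for z in row) for row in matrix]
    Path(path).write_text("\n".join(lines) + "\n")


def load_matrix_csv(path: str | Path) -> np.ndarray:
    rows = []
    for line in Path(path).read_text().strip().splitlines():
        rows.append([_parse_complex(tok) for tok in line.split(",")])
    matrix = np.asarray(rows, dtype=complex)
    if np.allclose(matrix.imag, 0.0):
        return matrix.real
    return matrix


# --------------------------------------------------------------------------
# cohorts and reports
# --------------------------------------------------------------------------

def save_cohort_csv(path: str | Path, records) -> None:
    from csmri.clinical_end import cohort_to_dataframe

    cohort_to_dataframe(records).to_csv(path, index=False)


def load_cohort_csv(path: str | Path):
    from csmri.clinical_end import dataframe_to_cohort

    return dataframe_to_cohort(pd.read_csv(path, keep_default_na=False))


def save_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
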