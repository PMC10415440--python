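"""File formats: NIfTI echo stacks and maps, JSON sidecars, DICOM reading.

Complex echo series are persisted as a pair of NIfTI-1 volumes (real and
imaginary parts, spatial axes first, echoes last) plus a JSON sidecar
holding the echo times and acquisition parameters:

    <stem>_real.nii, <stem>_imag.nii, <stem>.json with
    {"schema_version": 1, "echo_times_s": [...],
     "acquisition": {"te1_s": ..., "delta_te_s": ..., "n_echoes": ...,
                     "field_strength_t": ...}}

Parameter maps use one NIfTI per quantity plus a sidecar.  DICOM series
reading is an optional capability for measured data: files are grouped by
EchoTime and combined from real/imaginary (or magnitude/phase) components.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .signal_model import (
    AcquisitionParams,
    EchoSeries,
    ParameterMaps,
    PdffMap,
    ValidationError,
)

__all__ = [
    "SchemaError",
    "write_echoes",
    "read_echoes",
    "write_maps",
    "read_maps",
    "write_pdff",
    "read_dicom_series",
    "write_manifest",
    "read_manifest",
    "config_hash",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class SchemaError(ValidationError):
    """A file or sidecar does not match the documented schema."""


def _save_nifti(arr: np.ndarray, path: Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr, np.float64), np.eye(4)), str(path))


def _load_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# echo series
# ---------------------------------------------------------------------------


def write_echoes(series: EchoSeries, stem) -> None:
    """Write ``<stem>_real.nii``, ``<stem>_imag.nii`` and ``<stem>.json``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    # spatial axes first for NIfTI viewers; echoes on the last axis
    vol = np.moveaxis(series.data, 0, -1)
    _save_nifti(vol.real, stem.with_name(stem.name + "_real.nii"))
    _save_nifti(vol.imag, stem.with_name(stem.name + "_imag.nii"))
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "echo_times_s": list(series.echo_times_s),
        "acquisition": {
            "te1_s": series.acquisition.te1_s,
            "delta_te_s": series.acquisition.delta_te_s,
            "n_echoes": series.acquisition.n_echoes,
            "field_strength_t": series.acquisition.field_strength_t,
        },
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_echoes(stem) -> EchoSeries:
    """Read an echo series written by :func:`write_echoes`.

    A missing imaginary volume (legacy real-only data) is zero-filled with
    a warning; a missing or incomplete sidecar raises :class:`SchemaError`
    naming the absent field.
    """
    stem = Path(stem)
    sidecar_path = stem.with_suffix(".json")
    if not sidecar_path.exists():
        raise SchemaError(f"missing metadata sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for fld in ("echo_times_s", "acquisition"):
        if fld not in sidecar:
            raise SchemaError(f"sidecar missing field {fld!r}")
    acq_d = sidecar["acquisition"]
    for fld in ("te1_s", "delta_te_s", "n_echoes"):
        if fld not in acq_d:
            raise SchemaError(f"acquisition block missing field {fld!r}")
    acq = AcquisitionParams(
        te1_s=acq_d["te1_s"],
        delta_te_s=acq_d["delta_te_s"],
        n_echoes=acq_d["n_echoes"],
        field_strength_t=acq_d.get("field_strength_t", 1.5),
    )
    real = _load_nifti(stem.with_name(stem.name + "_real.nii"))
    imag_path = stem.with_name(stem.name + "_imag.nii")
    if imag_path.exists():
        imag = _load_nifti(imag_path)
    else:
        warnings.warn(f"{imag_path} not found; zero-filling imaginary channel")
        imag = np.zeros_like(real)
    data = np.moveaxis(real + 1j * imag, -1, 0)
    return EchoSeries(data=data, echo_times_s=sidecar["echo_times_s"], acquisition=acq)


# ---------------------------------------------------------------------------
# parameter maps / PDFF
# ---------------------------------------------------------------------------

_MAP_FILES = {
    "water_real": lambda m: m.water.real,
    "water_imag": lambda m: m.water.imag,
    "fat_real": lambda m: m.fat.real,
    "fat_imag": lambda m: m.fat.imag,
    "r2star_per_s": lambda m: m.r2star_per_s,
    "fieldmap_hz": lambda m: m.fieldmap_hz,
    "mask": lambda m: m.mask.astype(np.float64),
}


def write_maps(maps: ParameterMaps, stem) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    for name, getter in _MAP_FILES.items():
        _save_nifti(getter(maps), stem.with_name(f"{stem.name}_{name}.nii"))
    stem.with_suffix(".json").write_text(
        json.dumps({"schema_version": SCHEMA_VERSION, "kind": "parameter_maps"}, indent=2)
    )


def read_maps(stem) -> ParameterMaps:
    stem = Path(stem)
    arrays = {}
    for name in _MAP_FILES:
        path = stem.with_name(f"{stem.name}_{name}.nii")
        if not path.exists():
            raise SchemaError(f"missing map volume {path}")
        arrays[name] = _load_nifti(path)
    return ParameterMaps(
        water=arrays["water_real"] + 1j * arrays["water_imag"],
        fat=arrays["fat_real"] + 1j * arrays["fat_imag"],
        r2star_per_s=arrays["r2star_per_s"],
        fieldmap_hz=arrays["fieldmap_hz"],
        mask=arrays["mask"] > 0.5,
    )


def write_pdff(pdff: PdffMap, stem) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    _save_nifti(pdff.values, stem.with_name(stem.name + "_pdff.nii"))
    _save_nifti(pdff.mask.astype(np.float64), stem.with_name(stem.name + "_pdff_mask.nii"))


# ---------------------------------------------------------------------------
# DICOM (optional, read-only)
# ---------------------------------------------------------------------------


def read_dicom_series(directory, field_strength_t: float = 1.5) -> EchoSeries:
    """Assemble a complex echo series from a directory of 2-D DICOM files.

    Files are grouped and sorted by their EchoTime tag (ms); within each
    echo the complex image is built from real/imaginary components (image
    type containing "REAL"/"IMAGINARY") or magnitude/phase pairs ("M"/"P",
    phase scaled to radians from its stored range).  A lone component per
    echo is treated as real-valued.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise SchemaError(f"no files in {directory}")
    by_echo: dict[float, dict[str, np.ndarray]] = {}
    for path in files:
        ds = pydicom.dcmread(str(path))
        if "EchoTime" not in ds:
            raise SchemaError(f"{path.name}: missing EchoTime tag")
        te = float(ds.EchoTime)
        image_type = [s.upper() for s in getattr(ds, "ImageType", [])]
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + inter
        if any("REAL" in t for t in image_type):
            comp = "real"
        elif any("IMAG" in t for t in image_type):
            comp = "imag"
        elif any(t == "P" or "PHASE" in t for t in image_type):
            comp = "phase"
        elif any(t == "M" or "MAGNITUDE" in t for t in image_type):
            comp = "mag"
        else:
            comp = "real"
        by_echo.setdefault(te, {})[comp] = arr

    tes_ms = sorted(by_echo)
    images = []
    for te in tes_ms:
        comps = by_echo[te]
        if "real" in comps or "imag" in comps:
            re = comps.get("real")
            im = comps.get("imag")
            if im is None:
                warnings.warn(f"echo at {te} ms is real-only; zero-filling imaginary part")
                im = np.zeros_like(re)
            if re is None:
                re = np.zeros_like(im)
            images.append(re + 1j * im)
        elif "mag" in comps and "phase" in comps:
            images.append(comps["mag"] * np.exp(1j * comps["phase"]))
        elif "mag" in comps:
            images.append(comps["mag"].astype(np.complex128))
        else:
            raise SchemaError(f"echo at {te} ms has no reconstructable components")
    data = np.stack(images)

    tes_s = np.asarray(tes_ms) * 1e-3
    if len(tes_s) > 1:
        deltas = np.diff(tes_s)
        delta = float(deltas.mean())
        if not np.allclose(deltas, delta, rtol=1e-3):
            raise SchemaError("echo times are not uniformly spaced")
    else:
        delta = 1e-3  # single echo: spacing is undefined; nominal placeholder
    acq = AcquisitionParams(
        te1_s=float(tes_s[0]),
        delta_te_s=delta,
        n_echoes=len(tes_s),
        field_strength_t=field_strength_t,
    )
    return EchoSeries(data=data, echo_times_s=tuple(tes_s), acquisition=acq)


# ---------------------------------------------------------------------------
# dataset manifests
# ---------------------------------------------------------------------------


def write_manifest(directory, records: list, config: dict, seed: int) -> None:
    """Write ``manifest.json`` describing a dataset directory.

    ``records`` is a list of per-slice dicts (paths relative to the
    directory, seeds); the manifest stores the generating config and its
    hash for reproducibility checks.
    """
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "slices": records,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_manifest(directory, verify: bool = True) -> dict:
    directory = Path(directory)
    path = directory / "manifest.json"
    if not path.exists():
        raise SchemaError(f"missing manifest.json in {directory}")
    manifest = json.loads(path.read_text())
    for fld in ("schema_version", "config", "config_hash", "slices"):
        if fld not in manifest:
            raise SchemaError(f"manifest missing field {fld!r}")
    if manifest["config_hash"] != config_hash(manifest["config"]):
        raise SchemaError("manifest config hash does not verify")
    if verify:
        for rec in manifest["slices"]:
            for key in ("echoes", "maps"):
                if key in rec:
                    sidecar = (directory / rec[key]).with_suffix(".json")
                    if not sidecar.exists():
                        raise SchemaError(f"manifest references missing {sidecar}")
    return manifest
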