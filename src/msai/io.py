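"""Readers and writers: scheme JSON, SH coefficient volumes, output maps.

Formats
-------
* Acquisition scheme: JSON with keys ``b0_directions`` (list of unit
  3-vectors), ``echo_times_ms`` (increasing), ``reference_time_ms``,
  ``echo_mask`` (booleans, optional).  Field directions are expressed in
  the same world frame as the NIfTI affine — the field direction rotates
  between head positions rather than the image being resampled.
* ODF volumes: 4D NIfTI with 45 coefficient volumes in the documented
  ordering (degrees ascending, orders −l…l), plus a JSON sidecar recording
  the basis convention and maximum degree.
* Output maps are stored in Hz (ω/(2π)); all internal computation is in
  rad/s, converted only at this boundary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fdm import AcquisitionScheme
from .odf import N_COEFFS, ODF

__all__ = [
    "read_scheme",
    "write_scheme",
    "read_sh_volume",
    "write_sh_volume",
    "write_maps",
    "SH_SIDECAR",
]

logger = logging.getLogger("msai")

#: Basis metadata written next to every SH coefficient volume.
SH_SIDECAR = {
    "basis": "real-orthonormal",
    "parity": "even",
    "max_order": 8,
    "ordering": "degrees ascending; orders -l..l within degree",
    "n_coefficients": N_COEFFS,
}

#: b0 vectors whose norm deviates more than this are rejected outright;
#: smaller deviations are renormalized (and logged).
_B0_NORM_TOL = 1e-3


def read_scheme(path: str | Path) -> AcquisitionScheme:
    """Read an acquisition scheme from JSON (see module docstring for keys)."""
    with open(path) as fh:
        payload = json.load(fh)
    required = {"b0_directions", "echo_times_ms", "reference_time_ms"}
    missing = required - payload.keys()
    if missing:
        raise ValueError(f"scheme file {path} is missing keys: {sorted(missing)}")
    b0 = np.asarray(payload["b0_directions"], dtype=float)
    b0 = np.atleast_2d(b0)
    norms = np.linalg.norm(b0, axis=1)
    if np.any(np.abs(norms - 1.0) > _B0_NORM_TOL):
        raise ValueError(
            f"b0 directions in {path} deviate from unit norm by more than "
            f"{_B0_NORM_TOL}: norms {norms}"
        )
    if np.any(np.abs(norms - 1.0) > 1e-12):
        logger.info("renormalizing b0 directions (max deviation %.2e)",
                    float(np.abs(norms - 1.0).max()))
        b0 = b0 / norms[:, None]
    mask = payload.get("echo_mask")
    return AcquisitionScheme(
        b0_directions=b0,
        echo_times_ms=np.asarray(payload["echo_times_ms"], dtype=float),
        reference_time_ms=float(payload["reference_time_ms"]),
        echo_mask=None if mask is None else np.asarray(mask, dtype=bool),
    )


def write_scheme(scheme: AcquisitionScheme, path: str | Path) -> None:
    payload = {
        "b0_directions": scheme.b0_directions.tolist(),
        "echo_times_ms": scheme.echo_times_ms.tolist(),
        "reference_time_ms": float(scheme.reference_time_ms),
        "echo_mask": scheme.echo_mask.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def write_sh_volume(
    coeffs: np.ndarray, path: str | Path, affine: np.ndarray | None = None
) -> None:
    """Write a (X, Y, Z, 45) SH coefficient volume plus its JSON sidecar."""
    coeffs = np.asarray(coeffs)
    if coeffs.ndim != 4 or coeffs.shape[3] != N_COEFFS:
        raise ValueError(
            f"expected a 4D volume with {N_COEFFS} coefficient maps, "
            f"got shape {coeffs.shape}"
        )
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(coeffs.astype(np.float32), affine), str(path))
    with open(_sidecar_path(path), "w") as fh:
        json.dump(SH_SIDECAR, fh, indent=1)


def read_sh_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an SH coefficient volume; returns ``(coeffs, affine)``.

    The 4th dimension must hold exactly 45 coefficient volumes and the JSON
    sidecar declaring the basis convention must be present.
    """
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(
            f"missing sidecar {sidecar}; SH volumes must declare their basis "
            "convention"
        )
    with open(sidecar) as fh:
        meta = json.load(fh)
    if meta.get("n_coefficients") != N_COEFFS:
        raise ValueError(
            f"sidecar declares {meta.get('n_coefficients')} coefficients; "
            f"expected {N_COEFFS}"
        )
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != N_COEFFS:
        raise ValueError(
            f"SH volume {path} has shape {data.shape}; expected 45 coefficient "
            f"volumes (order-8 even basis) in the 4th dimension"
        )
    return data, np.asarray(img.affine)


def odfs_from_volume(coeffs: np.ndarray, mask: np.ndarray | None = None) -> list[ODF]:
    """Flatten a coefficient volume into per-voxel ODFs (row-major order)."""
    flat = coeffs.reshape(-1, coeffs.shape[-1])
    if mask is not None:
        flat = flat[np.asarray(mask, dtype=bool).ravel()]
    return [ODF(c) for c in flat]


def write_maps(
    result,
    path_prefix: str | Path,
    grid_shape: tuple[int, int, int],
    affine: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write a :class:`~msai.fit.MicroShiftResult` as NIfTI maps + CSV table.

    Microscopic shift maps are stored in Hz (ω̃/(2π)), one 4D volume over
    fitted echoes; the residual map likewise.  Offsets, when present, go to
    ``<prefix>_offsets.csv`` with columns position, echo_ms,
    offset_rad_per_s.
    """
    if affine is None:
        affine = np.eye(4)
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    hz = result.omega_A_hat / (2.0 * np.pi)
    shape4 = (*grid_shape, hz.shape[1])
    hz_path = prefix.parent / (prefix.name + "_microshift_hz.nii.gz")
    nib.save(nib.Nifti1Image(hz.reshape(shape4).astype(np.float32), affine),
             str(hz_path))
    written["microshift_hz"] = hz_path
    resid_path = prefix.parent / (prefix.name + "_residual.nii.gz")
    nib.save(
        nib.Nifti1Image(
            result.residual.reshape(shape4).astype(np.float32), affine
        ),
        str(resid_path),
    )
    written["residual"] = resid_path
    if result.gfactor is not None:
        g_path = prefix.parent / (prefix.name + "_gfactor.nii.gz")
        nib.save(
            nib.Nifti1Image(
                np.asarray(result.gfactor, dtype=np.float32).reshape(grid_shape),
                affine,
            ),
            str(g_path),
        )
        written["gfactor"] = g_path
    if result.offsets is not None:
        rows = []
        for p in range(result.offsets.shape[0]):
            for e, t_ms in enumerate(result.echo_times_ms):
                rows.append(
                    {"position": p, "echo_ms": float(t_ms),
                     "offset_rad_per_s": float(result.offsets[p, e])}
                )
        csv_path = prefix.parent / (prefix.name + "_offsets.csv")
        pd.DataFrame(rows).to_csv(csv_path, index=False)
        written["offsets"] = csv_path
    return written
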