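"""Volume, table and configuration IO.

Volumes and masks travel as NIfTI (``.nii``/``.nii.gz``, via nibabel) or
MetaImage (``.mha``/``.mhd``, via SimpleITK) with spacing and origin in the
header; axis order in memory is (LR, AP, SI). Tabular data (matches,
landmarks, gold standards, workflow outcomes, errors) travels as headed CSV
with fixed column schemas, all world quantities in mm, serialized with 10
significant digits so round-trips are lossless at float precision.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .grids import BinaryMask3D, VoxelGrid3D

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "read_table",
    "write_table",
    "TABLE_SCHEMAS",
    "load_config",
    "validate_config",
    "config_hash",
    "IOError3D",
]


class IOError3D(ValueError):
    """Raised on unreadable, non-3D or schema-violating inputs."""


_NIFTI_EXTS = (".nii", ".nii.gz")
_META_EXTS = (".mha", ".mhd")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_EXTS)


def _is_meta(path: Path) -> bool:
    return path.suffix in _META_EXTS


def write_volume(vol: VoxelGrid3D, path) -> None:
    """Write a volume as NIfTI or MetaImage, preserving spacing and origin."""
    path = Path(path)
    values = np.asarray(vol.values)
    out_dtype = np.uint8 if values.dtype == bool else np.float32
    if _is_nifti(path):
        affine = np.diag([*vol.spacing_mm, 1.0])
        affine[:3, 3] = vol.origin_mm
        nib.save(nib.Nifti1Image(values.astype(out_dtype), affine), str(path))
    elif _is_meta(path):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(
            np.ascontiguousarray(values.astype(out_dtype).transpose(2, 1, 0))
        )
        img.SetSpacing(tuple(float(s) for s in vol.spacing_mm))
        img.SetOrigin(tuple(float(o) for o in vol.origin_mm))
        sitk.WriteImage(img, str(path), useCompression=True)
    else:
        raise IOError3D(f"unsupported volume format: {path.name}")


def read_volume(path) -> VoxelGrid3D:
    """Read a NIfTI or MetaImage volume with its geometry."""
    path = Path(path)
    if not path.exists():
        raise IOError3D(f"volume file not found: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        values = np.asanyarray(img.dataobj)
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
    elif _is_meta(path):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise IOError3D(f"expected a 3D volume, got {img.GetDimension()}D")
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = np.asarray(img.GetSpacing(), dtype=float)
        origin = np.asarray(img.GetOrigin(), dtype=float)
    else:
        raise IOError3D(f"unsupported volume format: {path.name}")
    if values.ndim != 3:
        raise IOError3D(f"expected a 3D volume, got shape {values.shape}")
    if np.any(spacing <= 0):
        raise IOError3D(f"non-positive voxel spacing in header: {spacing}")
    return VoxelGrid3D(np.asarray(values), spacing_mm=spacing, origin_mm=origin)


def read_mask(path) -> BinaryMask3D:
    vol = read_volume(path)
    return BinaryMask3D(vol.values > 0, spacing_mm=vol.spacing_mm,
                        origin_mm=vol.origin_mm)


TABLE_SCHEMAS = {
    "landmarks": ["patient_id", "fraction", "landmark_id", "x_lr_mm", "y_ap_mm",
                  "z_si_mm"],
    "shifts": ["patient_id", "fraction", "dx_lr_mm", "dy_ap_mm", "dz_si_mm"],
    "matches": ["patient_id", "fraction", "method", "dx_lr_mm", "dy_ap_mm",
                "dz_si_mm", "peak_score", "time_s", "flags"],
    "gold": ["patient_id", "fraction", "dx_lr_mm", "dy_ap_mm", "dz_si_mm",
             "n_rounds", "converged"],
    "outcomes": ["patient_id", "fraction", "observer_id", "workflow",
                 "source_method", "dx_lr_mm", "dy_ap_mm", "dz_si_mm",
                 "total_time_s", "n_attempts"],
    "errors": ["patient_id", "fraction", "method", "e_lr_mm", "e_ap_mm",
               "e_si_mm"],
}


def _check_schema(columns, kind: str) -> None:
    if kind not in TABLE_SCHEMAS:
        raise IOError3D(f"unknown table kind {kind!r}")
    expected = TABLE_SCHEMAS[kind]
    missing = [c for c in expected if c not in columns]
    extra = [c for c in columns if c not in expected]
    if missing or extra:
        raise IOError3D(
            f"{kind} table schema mismatch: missing columns {missing}, "
            f"unexpected columns {extra}"
        )


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    _check_schema(list(df.columns), kind)
    df = df[TABLE_SCHEMAS[kind]]
    df.to_csv(path, index=False, float_format="%.10g")


def read_table(path, kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError3D(f"table file not found: {path}")
    df = pd.read_csv(path)
    _check_schema(list(df.columns), kind)
    return df


# --- configuration ---------------------------------------------------------

_CONFIG_KEYS = {
    "phantom": {
        "grid_shape", "voxel_mm", "prostate_semi_axes_mm", "prostate_center_mm",
        "echo_background", "echo_prostate", "n_landmarks", "landmark_amp",
        "landmark_sigma_mm", "psf_sigma_mm", "edge_mm", "seed",
    },
    "cohort": {
        "n_patients", "n_fractions", "shift_sd_mm", "train_fraction_of_patients",
        "gain_range", "decorrelation_rho", "shift_trunc_mm",
    },
    "registration": {
        "lambda_reg", "smooth_sigma_vox", "window_margin_vox", "max_shift_mm",
        "subvoxel", "low_score_threshold",
    },
    "gold": {"landmark_noise_sd_mm", "n_observers", "threshold_mm", "max_repeats"},
    "observers": None,  # list of observer mappings, validated separately
    "clarity": {"sd_mm", "match_time_s", "seed"},
    "workflow": {"mode", "split"},
}
_OBSERVER_KEYS = {
    "observer_id", "p_reject_auto", "p_reject_semi", "decision_mode",
    "score_threshold", "time_model", "seed",
}


def validate_config(config: dict) -> dict:
    """Reject unknown sections or keys; return the config unchanged."""
    if not isinstance(config, dict):
        raise IOError3D("config root must be a mapping")
    for section, content in config.items():
        if section not in _CONFIG_KEYS:
            raise IOError3D(f"unknown config section {section!r}")
        allowed = _CONFIG_KEYS[section]
        if allowed is None:
            if not isinstance(content, list):
                raise IOError3D("config section 'observers' must be a list")
            for obs in content:
                bad = set(obs) - _OBSERVER_KEYS
                if bad:
                    raise IOError3D(f"unknown observer keys {sorted(bad)}")
        else:
            bad = set(content or {}) - allowed
            if bad:
                raise IOError3D(
                    f"unknown keys {sorted(bad)} in config section {section!r}"
                )
    return config


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    return validate_config(config)


def config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
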