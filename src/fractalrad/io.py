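"""Reading and writing images, masks and cohort manifests.

Images and masks travel as 2D NIfTI files (via nibabel); single-frame
grayscale DICOM is supported read-only (via pydicom, when installed).
A cohort is a directory of image/mask pairs plus a CSV manifest with one
row per sample (columns ``sample_id, patient_id, label, image_path,
mask_path``, optionally the generating truth parameters).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import GrayImage, ROIMask

__all__ = [
    "read_gray_image",
    "write_nifti_image",
    "write_nifti_mask",
    "read_nifti_mask",
    "read_manifest",
]


def _affine(spacing: tuple[float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1] = spacing
    return aff


def write_nifti_image(image: GrayImage, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(image.pixels.astype(np.float32), _affine(image.spacing)), path)
    return path


def write_nifti_mask(
    mask: ROIMask, path: str | Path, spacing: tuple[float, float] = (1.0, 1.0)
) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.pixels.astype(np.uint8), _affine(spacing)), path)
    return path


def _load_nifti_2d(path: Path) -> tuple[np.ndarray, tuple[float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2D raster, got shape {data.shape}")
    zooms = img.header.get_zooms()[:2]
    return data, (float(zooms[0]), float(zooms[1]))


def read_gray_image(path: str | Path, id: str | None = None) -> GrayImage:
    """Read a 2D grayscale image from NIfTI (.nii/.nii.gz) or DICOM."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".ima") :
        import pydicom

        ds = pydicom.dcmread(str(path))
        data = ds.pixel_array.astype(float)
        if data.ndim == 3:  # RGB -> grayscale
            data = data.mean(axis=-1)
        spacing = tuple(float(v) for v in getattr(ds, "PixelSpacing", (1.0, 1.0)))
        return GrayImage(data, spacing=spacing, id=id or path.stem)
    data, spacing = _load_nifti_2d(path)
    return GrayImage(data.astype(float), spacing=spacing, id=id or path.name)


def read_nifti_mask(path: str | Path, provenance: str = "manual-seed") -> ROIMask:
    data, _ = _load_nifti_2d(Path(path))
    return ROIMask(data > 0, provenance=provenance)


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV.

    Paths are resolved relative to the manifest location; labels must be
    0 (ADC) or 1 (SCC); every referenced file must exist.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"sample_id", "patient_id", "label", "image_path", "mask_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = manifest_path.parent
    for idx, row in df.iterrows():
        if row["label"] not in (0, 1):
            raise ValueError(
                f"manifest row {idx} (sample {row['sample_id']}): "
                f"unknown label {row['label']!r} (expected 0=ADC or 1=SCC)"
            )
        for col in ("image_path", "mask_path"):
            p = base / row[col]
            if not p.exists():
                raise FileNotFoundError(
                    f"manifest row {idx} (sample {row['sample_id']}): missing {p}"
                )
    df["image_path"] = [str(base / p) for p in df["image_path"]]
    df["mask_path"] = [str(base / p) for p in df["mask_path"]]
    return df
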