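"""Read and write the stacks, masks, and tabular outputs the pipeline touches.

Conventions
-----------
- Voxel grids are ``(z, y, x)`` arrays, 0-based, with z equal to the TIFF
  page index.
- RI stacks are stored as physical values in 32-bit float multi-page TIFF;
  no integer scaling is applied.
- Voxel geometry travels in a JSON sidecar (``voxel_size_nm: [dz, dy, dx]``).
  A TIFF without a sidecar is only accepted when it carries ImageJ-style
  resolution metadata; otherwise reading fails loudly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "RIStack",
    "FluorStack",
    "MetadataError",
    "StackFormatError",
    "read_ri_stack",
    "read_fluor_stack",
    "write_stack",
    "write_mask",
    "read_mask",
    "write_results",
    "FINGERPRINT_COLUMNS",
    "DETECTION_COLUMNS",
    "COLOC_COLUMNS",
]


class MetadataError(IOError):
    """Voxel-size metadata is missing or malformed."""


class StackFormatError(IOError):
    """The pixel data cannot be interpreted as a numeric stack."""


def _as_volume(voxels: np.ndarray) -> np.ndarray:
    a = np.asarray(voxels)
    if a.ndim == 2:
        a = a[np.newaxis, ...]
    if a.ndim != 3:
        raise StackFormatError(f"expected a 2-D or 3-D array, got ndim={a.ndim}")
    return a.astype(np.float32, copy=False)


@dataclass
class RIStack:
    """A 3-D grid of refractive indices with anisotropic voxel geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Refractive-index values (dimensionless, typically 1.33-1.45).
    voxel_size : (dz, dy, dx)
        Voxel spacing in nanometres.
    provenance : str, optional
        Source path or phantom seed description.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    provenance: str | None = None

    def __post_init__(self) -> None:
        self.voxels = _as_volume(self.voxels)
        if not np.isfinite(self.voxels).all():
            raise StackFormatError("RI stack contains non-finite values")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise MetadataError(f"invalid voxel size {self.voxel_size!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class FluorStack:
    """A 3-D fluorescence-intensity grid (arbitrary units, >= 0)."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    provenance: str | None = None

    def __post_init__(self) -> None:
        self.voxels = _as_volume(self.voxels)
        if not np.isfinite(self.voxels).all():
            raise StackFormatError("fluorescence stack contains non-finite values")
        if (self.voxels < 0).any():
            raise StackFormatError("fluorescence stack contains negative intensities")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise MetadataError(f"invalid voxel size {self.voxel_size!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def sidecar_candidates(path: Path) -> list[Path]:
    """Sidecar search order for ``path``.

    ``stem.json`` first, then the shared ``<prefix>_meta.json`` used by the
    phantom writer for ``<prefix>_ri.tif`` / ``<prefix>_fl.tif`` pairs.
    """
    path = Path(path)
    cands = [path.with_suffix(".json")]
    stem = path.stem
    for suffix in ("_ri", "_fl", "_truth"):
        if stem.endswith(suffix):
            cands.append(path.with_name(stem[: -len(suffix)] + "_meta.json"))
    cands.append(path.with_name(stem + "_meta.json"))
    return cands


def _voxel_size_from_sidecar(path: Path, sidecar: Path | None) -> tuple[float, float, float] | None:
    cands = [Path(sidecar)] if sidecar is not None else sidecar_candidates(path)
    for cand in cands:
        if cand.is_file():
            meta = json.loads(cand.read_text())
            try:
                dz, dy, dx = meta["voxel_size_nm"]
            except (KeyError, TypeError, ValueError) as exc:
                raise MetadataError(f"sidecar {cand} lacks a voxel_size_nm triple") from exc
            return (float(dz), float(dy), float(dx))
    return None


def _voxel_size_from_tags(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    # ImageJ convention: XResolution in pixels per unit, spacing for z.
    ij = tif.imagej_metadata or {}
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    spacing = ij.get("spacing")
    if xres is None or yres is None or spacing is None:
        return None
    unit = ij.get("unit", "micron")
    scale = {"micron": 1e3, "um": 1e3, "µm": 1e3, "nm": 1.0}.get(unit)
    if scale is None:
        return None

    def per_pixel(tag) -> float:
        num, den = tag.value
        return den / num

    return (float(spacing) * scale, per_pixel(yres) * scale, per_pixel(xres) * scale)


def _read_stack(path, sidecar):
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        voxels = tif.asarray()
        voxel_size = _voxel_size_from_sidecar(path, sidecar)
        if voxel_size is None:
            voxel_size = _voxel_size_from_tags(tif)
    if voxel_size is None:
        raise MetadataError(
            f"no voxel-size metadata for {path}: provide a JSON sidecar "
            "with voxel_size_nm or ImageJ resolution tags"
        )
    if not np.issubdtype(voxels.dtype, np.number):
        raise StackFormatError(f"{path} holds non-numeric pixels ({voxels.dtype})")
    return voxels, voxel_size


def read_ri_stack(path, sidecar=None) -> RIStack:
    """Read a multi-page TIFF RI stack; page order is z order."""
    voxels, voxel_size = _read_stack(path, sidecar)
    return RIStack(voxels, voxel_size, provenance=str(path))


def read_fluor_stack(path, sidecar=None) -> FluorStack:
    """Read a multi-page TIFF fluorescence stack."""
    voxels, voxel_size = _read_stack(path, sidecar)
    return FluorStack(voxels, voxel_size, provenance=str(path))


def write_stack(stack: RIStack | FluorStack, path, extra_meta: Mapping | None = None) -> Path:
    """Write a stack as float32 multi-page TIFF plus a JSON sidecar.

    Returns the TIFF path; the sidecar lands at ``<path stem>.json`` unless
    the stem follows the ``*_ri`` / ``*_fl`` phantom convention, in which
    case the shared ``*_meta.json`` name is used.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.voxels.astype(np.float32), photometric="minisblack")
    meta = {"voxel_size_nm": list(stack.voxel_size)}
    if extra_meta:
        meta.update(extra_meta)
    if path.stem.endswith(("_ri", "_fl")):
        sidecar = path.with_name(path.stem[:-3] + "_meta.json")
    else:
        sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def write_mask(mask: np.ndarray, path) -> Path:
    """Write a boolean voxel mask as an 8-bit (0/255) multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)), photometric="minisblack")
    return path


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0


FINGERPRINT_COLUMNS = ("cell_id", "dose", "bin_lo", "percent")
DETECTION_COLUMNS = ("cell_id", "dose", "band_voxels", "band_percent", "n_components")
COLOC_COLUMNS = ("cell_id", "M1", "dice", "mean_fluor_au")


def _write_table(rows: Iterable[Mapping], columns: Sequence[str], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for row in rows:
            missing = [c for c in columns if c not in row]
            if missing:
                raise ValueError(f"row {row!r} is missing columns {missing} for {path.name}")
            out = []
            for col in columns:
                v = row[col]
                if isinstance(v, (float, np.floating)):
                    out.append(f"{float(v):.8g}")  # >= 6 significant digits
                else:
                    out.append(v)
            writer.writerow(out)


def write_results(fingerprints, detections, coloc, outdir) -> dict[str, Path]:
    """Write the three pipeline CSVs into ``outdir``.

    Each argument is an iterable of mappings with at least the columns of
    ``FINGERPRINT_COLUMNS`` / ``DETECTION_COLUMNS`` / ``COLOC_COLUMNS``
    respectively.  Empty iterables produce headers-only files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fingerprints": outdir / "fingerprints.csv",
        "detections": outdir / "detections.csv",
        "coloc": outdir / "coloc.csv",
    }
    _write_table(fingerprints, FINGERPRINT_COLUMNS, paths["fingerprints"])
    _write_table(detections, DETECTION_COLUMNS, paths["detections"])
    _write_table(coloc, COLOC_COLUMNS, paths["coloc"])
    return paths
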