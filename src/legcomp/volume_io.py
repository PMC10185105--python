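"""Multi-contrast volume containers, NIfTI I/O, stack stitching and slice-range selection.

A chemical-shift-encoded (Dixon) acquisition reconstructs co-registered
fat-weighted, water-weighted and in-phase contrasts.  Whole-body protocols
acquire several axially stacked volumes whose slice ranges overlap; the
overlapping duplicates must be removed before any per-slice analysis, and the
analyzed lower-extremity range (inferior ankle to superior thigh) is selected
manually from anatomical landmarks and passed in as slice indices.

Array convention: volumes are ``(n_slices, rows, cols)`` with slices ordered
inferior (ankle) -> superior (thigh); rows run anterior-posterior and columns
left-right with subject-left on image-right (radiological convention).
``voxel_spacing`` is ``(row_mm, col_mm, slice_mm)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CSEVolume",
    "StackSet",
    "stitch_stacks",
    "select_lower_extremity",
    "load_cse_volume",
    "save_cse_volume",
    "save_nifti",
    "load_nifti",
]


@dataclass
class CSEVolume:
    """Co-registered fat/water/in-phase intensity volumes on one grid."""

    fat: np.ndarray
    water: np.ndarray
    in_phase: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.fat = np.asarray(self.fat)
        self.water = np.asarray(self.water)
        self.in_phase = np.asarray(self.in_phase)
        if not (self.fat.shape == self.water.shape == self.in_phase.shape):
            raise ValueError(
                f"contrast shapes differ: fat {self.fat.shape}, "
                f"water {self.water.shape}, in-phase {self.in_phase.shape}"
            )
        if self.fat.ndim != 3 or self.fat.shape[0] < 1:
            raise ValueError("volumes must be 3D with at least one slice")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be three positive values, got {self.voxel_spacing}")
        for name in ("fat", "water", "in_phase"):
            arr = getattr(self, name)
            if arr.size and float(arr.min()) < 0:
                raise ValueError(f"{name} contrast contains negative intensities")

    @property
    def n_slices(self) -> int:
        return self.fat.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fat.shape

    def slice_contrasts(self, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return the (fat, water, in_phase) images of axial slice ``k``."""
        return self.fat[k], self.water[k], self.in_phase[k]


@dataclass
class StackSet:
    """Ordered axial acquisition stacks with physical slice-axis offsets (mm)."""

    stacks: Sequence[CSEVolume]
    offsets_mm: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.stacks) < 1:
            raise ValueError("at least one stack is required")
        if len(self.stacks) != len(self.offsets_mm):
            raise ValueError("one offset per stack is required")
        first = self.stacks[0]
        for s in self.stacks[1:]:
            if s.shape[1:] != first.shape[1:]:
                raise ValueError(
                    f"in-plane grid mismatch: {s.shape[1:]} vs {first.shape[1:]}"
                )
            if s.voxel_spacing != first.voxel_spacing:
                raise ValueError("stacks must share voxel spacing")
        offs = [float(o) for o in self.offsets_mm]
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("stack offsets must be strictly increasing")
        self.offsets_mm = offs


def stitch_stacks(stacks: StackSet) -> CSEVolume:
    """Concatenate overlapping stacks into one volume, dropping duplicate slices.

    Slices from neighboring stacks that land on the same physical position
    (within half the slice spacing) are duplicates; the copy from the more
    superior stack is kept.  A gap larger than one slice spacing between
    stacks is logged as a warning and the volumes are concatenated anyway.
    """
    dz = stacks.stacks[0].voxel_spacing[2]
    tol = 0.5 * dz
    # (position_mm, stack_index, slice_index); later stacks overwrite duplicates
    kept: list[tuple[float, int, int]] = []
    for si, (vol, off) in enumerate(zip(stacks.stacks, stacks.offsets_mm)):
        for j in range(vol.n_slices):
            pos = off + j * dz
            for ki, (kp, _, _) in enumerate(kept):
                if abs(kp - pos) < tol:
                    kept[ki] = (kp, si, j)  # keep-superior tie-break
                    break
            else:
                kept.append((pos, si, j))
    kept.sort(key=lambda t: t[0])
    positions = np.array([t[0] for t in kept])
    gaps = np.diff(positions)
    if np.any(gaps > dz + tol):
        logger.warning(
            "gap of %.1f mm between stacks exceeds one slice spacing; concatenating",
            float(gaps.max()),
        )
    spacing = stacks.stacks[0].voxel_spacing
    pick = lambda attr: np.stack(
        [getattr(stacks.stacks[si], attr)[j] for _, si, j in kept]
    )
    return CSEVolume(pick("fat"), pick("water"), pick("in_phase"), spacing)


def select_lower_extremity(volume: CSEVolume, lower_slice: int, upper_slice: int) -> CSEVolume:
    """Inclusive sub-volume from the ankle landmark to the thigh landmark.

    ``lower_slice`` (inferior ankle) and ``upper_slice`` (superior thigh) are
    indices in the inferior->superior slice ordering; both ends are kept.
    """
    n = volume.n_slices
    if not (0 <= lower_slice < n and 0 <= upper_slice < n):
        raise ValueError(f"landmark indices ({lower_slice}, {upper_slice}) out of range for {n} slices")
    if lower_slice > upper_slice:
        raise ValueError(f"lower landmark {lower_slice} is above upper landmark {upper_slice}")
    sl = slice(lower_slice, upper_slice + 1)
    return CSEVolume(
        volume.fat[sl], volume.water[sl], volume.in_phase[sl], volume.voxel_spacing
    )


# ---------------------------------------------------------------------------
# NIfTI I/O.  Arrays are stored (slices, rows, cols) in memory and written
# (rows, cols, slices) on disk so the file's third axis is the slice axis.
# ---------------------------------------------------------------------------

def _affine(spacing: Sequence[float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_nifti(array: np.ndarray, voxel_spacing: Sequence[float], path: str | Path) -> None:
    """Write a ``(slices, rows, cols)`` array as NIfTI with spacing in the header."""
    data = np.transpose(np.asarray(array), (1, 2, 0))
    img = nib.Nifti1Image(data, _affine(voxel_spacing))
    img.header.set_zooms(tuple(float(s) for s in voxel_spacing))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI file; returns ``(slices, rows, cols)`` data and spacing."""
    img = nib.load(str(path))
    data = np.transpose(np.asanyarray(img.dataobj), (2, 0, 1))
    zooms = img.header.get_zooms()[:3]
    return data, (float(zooms[0]), float(zooms[1]), float(zooms[2]))


def load_cse_volume(fat: str | Path, water: str | Path, in_phase: str | Path) -> CSEVolume:
    """Load the three contrasts of one acquisition from NIfTI files."""
    fat_arr, spacing = load_nifti(fat)
    water_arr, sp_w = load_nifti(water)
    ip_arr, sp_i = load_nifti(in_phase)
    if not (np.allclose(spacing, sp_w) and np.allclose(spacing, sp_i)):
        raise ValueError("contrast files disagree on voxel spacing")
    return CSEVolume(fat_arr, water_arr, ip_arr, spacing)


def save_cse_volume(volume: CSEVolume, out_dir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write fat/water/in-phase contrasts as ``<prefix><name>.nii.gz`` files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (("fat", volume.fat), ("water", volume.water), ("inphase", volume.in_phase)):
        p = out / f"{prefix}{name}.nii.gz"
        save_nifti(arr, volume.voxel_spacing, p)
        paths[name] = p
    return paths
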