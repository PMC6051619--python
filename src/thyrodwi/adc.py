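"""Apparent-diffusion-coefficient (ADC) mapping from multi-b-value DWI.

The signal of a diffusion-weighted acquisition follows, to first order, a
mono-exponential decay ``S(b) = S0 * exp(-b * ADC)`` where ``b`` is the
diffusion weighting in sec/mm^2 and ADC the apparent diffusion coefficient
in mm^2/sec.  Maps are reconstructed from subsets of the acquired b-values
(here b = 0, 800, 2000 sec/mm^2): a two-point subset inverts the decay in
closed form, three or more points use an ordinary least-squares line fit of
``ln S`` against ``b``.  No smoothing or noise filtering is applied.

ADC values are stored and reported in units of 1e-3 mm^2/sec, the scale on
which clinical thyroid thresholds (e.g. 1.16) are quoted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "BValueSet",
    "DWISeries",
    "ADCMap",
    "fit_adc_voxel",
    "compute_adc_map",
    "SUBSETS",
]


@dataclass(frozen=True)
class BValueSet:
    """An ordered subset of acquired b-values used for one ADC map."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise ValueError("a b-value subset needs at least two b-values")
        if len(set(vals)) != len(vals):
            raise ValueError(f"b-values must be unique, got {vals}")
        if any(v < 0 for v in vals):
            raise ValueError(f"b-values must be non-negative, got {vals}")
        if list(vals) != sorted(vals):
            raise ValueError(f"b-values must be ascending, got {vals}")
        if vals[0] != 0.0:
            raise ValueError(f"b-value subset must contain b=0, got {vals}")

    @property
    def label(self) -> str:
        return "b" + "-".join(f"{v:g}" for v in self.values)

    @classmethod
    def from_label(cls, label: str) -> "BValueSet":
        """Parse labels of the form ``b0-800-2000``."""
        if not label.startswith("b"):
            raise ValueError(f"bad subset label {label!r}")
        return cls(tuple(float(tok) for tok in label[1:].split("-")))


#: The three map subsets reconstructed in the thyroid protocol.
SUBSETS: dict[str, BValueSet] = {
    "b0-800": BValueSet((0, 800)),
    "b0-2000": BValueSet((0, 2000)),
    "b0-800-2000": BValueSet((0, 800, 2000)),
}


@dataclass
class DWISeries:
    """Per-b-value 3D signal volumes with shared geometry.

    Parameters
    ----------
    volumes
        Mapping from b-value (sec/mm^2) to a 3D magnitude-signal array.
    voxel_size_mm
        In-plane and through-plane voxel dimensions (dx, dy, dz) in mm.
    affine
        Optional 4x4 voxel-to-world matrix; a diagonal one is built from
        ``voxel_size_mm`` when absent.
    """

    volumes: dict[float, np.ndarray]
    voxel_size_mm: tuple[float, float, float] = (0.68, 0.68, 3.3)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.volumes = {float(b): np.asarray(v, dtype=float) for b, v in self.volumes.items()}
        if not self.volumes:
            raise ValueError("DWISeries needs at least one volume")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise ValueError(f"all volumes must share one shape, got {shapes}")
        for b, v in self.volumes.items():
            if np.any(v < 0):
                raise ValueError(f"magnitude signals must be >= 0 (b={b:g})")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])

    @property
    def b_values(self) -> tuple[float, ...]:
        return tuple(sorted(self.volumes))

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.volumes.values())).shape

    def stack(self, bvals: BValueSet) -> np.ndarray:
        """Stack the requested volumes along a leading b axis."""
        missing = [b for b in bvals.values if b not in self.volumes]
        if missing:
            raise KeyError(f"b-values {missing} not present in series {self.b_values}")
        return np.stack([self.volumes[b] for b in bvals.values], axis=0)

    def to_nifti(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write a 4D NIfTI-1 image plus a ``.bval`` text file (FSL style)."""
        prefix = Path(prefix)
        bvals = self.b_values
        data = np.stack([self.volumes[b] for b in bvals], axis=-1)
        img = nib.Nifti1Image(data.astype(np.float32), self.affine)
        nii_path = prefix.with_suffix(".nii")
        nib.save(img, nii_path)
        bval_path = prefix.with_suffix(".bval")
        bval_path.write_text(" ".join(f"{b:g}" for b in bvals) + "\n")
        return nii_path, bval_path

    @classmethod
    def from_nifti(cls, nii_path: str | Path, bval_path: str | Path | None = None) -> "DWISeries":
        nii_path = Path(nii_path)
        if bval_path is None:
            bval_path = nii_path.with_suffix(".bval")
        img = nib.load(str(nii_path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"expected a 4D DWI image, got shape {data.shape}")
        bvals = [float(tok) for tok in Path(bval_path).read_text().split()]
        if len(bvals) != data.shape[-1]:
            raise ValueError("number of b-values does not match 4D volumes")
        zooms = img.header.get_zooms()[:3]
        return cls(
            volumes={b: data[..., i] for i, b in enumerate(bvals)},
            voxel_size_mm=tuple(float(z) for z in zooms),
            affine=np.asarray(img.affine),
        )


@dataclass
class ADCMap:
    """A per-voxel ADC map for one b-value subset.

    ``values`` holds ADC in 1e-3 mm^2/sec with NaN at invalid voxels;
    ``valid`` flags voxels whose every input signal was strictly positive.
    Invalid voxels are never silently zeroed.
    """

    values: np.ndarray
    valid: np.ndarray
    subset: BValueSet
    voxel_size_mm: tuple[float, float, float] = (0.68, 0.68, 3.3)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask must share a shape")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])

    def to_nifti(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write the map and its validity mask as NIfTI-1 volumes."""
        prefix = Path(prefix)
        map_path = Path(f"{prefix}_adc_{self.subset.label}.nii")
        mask_path = Path(f"{prefix}_adc_{self.subset.label}_valid.nii")
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine), map_path)
        nib.save(nib.Nifti1Image(self.valid.astype(np.uint8), self.affine), mask_path)
        return map_path, mask_path


def fit_adc_voxel(signals, bvals: BValueSet) -> float:
    """Fit the mono-exponential ADC for one voxel.

    For two b-values this is the closed form ``ln(S(b0)/S(b1)) / (b1 - b0)``;
    for three or more it is minus the OLS slope of ``ln S`` against ``b``.
    Returns ADC in 1e-3 mm^2/sec.  Raises on non-positive signals (in map
    mode such voxels are flagged invalid instead, see `compute_adc_map`).
    """
    s = np.asarray(signals, dtype=float)
    if s.ndim != 1 or s.size != len(bvals.values):
        raise ValueError("signals must be 1D with one value per b-value")
    if np.any(s <= 0):
        raise ValueError("all signals must be > 0 for a scalar ADC fit")
    b = np.asarray(bvals.values, dtype=float)
    logs = np.log(s)
    bc = b - b.mean()
    slope = (bc * (logs - logs.mean())).sum() / (bc**2).sum()
    return float(-slope * 1e3)


def compute_adc_map(series: DWISeries, subset: BValueSet) -> ADCMap:
    """Reconstruct an ADC map over ``subset`` voxelwise, without filtering.

    Voxels with any non-positive signal are flagged invalid (NaN in the
    map); everything else is the exact per-voxel log-linear fit.  For a
    two-point subset the OLS slope reduces to the closed-form inversion.
    """
    sig = series.stack(subset)  # (k, X, Y, Z)
    valid = np.all(sig > 0, axis=0)
    b = np.asarray(subset.values, dtype=float).reshape(-1, 1, 1, 1)
    logs = np.log(np.where(sig > 0, sig, 1.0))  # placeholder, masked below
    bc = b - b.mean()
    slope = (bc * (logs - logs.mean(axis=0))).sum(axis=0) / (bc**2).sum()
    values = np.where(valid, -slope * 1e3, np.nan)
    return ADCMap(
        values=values,
        valid=valid,
        subset=subset,
        voxel_size_mm=series.voxel_size_mm,
        affine=series.affine,
    )
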