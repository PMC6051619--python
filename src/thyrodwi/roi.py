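"""Per-nodule indicator extraction from DWI volumes and ROI masks.

For each nodule an ROI is drawn on the single slice showing its maximum
transverse diameter (MTD) on the b=0 image, and copied to the other
b-value volumes and ADC maps.  From it the six diagnostic indicators are
read out: the signal-intensity ratios of nodule to adjacent normal thyroid
tissue at b = 0, 800 and 2000 sec/mm^2 (SIR_b0/b800/b2000) and the mean
ADC over the three b-value subsets.  Image-quality (IQ) scores on a 1-4
reader scale and unmeasurability flags drive the exclusion bookkeeping;
far-outside values (beyond Q3 + 3*IQR or Q1 - 3*IQR) can be flagged for
outlier-aware review.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .adc import ADCMap, DWISeries, SUBSETS, compute_adc_map
from .phantom import TissueSpec

__all__ = [
    "ROI",
    "MEASUREMENT_COLUMNS",
    "roi_mean_signal",
    "compute_sir",
    "measure_mtd",
    "flag_far_outliers",
    "apply_exclusions",
    "measure_nodules",
]

#: Canonical cohort-table columns emitted by the measurement stage.
MEASUREMENT_COLUMNS = (
    "nodule_id",
    "SIR_b0",
    "SIR_b800",
    "SIR_b2000",
    "ADC_b0_800",
    "ADC_b0_2000",
    "ADC_b0_800_2000",
    "DWI_MTD_mm",
    "IQ",
    "class_label",
    "exclusion_flags",
)

EXCLUSION_REASONS = ("tiny_solid", "hemorrhage", "no_normal_tissue", "not_detected", "not_matched")


@dataclass
class ROI:
    """A single-slice region of interest as in-plane voxel coordinates.

    ``coords`` is an (N, 2) array of (row, col) indices on ``slice_index``;
    ``role`` distinguishes the nodule ROI from the ~1 cm^2 normal-tissue
    reference ROI.
    """

    slice_index: int
    coords: np.ndarray
    role: str = "nodule"  # or "normal_tissue"

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=int))
        if self.coords.size == 0:
            raise ValueError("ROI must contain at least one voxel")
        if self.coords.shape[1] != 2:
            raise ValueError("ROI coords must be (N, 2) (row, col)")
        if self.role not in ("nodule", "normal_tissue"):
            raise ValueError("role must be 'nodule' or 'normal_tissue'")

    def __len__(self) -> int:
        return self.coords.shape[0]


def _check_bounds(volume: np.ndarray, roi: ROI) -> None:
    nx, ny, nz = volume.shape
    if not (0 <= roi.slice_index < nz):
        raise ValueError("ROI slice outside volume")
    if roi.coords[:, 0].max() >= nx or roi.coords[:, 1].max() >= ny or roi.coords.min() < 0:
        raise ValueError("ROI coordinates outside image bounds")


def roi_mean_signal(volume: np.ndarray, roi: ROI, exclude_nonpositive: bool = False) -> float:
    """Arithmetic mean signal inside the ROI.

    With ``exclude_nonpositive`` set, voxels with signal <= 0 are dropped
    from the mean (and all-invalid ROIs raise), mirroring how unusable
    voxels are excluded from reader measurements.
    """
    volume = np.asarray(volume, dtype=float)
    _check_bounds(volume, roi)
    vals = volume[roi.coords[:, 0], roi.coords[:, 1], roi.slice_index]
    if exclude_nonpositive:
        vals = vals[vals > 0]
        if vals.size == 0:
            raise ValueError("ROI has no valid (positive) voxels")
    return float(vals.mean())


def compute_sir(si_nodule: float, si_ntt: float) -> float:
    """Signal-intensity ratio nodule / normal thyroid tissue."""
    if si_ntt <= 0:
        raise ValueError("normal-tissue signal must be > 0")
    return float(si_nodule) / float(si_ntt)


def measure_mtd(roi: ROI, voxel_size_mm) -> float:
    """Maximum in-plane extent (max Feret diameter) of the ROI in mm.

    Convention: the largest center-to-center distance between ROI voxels
    plus one in-plane voxel size, so a 10-voxel line at 1 mm spacing
    measures 10 mm -- matching a physical caliper across voxel extents.  A
    single-voxel ROI returns its diagonal extent.
    """
    dx, dy = float(voxel_size_mm[0]), float(voxel_size_mm[1])
    pts = roi.coords.astype(float) * np.array([dx, dy])
    if len(roi) == 1:
        return float(np.hypot(dx, dy))
    # hull would be faster for big ROIs; direct pairwise is exact and fine here
    diff = pts[:, None, :] - pts[None, :, :]
    dmax = float(np.sqrt((diff**2).sum(axis=-1)).max())
    return dmax + max(dx, dy)


def flag_far_outliers(values, convention: str = "linear") -> np.ndarray:
    """Flag far-outside values beyond Q3 + 3*IQR or below Q1 - 3*IQR.

    ``convention`` selects the quartile estimator: "linear" interpolation
    (type 7) or Tukey "hinges".  Requires n >= 4.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size < 4:
        raise ValueError("need a 1D sample of at least 4 values")
    if convention == "linear":
        q1, q3 = np.percentile(vals, [25, 75])
    elif convention == "hinges":
        s = np.sort(vals)
        n = s.size
        half = (n + 1) // 2
        q1 = np.median(s[:half])
        q3 = np.median(s[n - half:])
    else:
        raise ValueError("convention must be 'linear' or 'hinges'")
    iqr = q3 - q1
    return (vals > q3 + 3 * iqr) | (vals < q1 - 3 * iqr)


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop unmeasurable nodules and poor-quality images; count removals.

    A record is excluded when its ``exclusion_flags`` field names any
    unmeasurability reason (semicolon-separated) or its IQ score is 1
    (images precluding assessment).  Each removed record is counted once,
    under its first flag or under ``IQ_1``.  Idempotent.
    """
    df = cohort.copy()
    flags = df.get("exclusion_flags", pd.Series("", index=df.index)).fillna("").astype(str)
    iq = df.get("IQ", pd.Series(4, index=df.index)).astype(int)
    report: dict[str, int] = {}
    drop = np.zeros(len(df), dtype=bool)
    for k, (f, q) in enumerate(zip(flags, iq)):
        reasons = [r for r in f.split(";") if r]
        if reasons:
            drop[k] = True
            report[reasons[0]] = report.get(reasons[0], 0) + 1
        elif q == 1:
            drop[k] = True
            report["IQ_1"] = report.get("IQ_1", 0) + 1
    retained = df.loc[~drop].reset_index(drop=True)
    report["n_input"] = len(df)
    report["n_retained"] = len(retained)
    return retained, report


def _slice_rois(labels: np.ndarray, label: int) -> ROI:
    """Nodule ROI on the slice where the nodule shows its largest area."""
    per_slice = (labels == label).sum(axis=(0, 1))
    z = int(per_slice.argmax())
    rows, cols = np.nonzero(labels[:, :, z] == label)
    return ROI(slice_index=z, coords=np.column_stack([rows, cols]), role="nodule")


def _ntt_roi(labels: np.ndarray, nodule_roi: ROI, area_cm2: float, voxel_size_mm) -> ROI:
    """Normal-tissue reference ROI: background voxels nearest the nodule.

    Emulates the ~1 cm^2 reference region placed adjacent to the nodule on
    the same slice.
    """
    z = nodule_roi.slice_index
    rows, cols = np.nonzero(labels[:, :, z] == 0)
    if rows.size == 0:
        raise ValueError("no normal tissue available on the nodule slice")
    center = nodule_roi.coords.mean(axis=0)
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    n_target = max(1, int(round(area_cm2 * 100.0 / (voxel_size_mm[0] * voxel_size_mm[1]))))
    order = np.argsort(d2, kind="stable")[:n_target]
    return ROI(slice_index=z, coords=np.column_stack([rows[order], cols[order]]), role="normal_tissue")


def measure_nodules(
    series: DWISeries,
    labels: np.ndarray,
    tissues: dict[int, TissueSpec],
    ntt_area_cm2: float = 1.0,
    iq_scores: dict[int, int] | None = None,
    exclusion_flags: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Measure every labelled nodule in a phantom into a cohort table.

    For each nodule label the MTD slice is selected on the b=0 volume, the
    SIR triplet is computed against an adjacent normal-tissue ROI, the
    three ADC subset means are read off the reconstructed maps, and the
    DWI-MTD is measured.  IQ scores and exclusion flags are reader
    annotations supplied by the caller (default IQ 4, no flags).
    """
    iq_scores = iq_scores or {}
    exclusion_flags = exclusion_flags or {}
    maps: dict[str, ADCMap] = {name: compute_adc_map(series, bset) for name, bset in SUBSETS.items()}
    rows = []
    for label in sorted(tissues):
        if label == 0:
            continue
        roi = _slice_rois(labels, label)
        ntt = _ntt_roi(labels, roi, ntt_area_cm2, series.voxel_size_mm)
        sirs = {}
        for b, key in ((0.0, "SIR_b0"), (800.0, "SIR_b800"), (2000.0, "SIR_b2000")):
            vol = series.volumes[b]
            si_nod = roi_mean_signal(vol, roi, exclude_nonpositive=True)
            si_ntt = roi_mean_signal(vol, ntt, exclude_nonpositive=True)
            sirs[key] = compute_sir(si_nod, si_ntt)
        adcs = {}
        for name, col in (("b0-800", "ADC_b0_800"), ("b0-2000", "ADC_b0_2000"),
                          ("b0-800-2000", "ADC_b0_800_2000")):
            m = maps[name]
            vals = m.values[roi.coords[:, 0], roi.coords[:, 1], roi.slice_index]
            ok = np.isfinite(vals)
            if not ok.any():
                warnings.warn(f"nodule {label}: no valid ADC voxels in subset {name}")
                adcs[col] = np.nan
            else:
                adcs[col] = float(vals[ok].mean())
        rows.append({
            "nodule_id": f"nod{label:03d}",
            **sirs,
            **adcs,
            "DWI_MTD_mm": measure_mtd(roi, series.voxel_size_mm),
            "IQ": iq_scores.get(label, 4),
            "class_label": tissues[label].class_label,
            "exclusion_flags": exclusion_flags.get(label, ""),
        })
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
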