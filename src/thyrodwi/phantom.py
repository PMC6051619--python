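"""Synthetic DWI phantoms, indicator cohorts and paired location profiles.

Three generators drive the whole pipeline without any real data:

* :func:`generate_phantom` builds multi-b-value magnitude volumes for a
  voxel grid containing spherical "nodules" embedded in normal thyroid
  tissue, with mono-exponential decay per tissue and optional Rician noise
  (the magnitude-MRI noise model).
* :func:`generate_cohort` draws per-nodule diagnostic indicator values
  (three signal-intensity ratios and three ADCs) from truncated-normal
  group distributions, emulating a benign / papillary-carcinoma (PTC) /
  microcarcinoma (PTMC) case mix.
* :func:`generate_location_pairs` produces MR-side nodule location
  profiles together with an ultrasound- or specimen-side counterpart whose
  distances are shrunk isotropically and jittered, for testing ratio-based
  co-localization.

All randomness flows from explicit seeds; identical seeds give identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .adc import DWISeries
from .colocalization import LocationProfile

__all__ = [
    "TissueSpec",
    "Nodule",
    "PhantomConfig",
    "GroupSpec",
    "INDICATORS",
    "NORMAL_THYROID",
    "BENIGN_NODULE",
    "PTC_NODULE",
    "PTMC_NODULE",
    "BENIGN_GROUP",
    "PTC_GROUP",
    "PTMC_GROUP",
    "decay_signal",
    "add_rician_noise",
    "generate_phantom",
    "generate_cohort",
    "generate_location_pairs",
]

#: Canonical indicator column names, shared with the measurement tables.
INDICATORS = (
    "SIR_b0",
    "SIR_b800",
    "SIR_b2000",
    "ADC_b0_800",
    "ADC_b0_2000",
    "ADC_b0_800_2000",
)

CLASS_LABELS = ("benign", "PTC", "PTMC", "normal_thyroid")


@dataclass(frozen=True)
class TissueSpec:
    """Signal model of one tissue: S0 distribution and decay rate.

    ``adc_true`` is the mono-exponential decay rate in 1e-3 mm^2/sec.  For
    normal thyroid it is an *effective* rate chosen so that nodule-to-tissue
    signal ratios across b reproduce the clinically observed pattern
    (benign SIR falling, carcinoma SIR rising with b); it absorbs T2 and
    perfusion effects and is not a literature thyroid ADC.
    """

    name: str
    s0_mean: float
    s0_sd: float
    adc_true: float
    class_label: str

    def __post_init__(self) -> None:
        if self.s0_mean <= 0:
            raise ValueError("s0_mean must be > 0")
        if self.s0_sd < 0:
            raise ValueError("s0_sd must be >= 0")
        if self.adc_true <= 0:
            raise ValueError("adc_true must be > 0")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")


# Default tissues.  S0 of nodules is expressed relative to normal thyroid
# tissue (S0=100) so that noiseless b=0 signal ratios equal the group-mean
# SIR_b0 of each class; decay rates equal the group-mean three-point ADC.
NORMAL_THYROID = TissueSpec("normal_thyroid", 100.0, 0.0, 1.17, "normal_thyroid")
BENIGN_NODULE = TissueSpec("benign_nodule", 201.0, 0.0, 1.40, "benign")
PTC_NODULE = TissueSpec("ptc_nodule", 132.0, 0.0, 0.89, "PTC")
PTMC_NODULE = TissueSpec("ptmc_nodule", 117.0, 0.0, 0.90, "PTMC")


@dataclass(frozen=True)
class Nodule:
    """A spherical nodule: center voxel index, radius in mm, tissue."""

    center_vox: tuple[int, int, int]
    radius_mm: float
    tissue: TissueSpec

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")


@dataclass
class PhantomConfig:
    """Geometry, acquisition and noise settings for one phantom.

    Default voxel size follows the axial DWI protocol (FOV 175 mm over a
    174 matrix in-plane, 3 mm slices with 0.3 mm gap); b-values are the
    acquisition's 0, 800 and 2000 sec/mm^2.  ``averages`` holds the number
    of excitations per b-value; when ``model_averaging`` is on, the noise
    sigma of an averaged volume is divided by sqrt(averages) (4 averages at
    b=2000 halves sigma).
    """

    grid_shape: tuple[int, int, int] = (32, 32, 8)
    voxel_size_mm: tuple[float, float, float] = (0.68, 0.68, 3.3)
    b_values: tuple[float, ...] = (0.0, 800.0, 2000.0)
    noise_sigma: float = 0.0
    seed: int = 0
    nodules: tuple[Nodule, ...] = ()
    background: TissueSpec = NORMAL_THYROID
    averages: dict[float, int] = field(default_factory=lambda: {0.0: 1, 800.0: 1, 2000.0: 4})
    model_averaging: bool = True
    overlap: str = "reject"  # or "last-wins"

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")
        bv = tuple(float(b) for b in self.b_values)
        if len(set(bv)) != len(bv) or any(b < 0 for b in bv) or 0.0 not in bv:
            raise ValueError("b_values must be unique, non-negative and contain 0")
        self.b_values = bv
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.overlap not in ("reject", "last-wins"):
            raise ValueError("overlap must be 'reject' or 'last-wins'")
        self.nodules = tuple(self.nodules)
        for nod in self.nodules:
            for c, n, dv in zip(nod.center_vox, self.grid_shape, self.voxel_size_mm):
                if not (0 <= c < n):
                    raise ValueError(f"nodule center {nod.center_vox} outside grid")
                # center must sit at least one radius from every grid face
                if (c + 0.5) * dv < nod.radius_mm or (n - c - 0.5) * dv < nod.radius_mm:
                    raise ValueError(f"nodule at {nod.center_vox} (r={nod.radius_mm} mm) exceeds grid")


def decay_signal(s0, adc, b):
    """Noiseless mono-exponential DWI signal ``s0 * exp(-b * adc * 1e-3)``.

    ``adc`` is in 1e-3 mm^2/sec and ``b`` in sec/mm^2; broadcasting over
    arrays is supported.  Strictly decreasing in b for adc > 0.
    """
    s0 = np.asarray(s0, dtype=float)
    adc = np.asarray(adc, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(s0 <= 0):
        raise ValueError("s0 must be > 0")
    if np.any(adc <= 0):
        raise ValueError("adc must be > 0")
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    out = s0 * np.exp(-b * adc * 1e-3)
    return float(out) if out.ndim == 0 else out


def add_rician_noise(signal, sigma: float, rng: np.random.Generator):
    """Corrupt a noiseless magnitude signal with Rician noise.

    Returns ``sqrt((signal + g1)^2 + g2^2)`` with independent zero-mean
    Gaussians g1, g2 of standard deviation ``sigma``.  ``sigma=0`` returns
    the input unchanged; the output is always non-negative.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        out = signal.copy()
    else:
        g1 = rng.normal(0.0, sigma, size=signal.shape)
        g2 = rng.normal(0.0, sigma, size=signal.shape)
        out = np.sqrt((signal + g1) ** 2 + g2**2)
    return float(out) if out.ndim == 0 else out


def _sphere_mask(shape, voxel_size_mm, center_vox, radius_mm) -> np.ndarray:
    """Voxel-center-inside rasterization of a sphere (in mm space)."""
    axes = [(np.arange(n) - c) * dv for n, c, dv in zip(shape, center_vox, voxel_size_mm)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij", sparse=True)
    return dx**2 + dy**2 + dz**2 <= radius_mm**2


def generate_phantom(config: PhantomConfig) -> tuple[DWISeries, np.ndarray, dict[int, TissueSpec]]:
    """Build the DWI series, integer label mask and label->tissue table.

    Label 0 is the background tissue; nodules get labels 1..K in config
    order.  Every voxel's noiseless signal follows :func:`decay_signal` for
    its tissue; Rician noise (if any) is applied per b-value volume with an
    independent stream derived from ``config.seed``.
    """
    labels = np.zeros(config.grid_shape, dtype=np.int16)
    tissues: dict[int, TissueSpec] = {0: config.background}
    for k, nod in enumerate(config.nodules, start=1):
        mask = _sphere_mask(config.grid_shape, config.voxel_size_mm, nod.center_vox, nod.radius_mm)
        if config.overlap == "reject" and np.any(labels[mask] != 0):
            raise ValueError(f"nodule {k} overlaps an earlier nodule")
        labels[mask] = k
        tissues[k] = nod.tissue

    rng = np.random.default_rng(config.seed)
    # Per-voxel S0: tissue mean plus optional biological spread, fixed across b.
    s0 = np.empty(config.grid_shape, dtype=float)
    adc = np.empty(config.grid_shape, dtype=float)
    for lab, tis in tissues.items():
        m = labels == lab
        if tis.s0_sd > 0:
            a = -tis.s0_mean / tis.s0_sd  # truncate at 0: S0 is physical
            s0[m] = stats.truncnorm.rvs(a, np.inf, loc=tis.s0_mean, scale=tis.s0_sd,
                                        size=int(m.sum()), random_state=rng)
        else:
            s0[m] = tis.s0_mean
        adc[m] = tis.adc_true

    volumes: dict[float, np.ndarray] = {}
    for b in config.b_values:
        clean = decay_signal(s0, adc, b)
        sigma = config.noise_sigma
        if sigma > 0 and config.model_averaging:
            sigma = sigma / np.sqrt(config.averages.get(b, 1))
        volumes[b] = add_rician_noise(clean, sigma, rng)
    series = DWISeries(volumes=volumes, voxel_size_mm=config.voxel_size_mm)
    return series, labels, tissues


@dataclass(frozen=True)
class GroupSpec:
    """Mean/SD of the six indicators plus group size for one nodule class."""

    class_label: str
    means: dict[str, float]
    sds: dict[str, float]
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        for ind in INDICATORS:
            if ind not in self.means or ind not in self.sds:
                raise ValueError(f"missing indicator {ind}")
            if self.sds[ind] < 0:
                raise ValueError(f"SD of {ind} must be >= 0")


def _group(label: str, n: int, vals: Sequence[tuple[float, float]]) -> GroupSpec:
    return GroupSpec(
        class_label=label,
        means={ind: m for ind, (m, _) in zip(INDICATORS, vals)},
        sds={ind: s for ind, (_, s) in zip(INDICATORS, vals)},
        n=n,
    )


# Published group summaries (mean, SD) in the order of INDICATORS.
BENIGN_GROUP = _group("benign", 62, [(2.01, 1.03), (1.53, 0.95), (1.23, 1.03),
                                     (1.99, 0.45), (1.43, 0.27), (1.40, 0.27)])
PTC_GROUP = _group("PTC", 52, [(1.32, 0.46), (1.93, 0.98), (2.29, 1.21),
                               (1.30, 0.30), (0.92, 0.16), (0.89, 0.16)])
PTMC_GROUP = _group("PTMC", 33, [(1.17, 0.30), (1.62, 0.61), (1.92, 0.74),
                                 (1.31, 0.30), (0.94, 0.17), (0.90, 0.16)])


def generate_cohort(groups: Iterable[GroupSpec] | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw a per-nodule indicator table from group distributions.

    Each indicator is drawn independently from a normal truncated at 0
    (indicator values are physically positive).  Returns a DataFrame with a
    ``class_label`` column plus one column per indicator; sample moments
    converge to the specified ones as n grows wherever the truncated mass
    is negligible.
    """
    if groups is None:
        groups = (BENIGN_GROUP, PTC_GROUP)
    rng = np.random.default_rng(seed)
    frames = []
    for g in groups:
        cols: dict[str, np.ndarray] = {"class_label": np.repeat(g.class_label, g.n)}
        for ind in INDICATORS:
            m, s = g.means[ind], g.sds[ind]
            if s == 0:
                cols[ind] = np.full(g.n, m)
            else:
                a = (0.0 - m) / s
                cols[ind] = stats.truncnorm.rvs(a, np.inf, loc=m, scale=s, size=g.n,
                                                random_state=rng)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def generate_location_pairs(
    n: int,
    jitter_fraction: float = 0.05,
    shrinkage_fraction: float = 0.12,
    seed: int = 0,
    other_modality: str = "specimen",
) -> tuple[list[LocationProfile], list[LocationProfile], pd.DataFrame]:
    """Generate MR location profiles paired with US/specimen counterparts.

    The MR side draws four positive distances per nodule (center to the
    gland's upper/lower and nearest/farthest margins).  The counterpart
    scales every distance by ``1 - shrinkage_fraction`` (isotropic in-vitro
    shrinkage; 10-15% is typical for thyroid specimens) and perturbs each
    multiplicatively by a uniform factor in ``1 +/- jitter_fraction``
    (independent measurement error per distance).  Returns the two profile
    lists plus a table carrying the ground-truth pairing.
    """
    if jitter_fraction < 0:
        raise ValueError("jitter_fraction must be >= 0")
    if not (0 <= shrinkage_fraction < 1):
        raise ValueError("shrinkage_fraction must be in [0, 1)")
    if other_modality not in ("US", "specimen"):
        raise ValueError("other_modality must be 'US' or 'specimen'")
    rng = np.random.default_rng(seed)
    sites = rng.choice(["left", "right", "isthmus"], size=n, p=[0.45, 0.45, 0.10])
    mr_profiles: list[LocationProfile] = []
    other_profiles: list[LocationProfile] = []
    rows = []
    for i in range(n):
        nid = f"nod{i:03d}"
        d = {
            "d_upper": rng.uniform(5.0, 35.0),
            "d_lower": rng.uniform(5.0, 35.0),
            "d_nearest": rng.uniform(2.0, 12.0),
            "d_farthest": rng.uniform(10.0, 35.0),
        }
        mr = LocationProfile(nodule_id=nid, modality="MR", site=str(sites[i]), **d)
        scale = 1.0 - shrinkage_fraction
        jit = {k: v * scale * (1.0 + jitter_fraction * rng.uniform(-1.0, 1.0))
               for k, v in d.items()}
        other = LocationProfile(nodule_id=nid, modality=other_modality, site=str(sites[i]), **jit)
        mr_profiles.append(mr)
        other_profiles.append(other)
        rows.append({"nodule_id": nid, "site": sites[i], **{f"mr_{k}": v for k, v in d.items()},
                     **{f"other_{k}": v for k, v in jit.items()}})
    return mr_profiles, other_profiles, pd.DataFrame(rows)
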