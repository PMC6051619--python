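"""Nodule co-localization between MR and ultrasound/specimen by location ratios.

A nodule is located inside the gland by four distances from its center:
to the thyroid upper and lower margins (longitudinal) and to the nearest
and farthest margins (horizontal).  Two normalized ratios summarize the
position: R_UL = D_upper / D_lower and R_NF = D_nearest / D_farthest.
Because ratios are scale invariant, isotropic specimen shrinkage (the
10-15% typical of in-vitro thyroid) cancels out, which is what makes
ratio-based matching workable across modalities.

A candidate pair matches when all four relative deviations -- the UL and
NF ratio differences expressed as a percentage of each side's own ratio --
stay within a threshold: 10% against ultrasound (FNAB follow-up), 20%
against surgical specimens (the wider band absorbs shrinkage-related
error).  Both thresholds are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

__all__ = [
    "LocationProfile",
    "MatchDecision",
    "location_ratios",
    "deviation_percentages",
    "match_nodules",
    "match_cohorts",
    "profiles_to_frame",
    "profiles_from_frame",
    "write_match_report",
]

MODALITIES = ("MR", "US", "specimen")
SITES = ("isthmus", "left", "right")

DEFAULT_US_THRESHOLD = 10.0
DEFAULT_SPECIMEN_THRESHOLD = 20.0


@dataclass(frozen=True)
class LocationProfile:
    """Distances (mm) locating one nodule's center within the gland."""

    nodule_id: str
    modality: str
    site: str
    d_upper: float
    d_lower: float
    d_nearest: float
    d_farthest: float

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}")
        for name in ("d_upper", "d_lower", "d_nearest", "d_farthest"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class MatchDecision:
    """Outcome of comparing one MR profile with one US/specimen profile.

    ``deviations`` maps the four deviation names to absolute percentages;
    ``signed_deviations`` keeps the sign for diagnostics.  ``matched`` is
    True iff all four absolute deviations are <= ``threshold_pct`` and the
    sites agree.
    """

    matched: bool
    deviations: dict[str, float]
    signed_deviations: dict[str, float]
    threshold_pct: float
    reason: str = ""


def location_ratios(profile: LocationProfile) -> tuple[float, float]:
    """Return (R_UL, R_NF) = (D_upper/D_lower, D_nearest/D_farthest)."""
    if profile.d_lower <= 0 or profile.d_farthest <= 0:
        raise ValueError("denominator distances must be > 0")
    return profile.d_upper / profile.d_lower, profile.d_nearest / profile.d_farthest


def deviation_percentages(r_a: float, r_b: float) -> tuple[float, float]:
    """Difference D = r_a - r_b as a percentage of r_a and of r_b.

    Returns signed percentages (100*D/r_a, 100*D/r_b); callers take the
    absolute value for the match rule.
    """
    if r_a <= 0 or r_b <= 0:
        raise ValueError("ratios must be > 0")
    d = r_a - r_b
    return 100.0 * d / r_a, 100.0 * d / r_b


def match_nodules(
    mr: LocationProfile,
    other: LocationProfile,
    us_threshold: float = DEFAULT_US_THRESHOLD,
    specimen_threshold: float = DEFAULT_SPECIMEN_THRESHOLD,
) -> MatchDecision:
    """Decide whether an MR profile and a US/specimen profile co-localize.

    Computes the UL and NF ratio deviations against both denominators and
    matches iff all four absolute percentages are within the modality's
    threshold.  A site mismatch is an automatic non-match (with reason);
    using a non-MR profile on the MR side is a usage error.
    """
    if mr.modality != "MR":
        raise ValueError("first profile must be the MR side")
    if other.modality not in ("US", "specimen"):
        raise ValueError("second profile must be US or specimen")
    threshold = us_threshold if other.modality == "US" else specimen_threshold

    mr_ul, mr_nf = location_ratios(mr)
    ot_ul, ot_nf = location_ratios(other)
    ul_vs_other, ul_vs_mr = deviation_percentages(ot_ul, mr_ul)
    nf_vs_other, nf_vs_mr = deviation_percentages(ot_nf, mr_nf)
    signed = {
        "UL_vs_other": ul_vs_other,
        "UL_vs_MR": ul_vs_mr,
        "NF_vs_other": nf_vs_other,
        "NF_vs_MR": nf_vs_mr,
    }
    absdev = {k: abs(v) for k, v in signed.items()}

    if mr.site != other.site:
        return MatchDecision(False, absdev, signed, threshold, reason="site mismatch")
    matched = all(v <= threshold for v in absdev.values())
    return MatchDecision(matched, absdev, signed, threshold)


def match_cohorts(
    mr_list: list[LocationProfile],
    other_list: list[LocationProfile],
    us_threshold: float = DEFAULT_US_THRESHOLD,
    specimen_threshold: float = DEFAULT_SPECIMEN_THRESHOLD,
) -> tuple[list[tuple[LocationProfile, LocationProfile, MatchDecision]],
           list[LocationProfile], list[LocationProfile]]:
    """One-to-one greedy assignment between MR and counterpart profiles.

    Eligible pairs (all four deviations within threshold, same site) are
    ranked by total absolute deviation and assigned greedily; ties break on
    input order, so the result is deterministic.  Returns the assignment
    plus the leftover unmatched profiles on each side.
    """
    candidates = []
    for i, mr in enumerate(mr_list):
        for j, other in enumerate(other_list):
            dec = match_nodules(mr, other, us_threshold, specimen_threshold)
            if dec.matched:
                total = sum(dec.deviations.values())
                candidates.append((total, i, j, dec))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_mr: set[int] = set()
    used_other: set[int] = set()
    pairs = []
    for total, i, j, dec in candidates:
        if i in used_mr or j in used_other:
            continue
        used_mr.add(i)
        used_other.add(j)
        pairs.append((mr_list[i], other_list[j], dec))
    unmatched_mr = [p for i, p in enumerate(mr_list) if i not in used_mr]
    unmatched_other = [p for j, p in enumerate(other_list) if j not in used_other]
    return pairs, unmatched_mr, unmatched_other


# ---------------------------------------------------------------------------
# Tabular IO

def profiles_to_frame(profiles: list[LocationProfile]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in profiles])


def profiles_from_frame(frame: pd.DataFrame) -> list[LocationProfile]:
    required = {"nodule_id", "modality", "site", "d_upper", "d_lower", "d_nearest", "d_farthest"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"location table missing columns {sorted(missing)}")
    return [
        LocationProfile(
            nodule_id=str(r.nodule_id), modality=str(r.modality), site=str(r.site),
            d_upper=float(r.d_upper), d_lower=float(r.d_lower),
            d_nearest=float(r.d_nearest), d_farthest=float(r.d_farthest),
        )
        for r in frame.itertuples()
    ]


def write_match_report(
    path: str | Path,
    pairs: list[tuple[LocationProfile, LocationProfile, MatchDecision]],
    unmatched_mr: list[LocationProfile],
    unmatched_other: list[LocationProfile],
) -> Path:
    """Serialize a cohort match as JSON with per-pair deviations."""
    payload = {
        "pairs": [
            {
                "mr_id": mr.nodule_id,
                "other_id": other.nodule_id,
                "other_modality": other.modality,
                "threshold_pct": dec.threshold_pct,
                "deviations_pct": dec.deviations,
                "signed_deviations_pct": dec.signed_deviations,
            }
            for mr, other, dec in pairs
        ],
        "unmatched_mr": [p.nodule_id for p in unmatched_mr],
        "unmatched_other": [p.nodule_id for p in unmatched_other],
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path
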