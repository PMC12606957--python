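"""ROI quantification, laterality grading and inter-observer agreement.

This module turns reconstructed sodium images (or externally tabulated
observer readings) into the study endpoints:

* per-structure signal statistics (mean / SD / median NaSI) over segmented
  cochlea, vestibule and internal auditory meatus (IAM) masks;
* median NaSI scaled to the adjacent IAM median -- a dimensionless quantity
  invariant to receive-gain so it compares across ears and scanners;
* observer-averaged between-ear ratios (normal : hydropic);
* the Likert-grade laterality decision rule: a structure lateralises when
  its visibility grade *relative to the ipsilateral IAM fundus* exceeds the
  contralateral relative grade by >= 2 points (definite) or exactly 1 point
  (possible), provided the better-seen side has anatomical compatibility
  >= 2;
* two-way random-effects absolute-agreement intraclass correlation between
  observers, in single- and average-measures forms;
* cohort summaries with month -> year conversion.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RoiStats",
    "LikertAssessment",
    "LateralityCall",
    "RatioReport",
    "roi_stats",
    "scale_to_iam",
    "between_ear_ratio",
    "classify_laterality",
    "icc_agreement",
    "cohort_summary",
    "segment_by_threshold",
    "grade_visibility_auto",
    "round_half_up",
]

STRUCTURES = ("cochlea", "vestibule", "iam")
SIDES = ("left", "right")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (printed-table convention, not banker's)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class RoiStats:
    structure: str
    side: str
    mean: float
    sd: float
    median: float
    volume: float        # mm^3
    voxel_count: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def roi_stats(
    volume: np.ndarray,
    mask: np.ndarray,
    voxel_size: float,
    structure: str = "",
    side: str = "",
) -> RoiStats:
    """Mean / SD / median over masked voxels; even-count medians midpoint."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = np.asarray(volume, dtype=float)[mask]
    return RoiStats(
        structure=structure,
        side=side,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
        median=float(np.median(vals)),
        volume=float(vals.size * voxel_size**3),
        voxel_count=int(vals.size),
    )


def scale_to_iam(inner_median: float, iam_median: float) -> float:
    """Inner-ear median NaSI scaled to the adjacent IAM median.

    The quotient cancels any global multiplicative intensity factor
    (coil gain, scanner scaling), which is the whole point of the scaling.
    """
    if iam_median <= 0:
        raise ValueError("IAM median must be positive")
    return float(inner_median) / float(iam_median)


def between_ear_ratio(
    normal_medians: list[float] | tuple[float, ...],
    hydropic_medians: list[float] | tuple[float, ...],
) -> float:
    """Observer-averaged normal : hydropic median ratio, half-up at 1 dp.

    Each argument carries one median per observer; observers are averaged
    per ear first, then the ratio is taken (the printed-table convention
    "calculated from the mean of the two observers").
    """
    normal = np.asarray(normal_medians, dtype=float)
    hydropic = np.asarray(hydropic_medians, dtype=float)
    if np.any(normal <= 0) or np.any(hydropic <= 0):
        raise ValueError("medians must be positive")
    return round_half_up(normal.mean() / hydropic.mean(), 1)


@dataclass(frozen=True)
class LikertAssessment:
    """One observer's visibility/compatibility grades at one timepoint.

    ``grades`` maps (structure, side) -> (visibility, compatibility), both
    integers 0-3, for structures cochlea/vestibule/iam on sides left/right.
    Visibility 0 implies compatibility 0 ("structure not visible").
    """

    observer: str
    timepoint: str                       # pre_registration | post_registration
    grades: dict[tuple[str, str], tuple[int, int]]

    def __post_init__(self) -> None:
        if self.timepoint not in ("pre_registration", "post_registration"):
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        for s in STRUCTURES:
            for d in SIDES:
                if (s, d) not in self.grades:
                    raise ValueError(f"missing grades for ({s}, {d})")
        for key, (vis, comp) in self.grades.items():
            if not (0 <= vis <= 3 and 0 <= comp <= 3):
                raise ValueError(f"grades for {key} outside 0-3: {vis}/{comp}")
            if int(vis) != vis or int(comp) != comp:
                raise ValueError(f"grades for {key} must be integers")
            if vis == 0 and comp != 0:
                raise ValueError(
                    f"{key}: visibility 0 implies compatibility 0, got {comp}"
                )

    def visibility(self, structure: str, side: str) -> int:
        return int(self.grades[(structure, side)][0])

    def compatibility(self, structure: str, side: str) -> int:
        return int(self.grades[(structure, side)][1])


@dataclass(frozen=True)
class LateralityCall:
    certainty: str                      # none | possible | definite
    hydropic_side: str | None = None
    deciding_structure: str | None = None

    def __post_init__(self) -> None:
        if (self.certainty == "none") != (self.hydropic_side is None):
            raise ValueError("hydropic_side must be absent iff certainty is none")


def classify_laterality(assessment: LikertAssessment) -> LateralityCall:
    """Apply the relative-visibility laterality rule to one grade set.

    For each inner-ear structure the visibility grade is referenced to the
    ipsilateral IAM fundus: ``rel(s, d) = vis(s, d) - vis(iam, d)``.  The
    side with the larger ``rel`` is the better-seen (candidate normal)
    side; the structure is eligible only if that side's anatomical
    compatibility is >= 2.  Among eligible structures the largest
    between-side difference decides: >= 2 points -> definite, exactly 1 ->
    possible, otherwise none; the hydropic side is the worse-seen side.
    Eligible structures pointing at opposite sides with equal strength
    yield a conservative "none".
    """
    best_diff = 0
    candidates: list[tuple[int, str, str]] = []   # (diff, hydropic_side, structure)
    for s in ("cochlea", "vestibule"):
        rel = {
            d: assessment.visibility(s, d) - assessment.visibility("iam", d)
            for d in SIDES
        }
        better = "left" if rel["left"] > rel["right"] else "right"
        worse = "right" if better == "left" else "left"
        diff = rel[better] - rel[worse]
        if diff <= 0:
            continue
        if assessment.compatibility(s, better) < 2:
            continue
        candidates.append((diff, worse, s))
        best_diff = max(best_diff, diff)

    if best_diff < 1:
        return LateralityCall("none")
    top = [c for c in candidates if c[0] == best_diff]
    sides = {c[1] for c in top}
    if len(sides) > 1:
        return LateralityCall("none")
    diff, side, structure = top[0]
    certainty = "definite" if diff >= 2 else "possible"
    return LateralityCall(certainty, side, structure)


def icc_agreement(ratings: np.ndarray, form: str = "single") -> float:
    """Two-way random-effects absolute-agreement ICC (rows items, cols raters).

    ``form='single'`` is ICC(2,1), ``form='average'`` ICC(2,k), both from
    the classical ANOVA mean-squares decomposition.  Degenerate input with
    zero variance everywhere returns 1.0 (perfect agreement by convention)
    with a warning.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an items x raters matrix, >= 2 each")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing or non-finite cells are not supported")
    if form not in ("single", "average"):
        raise ValueError(f"unknown form {form!r}")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        import warnings

        warnings.warn("zero-variance ratings; ICC = 1 by convention", stacklevel=2)
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "single":
        return float(
            (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        )
    return float((msr - mse) / (msr + (msc - mse) / n))


_DURATION_UNITS = {
    "y": 12.0, "yr": 12.0, "yrs": 12.0, "year": 12.0, "years": 12.0,
    "mo": 1.0, "mos": 1.0, "month": 1.0, "months": 1.0, "m": 1.0,
}


def _duration_to_years(text: str, row_label: str) -> float:
    parts = str(text).strip().split()
    try:
        value = float(parts[0])
        unit = parts[1].lower().rstrip(".")
        months = value * _DURATION_UNITS[unit]
    except (IndexError, ValueError, KeyError):
        raise ValueError(
            f"unparseable symptom duration {text!r} in row {row_label!r}; "
            "use '<value> years' or '<value> months'"
        ) from None
    return months / 12.0


def cohort_summary(metadata: pd.DataFrame) -> dict:
    """Summarise a cohort table: age, symptom duration (years), sex counts.

    Expects columns ``participant``, ``age``, ``sex`` and
    ``symptom_duration`` (unit-tagged strings such as "17 years" or
    "36 months"); durations are converted to years before averaging and
    means are reported half-up at 1 dp.
    """
    required = {"participant", "age", "sex", "symptom_duration"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    ages = metadata["age"].astype(float)
    durations = [
        _duration_to_years(row.symptom_duration, str(row.participant))
        for row in metadata.itertuples()
    ]
    sexes = metadata["sex"].astype(str).str.lower().str[0]
    return {
        "n": int(len(metadata)),
        "age_mean": round_half_up(ages.mean(), 1),
        "age_range": (float(ages.min()), float(ages.max())),
        "duration_mean_years": round_half_up(float(np.mean(durations)), 1),
        "duration_range_years": (float(np.min(durations)), float(np.max(durations))),
        "sex_counts": {
            "f": int((sexes == "f").sum()),
            "m": int((sexes == "m").sum()),
        },
    }


def segment_by_threshold(
    volume: np.ndarray,
    seed_mask: np.ndarray,
    threshold_fraction: float = 0.5,
) -> np.ndarray:
    """Seeded intensity segmentation: the connected component containing the
    seed among voxels brighter than ``threshold_fraction`` x seed mean."""
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise ValueError("seed region is empty")
    vol = np.asarray(volume, dtype=float)
    thresh = threshold_fraction * vol[seed_mask].mean()
    above = vol > thresh
    if not (above & seed_mask).any():
        raise ValueError("no voxels above threshold within the seed region")
    labels, _ = ndimage.label(above)
    seed_labels = np.unique(labels[above & seed_mask])
    out = np.isin(labels, seed_labels[seed_labels > 0])
    if not out.any():
        raise ValueError("threshold segmentation produced an empty mask")
    return out


def grade_visibility_auto(
    roi_median: float,
    reference_median: float,
    background_mean: float,
    background_sd: float,
) -> int:
    """Automated stand-in for human visibility grading.

    Grade 0 when the ROI median sits below the noise floor (background mean
    + 2 SD); otherwise graded by the ROI : reference median ratio --
    < 0.8 decreased (1), 0.8-1.25 similar (2), > 1.25 increased (3),
    mirroring the decreased/similar/increased wording of the visual scale.
    """
    if reference_median <= 0 or background_sd < 0:
        raise ValueError("reference stats are degenerate")
    if roi_median < background_mean + 2.0 * background_sd:
        return 0
    ratio = roi_median / reference_median
    if ratio < 0.8:
        return 1
    if ratio <= 1.25:
        return 2
    return 3


@dataclass
class RatioReport:
    """Per-participant, per-structure ratio summary (DataFrame wrapper)."""

    table: pd.DataFrame

    @classmethod
    def from_observer_medians(cls, rows: list[dict]) -> "RatioReport":
        """Build from per-observer median records.

        Each row needs: participant, structure, observer, normal_median,
        hydropic_median, normal_iam_median, hydropic_iam_median.
        """
        df = pd.DataFrame(rows)
        out = []
        for (participant, structure), grp in df.groupby(
            ["participant", "structure"], sort=True
        ):
            normal = grp["normal_median"].to_numpy(dtype=float)
            hydropic = grp["hydropic_median"].to_numpy(dtype=float)
            scaled_normal = np.array(
                [
                    scale_to_iam(r.normal_median, r.normal_iam_median)
                    for r in grp.itertuples()
                ]
            )
            scaled_hydropic = np.array(
                [
                    scale_to_iam(r.hydropic_median, r.hydropic_iam_median)
                    for r in grp.itertuples()
                ]
            )
            out.append(
                {
                    "participant": participant,
                    "structure": structure,
                    "ratio": between_ear_ratio(normal, hydropic),
                    "iam_scaled_ratio": round_half_up(
                        scaled_normal.mean() / scaled_hydropic.mean(), 1
                    ),
                    "normal_median_mean": normal.mean(),
                    "hydropic_median_mean": hydropic.mean(),
                }
            )
        return cls(pd.DataFrame(out))
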