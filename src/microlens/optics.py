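"""Micro-lens transparency and focusing quantification from focal stacks.

A focal stack holds five registered grey-scale planes of one micro-lens: the
in-focus lens plane (z=0) and four planes below it at z = f/2, f, 3f/2, 2f,
where f is the recorded focal distance. Two ratios summarise lens function,
both normalised to the surrounding culture medium (an annular background
region on the z=0 plane):

* ``transmittance_ratio`` — mean grey of the central ROI at z=0 over the
  background mean; 1.0 means the lens transmits as much light as the medium.
* ``focus_ratio`` — maximal central-ROI mean over the z>0 planes, over the
  background mean; values well above 1 indicate a bright focal spot.

The central ROI is a disc concentric with the lens whose diameter is one
quarter of the lens diameter. Group comparisons use the two-sample Student
t-test (pooled variance by default, Welch optional).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError

ROI_DIAMETER_FRACTION = 0.25  # "central quarter diameter" convention


@dataclass
class FocalStack:
    """Five registered grey-scale planes with axial offsets and lens geometry.

    ``lens_center`` is (row, col) in pixels; ``background_region`` is an
    annulus (inner_radius, outer_radius) in pixels around the lens centre,
    outside the lens disc, sampled on the z=0 plane.
    """

    planes: np.ndarray  # (5, H, W)
    z_offsets: np.ndarray  # micrometres, first = 0, strictly increasing
    lens_center: tuple[float, float]
    lens_diameter: float
    background_region: tuple[float, float]
    pixel_scale: float = 1.0  # micrometres per pixel

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        self.z_offsets = np.asarray(self.z_offsets, dtype=float)
        if self.planes.ndim != 3 or self.planes.shape[0] != 5:
            raise ValidationError("a focal stack holds exactly five planes")
        if self.z_offsets.shape != (5,):
            raise ValidationError("five z offsets required")
        if self.z_offsets[0] != 0 or np.any(np.diff(self.z_offsets) <= 0):
            raise ValidationError("z offsets must start at 0 and strictly increase")
        inner, outer = self.background_region
        if not (self.lens_diameter / 2 <= inner < outer):
            raise ValidationError("background annulus must lie outside the lens disc")
        h, w = self.planes.shape[1:]
        r0, c0 = self.lens_center
        if not (r0 - outer >= -0.5 and c0 - outer >= -0.5 and r0 + outer <= h - 0.5 and c0 + outer <= w - 0.5):
            raise ValidationError("background annulus must lie inside the image")


@dataclass
class OpticsMeasurement:
    """Per-lens summary derived from one focal stack."""

    plane_roi_means: np.ndarray
    background_mean: float
    transmittance_ratio: float
    focus_ratio: float
    focal_plane_index: int
    roi_pixel_count: int = 0


def disc_mask(shape: tuple[int, int], center: tuple[float, float], diameter: float) -> np.ndarray:
    """Boolean mask of pixels whose centres lie within the disc."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= (diameter / 2) ** 2


def central_roi(shape: tuple[int, int], lens_center: tuple[float, float], lens_diameter: float) -> np.ndarray:
    """Central-quarter-diameter circular ROI, concentric with the lens."""
    if lens_diameter < 8:
        raise ValidationError("lens too small to resolve a central-quarter ROI (need >= 8 px)")
    mask = disc_mask(shape, lens_center, lens_diameter * ROI_DIAMETER_FRACTION)
    if not mask.any():
        raise ValidationError("central ROI contains no pixels")
    return mask


def annulus_mask(shape: tuple[int, int], center: tuple[float, float], inner: float, outer: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return (r2 > inner**2) & (r2 <= outer**2)


def roi_mean_grey(image: np.ndarray, region: np.ndarray) -> float:
    """Arithmetic mean grey level over a boolean pixel region."""
    if image.shape != region.shape:
        raise ValidationError("region mask must match the image shape")
    if not region.any():
        raise DegenerateInputError("empty region")
    return float(np.asarray(image, dtype=float)[region].mean())


def measure_stack(stack: FocalStack) -> OpticsMeasurement:
    """Compute ROI means, background, transmittance and focus ratios.

    The focal plane is the z>0 plane with the highest central-ROI mean (ties
    go to the smallest z, matching an operator stopping at the first focus).
    """
    shape = stack.planes.shape[1:]
    roi = central_roi(shape, stack.lens_center, stack.lens_diameter)
    background = annulus_mask(shape, stack.lens_center, *stack.background_region)
    roi_means = np.array([roi_mean_grey(p, roi) for p in stack.planes])
    background_mean = roi_mean_grey(stack.planes[0], background)
    if background_mean == 0:
        raise DegenerateInputError("background mean is zero; cannot normalise")
    below = roi_means[1:]
    focal_plane_index = 1 + int(np.argmax(below))  # argmax takes the first maximum
    return OpticsMeasurement(
        plane_roi_means=roi_means,
        background_mean=background_mean,
        transmittance_ratio=float(roi_means[0] / background_mean),
        focus_ratio=float(below.max() / background_mean),
        focal_plane_index=focal_plane_index,
        roi_pixel_count=int(roi.sum()),
    )


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    df: float


def compare_groups(a, b, welch: bool = False) -> GroupComparison:
    """Two-sample Student t-test (pooled variance; Welch behind a flag).

    Returns the t statistic, two-sided p, and per-group mean +/- s.e.m.
    Two degenerate equal-mean, zero-variance groups give t=0, p=1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least two measurements")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        t, p, df = 0.0, 1.0, float(a.size + b.size - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        t_statistic=t,
        p_value=p,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(stats.sem(a)),
        sem_b=float(stats.sem(b)),
        df=df,
    )


def dose_response_summary(
    groups: dict[float, list[OpticsMeasurement]] | dict[float, np.ndarray],
    control_label: float,
    metric: str = "transmittance_ratio",
    welch: bool = False,
) -> pd.DataFrame:
    """Per-dose mean +/- s.e.m. and t-test against the control group.

    ``groups`` maps dose to either OpticsMeasurement lists or raw value
    arrays; rows are sorted by ascending dose; the control row carries
    t=0, p=1 (self-comparison).
    """
    if control_label not in groups:
        raise ValidationError(f"control group {control_label!r} missing")

    def extract(vals):
        vals = list(vals)
        if vals and isinstance(vals[0], OpticsMeasurement):
            return np.array([getattr(m, metric) for m in vals])
        return np.asarray(vals, dtype=float)

    control = extract(groups[control_label])
    rows = []
    for dose in sorted(groups):
        values = extract(groups[dose])
        if dose == control_label:
            t, p = 0.0, 1.0
        else:
            cmp = compare_groups(control, values, welch=welch)
            t, p = cmp.t_statistic, cmp.p_value
        rows.append(
            {
                "dose": dose,
                "n": values.size,
                "mean": values.mean(),
                "sem": float(stats.sem(values)),
                "t_vs_control": t,
                "p_vs_control": p,
            }
        )
    return pd.DataFrame(rows).set_index("dose")
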