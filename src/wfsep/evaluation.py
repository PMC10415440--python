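"""Agreement statistics for PDFF maps.

Mirrors the standard quantitative protocol for comparing a candidate
water-fat separation method against a reference: co-localised ~2 cm**2
liver ROIs per subject, ROI mean/standard deviation, ordinary least-squares
regression of candidate on reference means, Bland-Altman bias and 1.96-sigma
limits of agreement, and a one-way ANOVA with Tukey-HSD post hoc comparisons
of ROI standard deviations (a proxy for blurring).  Sample (n-1) standard
deviations are used throughout; both ROIs are pooled for the ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .signal_model import ParameterMaps, PdffMap, ValidationError

__all__ = [
    "Roi",
    "AgreementReport",
    "roi_stats",
    "ls_regression",
    "bland_altman",
    "anova_posthoc_std",
    "mae_map",
    "agreement_report",
]


@dataclass
class Roi:
    """A labelled pixel region on one slice (e.g. right/left hepatic lobe)."""

    label: str
    slice_index: int
    pixel_mask: np.ndarray

    def __post_init__(self) -> None:
        self.pixel_mask = np.asarray(self.pixel_mask, bool)
        if self.pixel_mask.ndim != 2 or not self.pixel_mask.any():
            raise ValidationError("ROI mask must be a non-empty 2-D boolean array")

    def to_json_dict(self) -> dict:
        """Run-length encoding over the flattened mask (documented schema)."""
        flat = self.pixel_mask.ravel()
        changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
        bounds = np.concatenate([[0], changes + 1, [flat.size]])
        starts, lengths = [], []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if flat[lo]:
                starts.append(int(lo))
                lengths.append(int(hi - lo))
        return {
            "label": self.label,
            "slice_index": self.slice_index,
            "shape": list(self.pixel_mask.shape),
            "rle_starts": starts,
            "rle_lengths": lengths,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "Roi":
        try:
            shape = tuple(d["shape"])
            flat = np.zeros(int(np.prod(shape)), bool)
            for s, l in zip(d["rle_starts"], d["rle_lengths"]):
                flat[s : s + l] = True
            return cls(d["label"], int(d["slice_index"]), flat.reshape(shape))
        except KeyError as exc:
            raise ValidationError(f"ROI record missing field {exc}") from exc


@dataclass
class AgreementReport:
    """Full agreement summary between a test method and the reference."""

    roi_means: dict  # method -> list of ROI means
    roi_stds: dict  # method -> list of ROI sample STDs
    slope: float
    intercept: float
    r_squared: float
    bias: float
    loa_low: float
    loa_high: float
    anova_p: float
    posthoc: list  # (method_a, method_b, p_value, significant)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValidationError("limits of agreement must bracket the bias")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValidationError("R^2 must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "roi_means": {k: list(map(float, v)) for k, v in self.roi_means.items()},
            "roi_stds": {k: list(map(float, v)) for k, v in self.roi_stds.items()},
            "regression": {
                "slope": self.slope,
                "intercept": self.intercept,
                "r_squared": self.r_squared,
            },
            "bland_altman": {
                "bias": self.bias,
                "loa_low": self.loa_low,
                "loa_high": self.loa_high,
            },
            "anova": {
                "p_value": self.anova_p,
                "posthoc": [
                    {"pair": [a, b], "p_value": p, "significant": bool(s)}
                    for a, b, p, s in self.posthoc
                ],
            },
            "alpha": self.alpha,
        }


def roi_stats(pdff: PdffMap, roi: Roi) -> tuple[float, float]:
    """Mean and sample standard deviation of PDFF over in-mask ROI pixels."""
    if roi.pixel_mask.shape != pdff.values.shape:
        raise ValidationError("ROI and map shapes differ")
    sel = roi.pixel_mask & pdff.mask
    if not sel.any():
        raise ValidationError(f"ROI {roi.label!r} does not intersect the map mask")
    vals = pdff.values[sel]
    std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), std


def ls_regression(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x; returns (slope, intercept, R^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("regression needs >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValidationError("regression undefined for zero-variance x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bias and 1.96-sigma limits of agreement of differences y - x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("Bland-Altman needs >= 3 paired points")
    d = y - x
    bias = float(d.mean())
    spread = 1.96 * float(d.std(ddof=1))
    return bias, bias - spread, bias + spread


def anova_posthoc_std(groups: dict, alpha: float = 0.05):
    """One-way ANOVA + Tukey-HSD pairwise comparisons of ROI STD groups.

    ``groups`` maps method name to a vector of ROI standard deviations.
    Returns ``(anova_p, posthoc)`` where posthoc is a list of
    ``(method_a, method_b, p_value, significant)``.  When every group is
    constant and identical (zero total variance) the comparison is
    vacuous: p = 1 for all pairs, flagged non-significant.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(groups[n], float) for n in names]
    if any(a.size < 2 for a in arrays):
        raise ValidationError("each group needs at least two values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        pairs = [
            (names[i], names[j], 1.0, False)
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        return 1.0, pairs
    anova_p = float(stats.f_oneway(*arrays).pvalue)
    tukey = stats.tukey_hsd(*arrays)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(tukey.pvalue[i, j])
            pairs.append((names[i], names[j], p, p < alpha))
    return anova_p, pairs


def mae_map(pred: ParameterMaps, ref: ParameterMaps, mask=None) -> dict:
    """In-mask mean absolute error per output map (plus PDFF).

    Water/fat are compared on magnitudes (network outputs are magnitude
    images); PDFF uses the zero-signal convention on both sides.
    """
    if pred.shape != ref.shape:
        raise ValidationError("map shapes differ")
    if mask is None:
        mask = pred.mask & ref.mask
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValidationError("empty comparison mask")

    def pdff_of(m: ParameterMaps) -> np.ndarray:
        aw, af = np.abs(m.water), np.abs(m.fat)
        denom = aw + af
        out = np.zeros(m.shape)
        nz = denom > 0
        out[nz] = af[nz] / denom[nz]
        return out

    return {
        "water": float(np.abs(np.abs(pred.water) - np.abs(ref.water))[mask].mean()),
        "fat": float(np.abs(np.abs(pred.fat) - np.abs(ref.fat))[mask].mean()),
        "r2star_per_s": float(np.abs(pred.r2star_per_s - ref.r2star_per_s)[mask].mean()),
        "fieldmap_hz": float(np.abs(pred.fieldmap_hz - ref.fieldmap_hz)[mask].mean()),
        "pdff": float(np.abs(pdff_of(pred) - pdff_of(ref))[mask].mean()),
    }


def agreement_report(
    reference_rois: list, test_rois: list, reference_name: str = "reference",
    test_name: str = "test", alpha: float = 0.05,
) -> AgreementReport:
    """Assemble the full report from paired per-ROI (mean, std) tuples.

    ``reference_rois``/``test_rois`` are equal-length lists of (mean, std)
    pairs, co-localised ROI by ROI.
    """
    if len(reference_rois) != len(test_rois) or len(reference_rois) < 3:
        raise ValidationError("need >= 3 co-localised ROI pairs")
    ref_means = [m for m, _ in reference_rois]
    ref_stds = [s for _, s in reference_rois]
    test_means = [m for m, _ in test_rois]
    test_stds = [s for _, s in test_rois]
    slope, intercept, r2 = ls_regression(ref_means, test_means)
    bias, lo, hi = bland_altman(ref_means, test_means)
    anova_p, pairs = anova_posthoc_std(
        {reference_name: ref_stds, test_name: test_stds}, alpha=alpha
    )
    return AgreementReport(
        roi_means={reference_name: ref_means, test_name: test_means},
        roi_stds={reference_name: ref_stds, test_name: test_stds},
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        anova_p=anova_p,
        posthoc=pairs,
        alpha=alpha,
    )
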