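"""External calibration against matrix-matched gelatine standards.

Spiked-gelatine blocks are ablated like tissue (5 lines x 200 pixels per
standard); the mean intensity of each standard is regressed (ordinary least
squares) against its independently cross-quantified concentration.  The
limit of quantification follows the 10-sigma convention,

    LOQ = 10 * SD(blank pixels) / slope,

and calibrated maps carry a below-LOQ flag mask rather than censoring.
An element without its own standards (Ba here) can be converted to a
pseudo-concentration through a single-point response factor borrowed from a
reference element's spiked standard (Sr at 1.31 ug/g).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps

from .imaging import ElementImage, Mask

#: R^2 below which a calibration is flagged as suspect.
R2_WARN = 0.98


@dataclass
class StandardMeasurement:
    """Ablation of one gelatine standard: line scans plus its nominal and
    independently measured (acid digestion) concentration in ug/g."""

    element: str
    nominal_conc: float
    measured_conc: float
    lines: list[np.ndarray]

    def __post_init__(self) -> None:
        if self.measured_conc < 0:
            raise ValueError("measured_conc must be nonnegative")
        if not self.lines:
            raise ValueError("standard must have at least one ablated line")
        self.lines = [np.asarray(l, dtype=float).ravel() for l in self.lines]

    @property
    def pixels(self) -> np.ndarray:
        return np.concatenate(self.lines)

    @property
    def mean_intensity(self) -> float:
        return float(self.pixels.mean())

    @property
    def is_blank(self) -> bool:
        return self.nominal_conc == 0


@dataclass
class CalibrationCurve:
    """Per-element calibration: intensity = slope * conc + intercept."""

    element: str
    slope: float
    intercept: float
    r_squared: float
    blank_sd: float
    loq: float
    range: tuple[float, float]


@dataclass
class NormalizationParams:
    """Single-point response factor borrowed from a reference element."""

    reference_element: str = "88Sr"
    reference_conc: float = 1.31
    reference_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.reference_conc <= 0:
            raise ValueError("reference_conc must be positive")
        if self.reference_intensity <= 0:
            raise ValueError("reference_intensity must be positive")


@dataclass
class ConcentrationMap:
    """Calibrated (or reference-normalized) concentration field in ug/g.

    Below-LOQ pixels are flagged (``below_loq``), never censored; negative
    calibrated values are retained and counted so low-concentration medians
    are not biased upward.
    """

    element: str
    data: np.ndarray
    unit: str = "ug/g"
    below_loq: Optional[Mask] = None
    n_negative: int = 0
    curve: Optional[CalibrationCurve] = field(default=None, repr=False)


def loq(blank_sd: float, slope: float) -> float:
    """Limit of quantification: 10 * blank SD / calibration slope (ug/g)."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if blank_sd < 0:
        raise ValueError("blank_sd must be nonnegative")
    return 10.0 * blank_sd / slope


def fit_calibration(standards: list[StandardMeasurement]) -> CalibrationCurve:
    """OLS calibration from standard line scans.

    Mean intensity per standard (pooled over all its line pixels) is
    regressed on the independently measured concentration.  The blank SD is
    the sample SD of all blank pixels pooled across lines.  Warns when
    R^2 < 0.98 (well-behaved gelatine calibrations run 0.987-0.997).
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 standards (including a blank)")
    elements = {s.element for s in standards}
    if len(elements) != 1:
        raise ValueError(f"standards mix elements: {sorted(elements)}")
    element = standards[0].element
    blanks = [s for s in standards if s.is_blank]
    if not blanks:
        raise ValueError(f"{element}: no blank (zero-concentration) standard")

    x = np.array([s.measured_conc for s in standards])
    y = np.array([s.mean_intensity for s in standards])
    fit = sps.linregress(x, y)
    if fit.slope <= 0:
        raise ValueError(f"{element}: non-positive calibration slope "
                         f"({fit.slope:.3g}); calibration uninterpretable")
    r2 = float(fit.rvalue ** 2)
    if r2 < R2_WARN:
        warnings.warn(f"{element}: calibration R^2 = {r2:.4f} < {R2_WARN}",
                      UserWarning, stacklevel=2)
    blank_pixels = np.concatenate([s.pixels for s in blanks])
    blank_sd = float(blank_pixels.std(ddof=1)) if blank_pixels.size > 1 else 0.0
    return CalibrationCurve(
        element=element,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        blank_sd=blank_sd,
        loq=loq(blank_sd, float(fit.slope)),
        range=(float(x.min()), float(x.max())),
    )


def apply_calibration(image: ElementImage, curve: CalibrationCurve) -> ConcentrationMap:
    """Convert an intensity map to ug/g: conc = (I - intercept) / slope."""
    if image.isotope != curve.element:
        raise ValueError(
            f"element mismatch: image {image.isotope!r} vs curve {curve.element!r}")
    conc = (image.data - curve.intercept) / curve.slope
    return ConcentrationMap(
        element=curve.element,
        data=conc,
        below_loq=Mask(conc < curve.loq),
        n_negative=int((conc < 0).sum()),
        curve=curve,
    )


def normalize_by_standard(image: ElementImage, params: NormalizationParams) -> ConcentrationMap:
    """Response-factor pseudo-quantification against a reference standard.

    Each pixel is scaled by reference_conc / reference_intensity.  The
    result is in reference-element-equivalent ug/g: a response-factor
    estimate, not a matrix-matched calibration, so no LOQ is attached.
    """
    data = image.data * (params.reference_conc / params.reference_intensity)
    return ConcentrationMap(
        element=image.isotope,
        data=data,
        unit=f"ug/g ({params.reference_element}-equivalent)",
        below_loq=None,
        n_negative=0,
    )
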