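"""Biochemical quantification: colorimetric/fluorometric standard curves,
mass normalization, and masked-intensity fluorescence ratios.

Standard curves are straight lines on the stated working ranges
(sGAG 0-25, DNA 0-4 assay units, eight standards each); the blank is
the zero-concentration standard and is subtracted before fitting and
inverse prediction.  Image intensities are 12-bit integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StandardCurve",
    "TissueSample",
    "IHCImageSet",
    "QuantResult",
    "fit_standard_curve",
    "quantify_sample",
    "gag_dna_ratio",
    "normalized_fluorescence",
    "WORKING_RANGES",
]

WORKING_RANGES = {"sGAG": (0.0, 25.0), "DNA": (0.0, 4.0)}

MAX_12BIT = 4095


@dataclass
class StandardCurve:
    """Fitted linear absorbance-vs-concentration relation for one analyte."""

    analyte: str
    concentrations: np.ndarray
    absorbances: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    blank: float
    working_range: tuple[float, float]

    def predict(self, concentration: float) -> float:
        """Blank-subtracted absorbance expected at ``concentration``."""
        return self.slope * concentration + self.intercept

    def inverse(self, absorbance: float) -> tuple[float, bool]:
        """Concentration from a blank-subtracted absorbance.

        Returns ``(concentration, extrapolated)``; extrapolation beyond
        the working range is flagged, not refused.
        """
        conc = (absorbance - self.intercept) / self.slope
        lo, hi = self.working_range
        return conc, bool(conc < lo - 1e-12 or conc > hi + 1e-12)


@dataclass
class TissueSample:
    """One scleral digest with triplicate plate readings per assay."""

    sample_id: str
    dry_mass_mg: float  # mean of three weighings
    digest_volume_uL: float = 200.0
    absorbances: dict[str, np.ndarray] = field(default_factory=dict)
    aliquot_fraction: dict[str, float] = field(default_factory=dict)
    dilution_factor: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dry_mass_mg > 0:
            raise ValueError("dry mass must be positive")


@dataclass
class QuantResult:
    sample_id: str
    analyte: str
    concentration: float  # ug/uL in the digest
    total_ug: float
    mass_fraction_ug_per_mg: float
    blank_limited: bool
    extrapolated: bool


@dataclass
class IHCImageSet:
    """Two-channel confocal intensities for the three enzyme conditions.

    ``images`` maps condition ("ChB", "ChAC", "buffer") to a 2-D 12-bit
    intensity array; ``mask`` is the manually drawn scleral mask and
    ``optic_nerve_row`` the row index splitting superior from inferior.
    """

    images: dict[str, np.ndarray]
    mask: np.ndarray
    optic_nerve_row: int

    def __post_init__(self) -> None:
        shapes = {k: v.shape for k, v in self.images.items()}
        for cond in ("ChB", "ChAC", "buffer"):
            if cond not in self.images:
                raise ValueError(f"missing condition {cond!r}")
        if len(set(shapes.values())) != 1 or self.mask.shape not in shapes.values():
            raise ValueError("images and mask must share a shape")
        if not self.mask.any():
            raise ValueError("mask is empty")

    def saturation_fraction(self, condition: str) -> float:
        img = self.images[condition]
        return float(np.mean(img[self.mask] >= MAX_12BIT))


def fit_standard_curve(
    concentrations,
    absorbances,
    analyte: str = "sGAG",
    *,
    noise_tolerance: float = 0.05,
) -> StandardCurve:
    """Ordinary least-squares line through blank-subtracted standards.

    The blank is the mean absorbance of the zero-concentration
    standard(s).  Standards that are non-monotone beyond the noise
    tolerance (relative to the fitted span) raise an error instead of
    silently switching functional form.
    """
    conc = np.asarray(concentrations, dtype=float)
    absb = np.asarray(absorbances, dtype=float)
    if conc.shape != absb.shape:
        raise ValueError("concentrations and absorbances must align")
    if len(np.unique(conc)) < 2:
        raise ValueError("need at least 2 distinct standard concentrations")
    order = np.argsort(conc)
    conc, absb = conc[order], absb[order]
    zero = conc == 0
    blank = float(absb[zero].mean()) if zero.any() else 0.0
    y = absb - blank

    slope, intercept = np.polyfit(conc, y, 1)
    fitted = slope * conc + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    span = float(np.ptp(y))
    drops = np.diff(y)
    if span > 0 and np.any(drops < -noise_tolerance * span):
        raise ValueError("standards are non-monotone beyond noise tolerance")
    if slope <= 0:
        raise ValueError("fitted response is not increasing")

    working = WORKING_RANGES.get(analyte, (float(conc.min()), float(conc.max())))
    return StandardCurve(
        analyte=analyte,
        concentrations=conc,
        absorbances=absb,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        blank=blank,
        working_range=working,
    )


def quantify_sample(
    sample: TissueSample, curve: StandardCurve
) -> QuantResult:
    """Mass fraction (ug analyte per mg dry sclera) for one assay.

    Triplicates are averaged, the blank subtracted, and the digest
    concentration inverse-predicted from the standard curve; the total
    analyte is concentration x digest volume (the aliquot carries the
    digest concentration, corrected by any recorded dilution factor).
    A mean absorbance at or below blank is reported as zero with a flag.
    """
    analyte = curve.analyte
    if analyte not in sample.absorbances:
        raise ValueError(f"sample has no {analyte!r} readings")
    triplicate = np.asarray(sample.absorbances[analyte], dtype=float)
    mean_abs = float(triplicate.mean()) - curve.blank
    dilution = sample.dilution_factor.get(analyte, 1.0)
    if mean_abs <= 1e-12:  # at or below blank (within float tolerance)
        return QuantResult(
            sample_id=sample.sample_id,
            analyte=analyte,
            concentration=0.0,
            total_ug=0.0,
            mass_fraction_ug_per_mg=0.0,
            blank_limited=True,
            extrapolated=False,
        )
    conc, extrapolated = curve.inverse(mean_abs)
    conc *= dilution  # back to digest concentration
    total = conc * sample.digest_volume_uL
    return QuantResult(
        sample_id=sample.sample_id,
        analyte=analyte,
        concentration=conc,
        total_ug=total,
        mass_fraction_ug_per_mg=total / sample.dry_mass_mg,
        blank_limited=False,
        extrapolated=extrapolated,
    )


def gag_dna_ratio(gag: QuantResult, dna: QuantResult) -> float:
    """Per-eye ug sGAG per ug DNA (ratio of this eye's mass fractions)."""
    if dna.mass_fraction_ug_per_mg <= 0:
        raise ValueError("DNA mass fraction must be positive for the ratio")
    return gag.mass_fraction_ug_per_mg / dna.mass_fraction_ug_per_mg


def _region_mask(images: IHCImageSet, region: str) -> np.ndarray:
    mask = images.mask.astype(bool)
    if region == "whole":
        return mask
    split = np.zeros_like(mask)
    if region == "superior":
        split[: images.optic_nerve_row, :] = True
    elif region == "inferior":
        split[images.optic_nerve_row + 1 :, :] = True
    else:
        raise ValueError(f"unknown region {region!r}")
    out = mask & split
    if not out.any():
        raise ValueError(f"empty mask for region {region!r}")
    return out


def normalized_fluorescence(
    images: IHCImageSet, region: str = "whole"
) -> dict[str, float]:
    """Masked mean-intensity ratios relative to the buffer-only section.

    DS is the ChB/buffer ratio; C4S the ChAC/buffer ratio.  The regional
    variants restrict the mask to one side of the optic nerve.
    """
    mask = _region_mask(images, region)
    means = {cond: float(img[mask].mean()) for cond, img in images.images.items()}
    if means["buffer"] <= 0:
        raise ValueError("buffer-only mean intensity is zero")
    return {
        "DS": means["ChB"] / means["buffer"],
        "C4S": means["ChAC"] / means["buffer"],
    }
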