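"""Linear P4-equivalent calibration and unit conversions.

Within the linear low-dose regime (0–1 nM progesterone) the normalized
translocation y follows a straight line in concentration x:

    y = slope * x + intercept        (assay standard line)

so an unknown sample's progesterone-equivalent concentration (P4-EQ) is the
inverse, x = (y - intercept) / slope, in nM at the tested strength. Because
y is vehicle-normalized, y = 1 at x = 0 by construction, and the intercept
is fixed at 1 by default when fitting standards. Enriched extracts (e.g.
200x solid-phase-extracted water) are corrected back to source strength by
dividing by the concentration factor, and nM converts to ng/L through the
analyte's molar mass (g/mol numerically equals ng/nmol).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

#: molar mass of progesterone, g/mol
PROGESTERONE_MOLAR_MASS = 314.46


@dataclass(frozen=True)
class CalibrationCurve:
    """Standard line y = slope * x + intercept with its validity range (nM)."""

    slope: float
    intercept: float = 1.0
    r_squared: float = float("nan")
    conc_range: tuple[float, float] = (0.0, 1.0)
    degenerate: bool = False

    def forward(self, conc):
        return self.slope * np.asarray(conc, dtype=float) + self.intercept

    def inverse(self, y):
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0 to invert")
        return (np.asarray(y, dtype=float) - self.intercept) / self.slope

    @classmethod
    def fit(cls, concs, y, fix_intercept_at_1: bool = True) -> "CalibrationCurve":
        return fit_calibration(concs, y, fix_intercept_at_1=fix_intercept_at_1)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self))
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source) -> "CalibrationCurve":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["conc_range"] = tuple(d["conc_range"])
        return cls(**d)


def fit_calibration(concs, y, fix_intercept_at_1: bool = True) -> CalibrationCurve:
    """Fit the standard line to (concentration, normalized translocation).

    With the intercept fixed at 1 (default) the slope is the least-squares
    slope of (y - 1) on x through the origin; otherwise an ordinary
    two-parameter fit. R^2 is computed against the fitted line. A flat
    standard series (all y equal) is returned flagged ``degenerate`` with
    slope 0 and undefined R^2.
    """
    x = np.asarray(concs, dtype=float)
    yv = np.asarray(y, dtype=float)
    if x.shape != yv.shape or x.ndim != 1:
        raise ValueError("concs and y must be 1-D and the same length")
    distinct = np.unique(x)
    if distinct.size < 2:
        raise ValueError("all concentrations identical; cannot fit a line")
    if distinct.size < 3 or 0.0 not in distinct:
        raise ValueError("need >= 3 distinct concentrations including 0")

    if fix_intercept_at_1:
        intercept = 1.0
        denom = float(np.sum(x * x))
        slope = float(np.sum(x * (yv - 1.0)) / denom)
    else:
        slope_f, intercept_f = np.polyfit(x, yv, 1)
        slope, intercept = float(slope_f), float(intercept_f)

    fitted = slope * x + intercept
    ss_res = float(np.sum((yv - fitted) ** 2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    degenerate = ss_tot == 0.0
    r2 = float("nan") if degenerate else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        conc_range=(float(distinct.min()), float(distinct.max())),
        degenerate=degenerate,
    )


def p4_equivalent(y: float, curve: CalibrationCurve) -> float:
    """P4-EQ (nM, assay strength) for a normalized translocation value.

    Readings below the intercept (below-vehicle) are clamped to 0 nM with a
    warning; values above the calibrated concentration range are returned
    but flagged as extrapolated via a warning.
    """
    x = float(curve.inverse(y))
    if x < 0:
        warnings.warn(
            f"normalized translocation {y} below the vehicle level; "
            "P4-EQ clamped to 0 nM",
            stacklevel=2,
        )
        return 0.0
    if x > curve.conc_range[1]:
        warnings.warn(
            f"P4-EQ {x:.3g} nM lies above the calibrated range "
            f"{curve.conc_range}; extrapolated",
            stacklevel=2,
        )
    return x


def nm_to_ngl(conc_nm: float, molar_mass: float = PROGESTERONE_MOLAR_MASS) -> float:
    """nM -> ng/L (molar mass in g/mol equals ng/nmol numerically)."""
    return conc_nm * molar_mass


def ngl_to_nm(conc_ngl: float, molar_mass: float = PROGESTERONE_MOLAR_MASS) -> float:
    """ng/L -> nM."""
    return conc_ngl / molar_mass


@dataclass(frozen=True)
class SampleP4EQ:
    """A sample's P4-EQ at assay strength and back-calculated source strength."""

    sample: str
    y: float
    p4eq_assay_nM: float
    concentration_factor: float
    p4eq_source_nM: float
    p4eq_source_ngL: float


def to_source_concentration(
    p4eq_assay_nm: float,
    concentration_factor: float = 200.0,
    molar_mass: float = PROGESTERONE_MOLAR_MASS,
    sample: str = "",
    y: float = float("nan"),
) -> SampleP4EQ:
    """Back-calculate a source-water P4-EQ from the assayed (enriched) one."""
    if concentration_factor < 1:
        raise ValueError("concentration_factor must be >= 1")
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    source_nm = p4eq_assay_nm / concentration_factor
    return SampleP4EQ(
        sample=sample,
        y=y,
        p4eq_assay_nM=p4eq_assay_nm,
        concentration_factor=concentration_factor,
        p4eq_source_nM=source_nm,
        p4eq_source_ngL=nm_to_ngl(source_nm, molar_mass),
    )
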