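"""Linear-calibration utilities for photometric oil assays.

Converts raw absorbance readings into the working units of the pipeline:
peroxide value (micro-equivalents O2 per g oil, ferric-thiocyanate
chemistry), total phenolic concentration (mg caffeic acid per g oil,
Folin-Ciocalteu) and DPPH radical-scavenging activity (micromol trolox per
g oil).  Every assay has an explicit forward model so the inverse can be
round-trip tested.  Also covers spin-trap dilution arithmetic and oil-yield
bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "linear_calibration",
    "peroxide_value",
    "absorbance_from_pv",
    "total_phenolics",
    "absorbance_from_tpc",
    "rsa_dpph",
    "absorbance_from_rsa",
    "pbn_final_concentration",
    "oil_yield",
]

# Fe(III) calibration range used for the peroxide assay, mol/L
FE_RANGE_M = (6.1e-5, 4.6e-4)
# Folin-Ciocalteu dilution chain defaults: 200 uL aliquot brought to 10 mL
TPC_ALIQUOT_ML = 0.2
TPC_FINAL_ML = 10.0
TPC_EXTRACT_ML = 5.0
# total liquid volume of the peroxide assay mixture, L (9.8 mL solvent + 2x50 uL)
PV_ASSAY_VOLUME_L = 9.9e-3


class CalibrationRangeWarning(UserWarning):
    """Reading falls outside the concentration range of the standards."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Ordinary-least-squares line mapping concentration (x) to response (y)."""

    slope: float
    intercept: float
    r_squared: float
    x_unit: str = ""
    y_unit: str = "absorbance"
    range: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")
        if not self.range[0] < self.range[1]:
            raise ValueError("range min must be < range max")

    def forward(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def inverse(self, response: float, warn_out_of_range: bool = True) -> float:
        if self.slope == 0:
            raise ZeroDivisionError("calibration slope is zero")
        conc = (response - self.intercept) / self.slope
        if warn_out_of_range and not (self.range[0] <= conc <= self.range[1]):
            warnings.warn(
                f"concentration {conc:.4g} outside calibration range {self.range}",
                CalibrationRangeWarning,
                stacklevel=2,
            )
        return conc


def linear_calibration(
    standards: Sequence[tuple[float, float]],
    x_unit: str = "",
    y_unit: str = "absorbance",
) -> CalibrationCurve:
    """Fit a calibration line to >= 3 (concentration, response) standards."""
    pts = list(standards)
    if len(pts) < 3:
        raise ValueError("at least 3 calibration standards are required")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("standards must span at least 2 distinct concentrations")
    if np.allclose(y, y[0]):
        warnings.warn("constant responses: calibration is degenerate", stacklevel=2)
        return CalibrationCurve(0.0, float(y[0]), 0.0, x_unit, y_unit,
                                (float(x.min()), float(x.max())))
    res = stats.linregress(x, y)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        x_unit=x_unit,
        y_unit=y_unit,
        range=(float(x.min()), float(x.max())),
    )


def peroxide_value(
    abs_sample: float,
    abs_blank: float,
    curve: CalibrationCurve,
    oil_mass: float,
    assay_volume_l: float = PV_ASSAY_VOLUME_L,
) -> float:
    """Peroxide value in micro-equivalents O2 per g oil.

    The blank-subtracted 507 nm absorbance is converted to the Fe(III)
    concentration (mol/L) via the calibration, then to micro-equivalents
    using the stoichiometry 2 Fe(III) per peroxide — i.e. 1 umol Fe(III)
    equals 1 micro-equivalent of peroxide oxygen.
    """
    if oil_mass <= 0:
        raise ValueError("oil_mass must be positive")
    net = abs_sample - abs_blank
    if net <= 0:
        return 0.0
    fe_molar = curve.inverse(net + curve.intercept, warn_out_of_range=True)
    ueq = fe_molar * assay_volume_l * 1e6  # umol Fe(III) == micro-equivalents
    return ueq / oil_mass


def absorbance_from_pv(
    pv: float,
    curve: CalibrationCurve,
    oil_mass: float,
    abs_blank: float = 0.0,
    assay_volume_l: float = PV_ASSAY_VOLUME_L,
) -> float:
    """Forward model of :func:`peroxide_value` (for round-trip checks)."""
    fe_molar = pv * oil_mass / (assay_volume_l * 1e6)
    return curve.forward(fe_molar) - curve.intercept + abs_blank


def total_phenolics(
    absorbance: float,
    curve: CalibrationCurve,
    extract_volume_ml: float = TPC_EXTRACT_ML,
    final_volume_ml: float = TPC_FINAL_ML,
    aliquot_volume_ml: float = TPC_ALIQUOT_ML,
    oil_mass: float = 2.5,
) -> float:
    """Total phenolics as mg caffeic acid per g oil.

    Reading (mg/mL caffeic acid in the assay mixture) x dilution factor
    (final/aliquot) gives the extract concentration; times the extract
    volume and per gram of oil gives the result.
    """
    for name, v in (
        ("extract_volume_ml", extract_volume_ml),
        ("final_volume_ml", final_volume_ml),
        ("aliquot_volume_ml", aliquot_volume_ml),
        ("oil_mass", oil_mass),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    conc = curve.inverse(absorbance)
    if conc < 0:
        conc = 0.0
    return conc * (final_volume_ml / aliquot_volume_ml) * extract_volume_ml / oil_mass


def absorbance_from_tpc(
    tpc: float,
    curve: CalibrationCurve,
    extract_volume_ml: float = TPC_EXTRACT_ML,
    final_volume_ml: float = TPC_FINAL_ML,
    aliquot_volume_ml: float = TPC_ALIQUOT_ML,
    oil_mass: float = 2.5,
) -> float:
    """Forward model of :func:`total_phenolics`."""
    conc = tpc * oil_mass / (extract_volume_ml * (final_volume_ml / aliquot_volume_ml))
    return curve.forward(conc)


def rsa_dpph(
    abs_control: float,
    abs_sample: float,
    trolox_curve: CalibrationCurve,
    oil_mass: float,
) -> float:
    """Radical-scavenging activity in micromol trolox per g oil.

    The inhibition fraction (A0 - A)/A0 is mapped through a trolox
    calibration (x = umol trolox in the assay, y = inhibition fraction) and
    normalised by the oil mass.  A sample absorbance above the control is
    clipped to zero inhibition with a warning.
    """
    if abs_control <= 0:
        raise ValueError("control absorbance must be positive")
    if oil_mass <= 0:
        raise ValueError("oil_mass must be positive")
    inhibition = (abs_control - abs_sample) / abs_control
    if inhibition < 0:
        warnings.warn("sample absorbance exceeds control; clipping inhibition to 0",
                      stacklevel=2)
        inhibition = 0.0
    umol = trolox_curve.inverse(inhibition)
    if umol < 0:
        umol = 0.0
    return umol / oil_mass


def absorbance_from_rsa(
    rsa: float,
    abs_control: float,
    trolox_curve: CalibrationCurve,
    oil_mass: float,
) -> float:
    """Forward model of :func:`rsa_dpph`."""
    inhibition = trolox_curve.forward(rsa * oil_mass)
    return abs_control * (1.0 - inhibition)


def pbn_final_concentration(
    stock_volume_ul: float, stock_conc_m: float, oil_volume_ul: float
) -> float:
    """Spin-trap concentration (mM) after drying the stock into the oil.

    The solvent evaporates so only the solute carries over; the final volume
    is the oil volume alone.
    """
    if stock_volume_ul < 0 or stock_conc_m < 0:
        raise ValueError("stock volume and concentration must be non-negative")
    if oil_volume_ul <= 0:
        raise ValueError("oil volume must be positive")
    return 1000.0 * stock_volume_ul * stock_conc_m / oil_volume_ul


def oil_yield(oil_mass: float, seed_mass: float) -> float:
    """Extraction yield as % (w/w) of oil over seed weight."""
    if oil_mass < 0 or seed_mass <= 0:
        raise ValueError("masses must be positive (oil mass may be zero)")
    if oil_mass > seed_mass:
        raise ValueError("oil mass cannot exceed seed mass")
    return 100.0 * oil_mass / seed_mass
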