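"""Cloud-point (Tc) extraction from turbidity ramps and partition
coefficients between dense and light phases.

The cloud point of a solution that demixes on heating (LCST regime) is
read off an absorbance-vs-temperature ramp as the temperature of the
maximum of the first-order derivative of the (optionally smoothed) curve.
Partition coefficients follow the dense-phase dilution protocol:
P = c_dense_measured * D / c_light, where D is the dilution factor applied
to dissolve the dense phase (default 9).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .datatypes import Curve

__all__ = [
    "CloudPoint",
    "cloud_point",
    "PartitionMeasurement",
    "partition_coefficient",
    "calibration_concentration",
]


@dataclass
class CloudPoint:
    """Cloud-point estimate with a quality flag.

    flag: ``clear`` (derivative peak well above noise), ``flat`` (no
    transition detected; Tc is NaN), ``edge`` (maximum at a grid boundary,
    transition likely outside the ramp).
    """

    Tc: float
    peak_height: float
    flag: str
    derivative: np.ndarray | None = None


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    if window % 2 == 0:
        window += 1
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(ypad, kernel, mode="valid")


def cloud_point(curve: Curve, smooth_window: int = 5) -> CloudPoint:
    """Cloud point as the temperature of the first-derivative maximum.

    The absorbance trace is smoothed with a centered moving average
    (``smooth_window`` points), differentiated with centered finite
    differences, and the maximum of the derivative located on the rising
    edge. The estimate is flagged ``flat`` when the peak height is below
    5x the derivative noise floor (robust MAD estimate), and ``edge`` when
    the maximum falls on a grid boundary.
    """
    T, y = curve.x, curve.y
    if T.size < 10:
        raise ValueError("need >= 10 temperature points")
    if not np.all(np.diff(T) > 0):
        raise ValueError("temperature grid must be strictly increasing")
    ys = _moving_average(y, smooth_window)
    dy = np.gradient(ys, T)
    # noise floor: robust s.d. of the derivative about its own local trend,
    # so broad genuine transitions are not mistaken for noise
    resid = dy - _moving_average(dy, 5)
    noise_floor = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    idx = int(np.argmax(dy))
    peak = float(dy[idx] - np.median(dy))
    if y.max() == y.min() or peak <= 5 * noise_floor or peak <= 0:
        return CloudPoint(Tc=float("nan"), peak_height=peak, flag="flat", derivative=dy)
    # edge detection on the raw derivative: the moving-average edge padding
    # flattens the smoothed tail, hiding a transition still rising off-ramp
    raw_idx = int(np.argmax(np.gradient(y, T)))
    at_edge = idx in (0, T.size - 1) or raw_idx in (0, T.size - 1)
    flag = "edge" if at_edge else "clear"
    return CloudPoint(Tc=float(T[idx]), peak_height=peak, flag=flag, derivative=dy)


@dataclass
class PartitionMeasurement:
    """Dense/light partition coefficient with optional propagated s.d."""

    P: float
    c_light: float
    c_dense_measured: float
    dilution_factor: float
    P_sd: float | None = None


def partition_coefficient(
    c_light: float,
    c_dense_measured: float,
    D: float = 9.0,
    c_light_sd: float | None = None,
    c_dense_sd: float | None = None,
) -> PartitionMeasurement:
    """P = c_dense_measured * D / c_light.

    ``c_dense_measured`` is the concentration measured after the dense
    phase was diluted ``D``-fold to dissolve it (default 9). If standard
    deviations are given, the s.d. of P is propagated to first order
    (independent errors).
    """
    if c_light <= 0:
        raise ValueError("c_light must be positive (P undefined otherwise)")
    if D < 1:
        raise ValueError("dilution factor must be >= 1")
    P = c_dense_measured * D / c_light
    P_sd = None
    if c_light_sd is not None or c_dense_sd is not None:
        rel2 = 0.0
        if c_dense_sd is not None:
            rel2 += (c_dense_sd / c_dense_measured) ** 2
        if c_light_sd is not None:
            rel2 += (c_light_sd / c_light) ** 2
        P_sd = abs(P) * float(np.sqrt(rel2))
    return PartitionMeasurement(
        P=float(P),
        c_light=float(c_light),
        c_dense_measured=float(c_dense_measured),
        dilution_factor=float(D),
        P_sd=P_sd,
    )


def calibration_concentration(
    peak_area: float, calibration: np.ndarray
) -> tuple[float, bool]:
    """Inverse-predict a concentration from an HPLC peak area.

    ``calibration`` is an (n >= 4, 2) array of (concentration, area)
    standards. An ordinary least-squares line is fitted through the
    standards and inverted. Returns ``(concentration, extrapolated)``;
    ``extrapolated`` is True when the measured area falls outside the
    calibrated range.
    """
    cal = np.asarray(calibration, dtype=float)
    if cal.ndim != 2 or cal.shape[1] != 2 or cal.shape[0] < 4:
        raise ValueError("calibration needs >= 4 (concentration, area) points")
    conc, area = cal[:, 0], cal[:, 1]
    fit = linregress(conc, area)
    if fit.slope == 0:
        raise ValueError("calibration line has zero slope")
    estimate = (peak_area - fit.intercept) / fit.slope
    extrapolated = not (area.min() <= peak_area <= area.max())
    return float(estimate), bool(extrapolated)
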