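"""FRAP double normalization and single-exponential recovery fitting.

The analysis follows the easyFRAP convention: the bleached-ROI signal is
background-corrected, divided by the background-corrected whole-cell signal
(cancelling acquisition bleaching), scaled so the pre-bleach mean is 1, and
fitted for t >= 0 with

    N(t) = I0 + (Finf - I0) * (1 - exp(-k t))

yielding mobile fraction (Finf - I0) / (1 - I0) and half-time of recovery
t1/2 = ln 2 / k.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .datatypes import TimeTrace

logger = logging.getLogger(__name__)

__all__ = [
    "FRAPTrace",
    "FrapFitError",
    "normalize_double",
    "FrapRecoveryModel",
    "FrapRecoveryResults",
    "fit_recovery",
]


class FrapFitError(RuntimeError):
    """Degenerate or non-convergent FRAP fit."""


@dataclass
class FRAPTrace:
    """Raw three-ROI FRAP record; t < 0 marks pre-bleach frames."""

    t: np.ndarray
    bleach: np.ndarray
    whole: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("bleach", "whole", "background"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != self.t.shape:
                raise ValueError(f"{name} length must match t")
            setattr(self, name, v)
        if (self.t < 0).sum() < 2:
            raise ValueError("need >= 2 pre-bleach frames (t < 0)")

    @classmethod
    def from_traces(cls, traces: dict[str, TimeTrace]) -> "FRAPTrace":
        return cls(
            traces["bleach"].t,
            traces["bleach"].value,
            traces["whole"].value,
            traces["background"].value,
        )

    @classmethod
    def from_csv(cls, path) -> "FRAPTrace":
        """Read a long-format CSV with columns t, roi, value
        (roi in {bleach, whole, background})."""
        df = pd.read_csv(path)
        wide = df.pivot_table(index="t", columns="roi", values="value").reset_index()
        return cls(
            wide["t"].to_numpy(),
            wide["bleach"].to_numpy(),
            wide["whole"].to_numpy(),
            wide["background"].to_numpy(),
        )


def normalize_double(trace: FRAPTrace) -> TimeTrace:
    """Double normalization: background-corrected bleach/whole ratio,
    scaled to a pre-bleach mean of 1.

    Frames where the background-corrected whole-cell signal is <= 0 are
    rejected with a log entry; if no frames survive, raises ValueError.
    """
    denom = trace.whole - trace.background
    keep = denom > 0
    n_bad = int((~keep).sum())
    if n_bad:
        logger.info("rejected %d frames with non-positive whole-cell signal", n_bad)
    if not keep.any():
        raise ValueError("all frames rejected: whole-cell signal never exceeds background")
    t = trace.t[keep]
    ratio = (trace.bleach[keep] - trace.background[keep]) / denom[keep]
    pre = ratio[t < 0]
    if pre.size == 0 or pre.mean() == 0:
        raise ValueError("no usable pre-bleach frames for normalization")
    return TimeTrace(t, ratio / pre.mean(), roi="normalized")


@dataclass
class FrapRecoveryResults:
    """Fitted recovery parameters with covariance-based standard errors."""

    mobile_fraction: float
    t_half: float
    k: float
    I0_norm: float
    plateau_norm: float
    rmse: float
    se: dict[str, float]
    n_post: int
    clipped: bool = False
    immobile_flag: bool = False

    def summary(self) -> str:
        lines = [
            "FRAP single-exponential recovery fit",
            "=" * 44,
            f"{'post-bleach frames':<28}{self.n_post:>10d}",
            f"{'mobile fraction':<28}{self.mobile_fraction:>10.4f}  (se {self.se.get('mobile_fraction', float('nan')):.4f})",
            f"{'half-time t1/2 (s)':<28}{self.t_half:>10.4f}  (se {self.se.get('t_half', float('nan')):.4f})",
            f"{'rate k (1/s)':<28}{self.k:>10.4f}",
            f"{'bleach floor I0 (norm.)':<28}{self.I0_norm:>10.4f}",
            f"{'plateau (norm.)':<28}{self.plateau_norm:>10.4f}",
            f"{'residual RMSE':<28}{self.rmse:>10.5f}",
        ]
        if self.clipped:
            lines.append("note: mobile fraction clipped into [0, 1]")
        if self.immobile_flag:
            lines.append("note: plateau below bleach floor; flagged immobile")
        return "\n".join(lines)


class FrapRecoveryModel:
    """Single-exponential recovery model for a double-normalized FRAP trace.

    Parameters
    ----------
    trace : TimeTrace or FRAPTrace
        A normalized trace (from :func:`normalize_double`), or a raw
        three-ROI trace which will be normalized first.
    """

    def __init__(self, trace: TimeTrace | FRAPTrace):
        if isinstance(trace, FRAPTrace):
            trace = normalize_double(trace)
        self.trace = trace
        self.t_post = trace.t[trace.t >= 0]
        self.n_post = self.t_post[self.t_post >= 0].size
        if self.n_post < 10:
            raise ValueError("need >= 10 post-bleach frames")

    @staticmethod
    def _model(t, i0, f_inf, k):
        return i0 + (f_inf - i0) * (1.0 - np.exp(-k * t))

    def fit(self) -> FrapRecoveryResults:
        t = self.trace.t[self.trace.t >= 0]
        y = self.trace.value[self.trace.t >= 0]
        i0_guess = float(y[0])
        n_tail = max(1, y.size // 10)
        finf_guess = float(y[-n_tail:].mean())
        if abs(finf_guess - i0_guess) < 1e-12 and abs(i0_guess - 1.0) < 1e-6:
            raise FrapFitError("trace indistinguishable from 1 throughout: no bleach detected")
        # time to reach halfway between I0 and the plateau guess
        half_level = i0_guess + 0.5 * (finf_guess - i0_guess)
        above = np.nonzero(y >= half_level)[0] if finf_guess > i0_guess else np.array([])
        t_half_guess = t[above[0]] if above.size and t[above[0]] > 0 else (t[-1] / 4 or 1.0)
        k_guess = math.log(2) / t_half_guess
        p0 = (i0_guess, finf_guess, k_guess)
        try:
            popt, pcov = curve_fit(self._model, t, y, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            raise FrapFitError(f"recovery fit did not converge (p0={p0})") from exc
        i0, f_inf, k = popt
        if k <= 0:
            raise FrapFitError("fitted rate k <= 0")
        resid = y - self._model(t, *popt)
        rmse = float(np.sqrt(np.mean(resid**2)))
        immobile = f_inf < i0
        denom = 1.0 - i0
        mobile = (f_inf - i0) / denom if denom != 0 else np.nan
        clipped = False
        if np.isfinite(mobile) and not 0 <= mobile <= 1:
            mobile = float(np.clip(mobile, 0.0, 1.0))
            clipped = True
        if np.all(np.isfinite(pcov)) and denom != 0:
            perr = np.sqrt(np.diag(pcov))
            # delta method for derived quantities
            se_k = float(perr[2])
            se_thalf = se_k * math.log(2) / k**2
            dm_di0 = (f_inf - 1.0) / denom**2
            dm_dfinf = 1.0 / denom
            var_m = (
                dm_di0**2 * pcov[0, 0]
                + dm_dfinf**2 * pcov[1, 1]
                + 2 * dm_di0 * dm_dfinf * pcov[0, 1]
            )
            se_m = float(np.sqrt(var_m)) if var_m >= 0 else float("nan")
        else:
            se_k = se_thalf = se_m = float("nan")
        return FrapRecoveryResults(
            mobile_fraction=float(mobile),
            t_half=math.log(2) / k,
            k=float(k),
            I0_norm=float(i0),
            plateau_norm=float(f_inf),
            rmse=rmse,
            se={"mobile_fraction": se_m, "t_half": float(se_thalf), "k": float(se_k)},
            n_post=int(t.size),
            clipped=clipped,
            immobile_flag=bool(immobile),
        )


def fit_recovery(norm_trace: TimeTrace) -> FrapRecoveryResults:
    """Functional wrapper: fit the recovery model on a normalized trace."""
    return FrapRecoveryModel(norm_trace).fit()
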