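"""Statistical layer: granularity slope-contrast linear model with Dunnett
adjustment, three-parameter log-logistic dose-response with IC50/IC10,
ChromLogD, the 2^-ddCt fold change and the ovoid tumor volume formula.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from scipy.optimize import curve_fit

__all__ = [
    "GranularityModel",
    "GranularityResults",
    "granularity_model",
    "dunnett_adjust",
    "LogLogisticModel",
    "LogLogisticResults",
    "fit_log_logistic",
    "ChromLogDRecord",
    "chrom_logd",
    "fold_change_ddct",
    "ovoid_volume",
]


def dunnett_adjust(
    estimates: np.ndarray,
    cov: np.ndarray,
    df: float,
    seed: int = 20260927,
) -> np.ndarray:
    """Dunnett-style many-to-one adjusted p-values.

    Given contrast estimates with covariance ``cov`` and residual degrees
    of freedom ``df``, each two-sided p-value is the tail probability of
    the maximum modulus of a multivariate-t vector with the contrasts'
    correlation matrix: ``p_adj_i = P(max_j |T_j| >= |t_i|)``. The tail
    probability is evaluated by seeded quasi-Monte-Carlo integration
    (scrambled Sobol' points through the Gaussian copula, one chi-square
    scale draw per point), so results are reproducible and accurate to
    ~1e-4. A single contrast reduces exactly to the two-sided t-test;
    perfectly correlated contrasts reduce to the raw p-value.
    """
    est = np.atleast_1d(np.asarray(estimates, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    m = est.size
    if cov.shape != (m, m):
        raise ValueError("covariance shape must match number of contrasts")
    eig = np.linalg.eigvalsh((cov + cov.T) / 2)
    if eig.min() < -1e-8 * max(eig.max(), 1.0):
        raise ValueError("contrast covariance is not positive semi-definite")
    se = np.sqrt(np.diag(cov))
    if np.any(se == 0):
        raise ValueError("zero-variance contrast")
    t = est / se
    raw = 2 * sps.t.sf(np.abs(t), df)
    if m == 1:
        return raw
    corr = cov / np.outer(se, se)
    # factor the (possibly singular) correlation matrix
    w, U = np.linalg.eigh((corr + corr.T) / 2)
    L = U * np.sqrt(np.clip(w, 0.0, None))
    sampler = sps.qmc.Sobol(d=m + 1, scramble=True, rng=np.random.default_rng(seed))
    u = sampler.random(2**16)
    z = sps.norm.ppf(np.clip(u[:, :m], 1e-12, 1 - 1e-12))
    chi2 = sps.chi2.ppf(np.clip(u[:, m], 1e-12, 1 - 1e-12), df)
    tvec = (z @ L.T) / np.sqrt(chi2 / df)[:, None]
    max_mod = np.abs(tvec).max(axis=1)
    adj = np.array([np.mean(max_mod >= ti) for ti in np.abs(t)])
    # the adjusted p can never fall below the raw two-sided p
    return np.minimum(1.0, np.maximum(adj, raw))


@dataclass
class GranularityResults:
    """Slope contrasts of the granularity (s.d. vs mean-intensity) model.

    ``contrasts`` has one row per non-control group: the difference in
    s.d.-vs-mean slope relative to the control, its standard error, raw
    and Dunnett-adjusted p-values.
    """

    params: pd.Series
    contrasts: pd.DataFrame
    control: str
    df_resid: float
    model_summary: object

    def summary(self) -> str:
        lines = [
            "Granularity linear model (sd ~ mean * group + replicate)",
            f"control group: {self.control}   residual df: {self.df_resid:.0f}",
            "",
            self.contrasts.to_string(
                float_format=lambda v: f"{v:.5g}", index=False
            ),
        ]
        return "\n".join(lines)


class GranularityModel:
    """OLS model for nuclear granularity vs expression level across groups.

    Response: within-nucleus intensity s.d.; explanatory: mean intensity,
    group, group x mean-intensity interaction, and biological replicate
    (fixed effect). The per-group difference in the s.d.-vs-mean slope
    relative to the control is read off the interaction coefficients and
    tested with a Dunnett many-to-one adjustment.
    """

    def __init__(self, data, control_group: str, seed: int = 20260927):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(
                [
                    {
                        "intensity_sd": r.intensity_sd,
                        "mean_intensity": r.mean_intensity,
                        "group": r.group,
                        "replicate": r.replicate,
                    }
                    for r in data
                ]
            )
        required = {"intensity_sd", "mean_intensity", "group"}
        if not required.issubset(data.columns):
            raise ValueError(f"data must have columns {sorted(required)}")
        groups = data["group"].unique()
        if control_group not in groups:
            raise ValueError(f"control group {control_group!r} not present")
        if len(groups) < 2:
            raise ValueError("need >= 2 groups including the control")
        counts = data.groupby("group").size()
        if (counts < 3).any():
            raise ValueError("need >= 3 nuclei per group")
        self.data = data.copy()
        self.control = control_group
        self.seed = seed

    @classmethod
    def from_records(cls, records, control_group: str, **kw) -> "GranularityModel":
        return cls(records, control_group, **kw)

    def fit(self) -> GranularityResults:
        df = self.data
        rep_term = ""
        if "replicate" in df.columns and df["replicate"].nunique() > 1:
            rep_term = " + C(replicate)"
        elif "replicate" in df.columns:
            warnings.warn(
                "single replicate level: replicate term dropped (rank-deficient)",
                stacklevel=2,
            )
        formula = (
            "intensity_sd ~ mean_intensity "
            f"+ C(group, Treatment('{self.control}')) "
            f"+ C(group, Treatment('{self.control}')):mean_intensity{rep_term}"
        )
        fit = smf.ols(formula, data=df).fit()
        inter_names = [
            n
            for n in fit.params.index
            if ":mean_intensity" in n and "Treatment" in n
        ]
        groups = [n.split("[T.")[1].split("]")[0] for n in inter_names]
        est = fit.params[inter_names].to_numpy()
        cov = fit.cov_params().loc[inter_names, inter_names].to_numpy()
        se = np.sqrt(np.diag(cov))
        tvals = est / se
        raw_p = 2 * sps.t.sf(np.abs(tvals), fit.df_resid)
        adj_p = dunnett_adjust(est, cov, fit.df_resid, seed=self.seed)
        contrasts = pd.DataFrame(
            {
                "group": groups,
                "slope_diff": est,
                "se": se,
                "t": tvals,
                "p_raw": raw_p,
                "p_adjusted": np.maximum(adj_p, raw_p),
            }
        )
        return GranularityResults(
            params=fit.params,
            contrasts=contrasts,
            control=self.control,
            df_resid=float(fit.df_resid),
            model_summary=fit.summary,
        )


def granularity_model(records, control_group: str, seed: int = 20260927) -> GranularityResults:
    """Functional wrapper around :class:`GranularityModel`."""
    return GranularityModel(records, control_group, seed=seed).fit()


def _ll3(x, b, d, e):
    """Three-parameter log-logistic with lower limit 0; f(0) = d for b > 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x > 0
    out[pos] = d / (1.0 + np.exp(b * (np.log(x[pos]) - math.log(e))))
    out[~pos] = d if b > 0 else 0.0
    return out


@dataclass
class LogLogisticResults:
    """Fitted three-parameter log-logistic dose-response."""

    b: float
    d: float
    e: float
    cov: np.ndarray
    rmse: float
    n: int

    @property
    def ic50(self) -> float:
        return self.e

    @property
    def ic10(self) -> float:
        """Dose producing 10% inhibition (response = 0.9 d): e * 9^(-1/b)."""
        return self.e * 9.0 ** (-1.0 / self.b)

    def ed(self, fraction: float) -> float:
        """Dose producing the given inhibition fraction (0 < fraction < 1)."""
        if not 0 < fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        return self.e * (fraction / (1 - fraction)) ** (1.0 / self.b)

    def predict(self, x) -> np.ndarray:
        return _ll3(np.asarray(x, dtype=float), self.b, self.d, self.e)

    def summary(self) -> str:
        se = np.sqrt(np.diag(self.cov))
        return "\n".join(
            [
                "Three-parameter log-logistic fit (lower limit 0)",
                "=" * 48,
                f"{'hill slope b':<20}{self.b:>12.4f}  (se {se[0]:.4f})",
                f"{'upper limit d':<20}{self.d:>12.4f}  (se {se[1]:.4f})",
                f"{'IC50 e':<20}{self.e:>12.4f}  (se {se[2]:.4f})",
                f"{'IC10':<20}{self.ic10:>12.4f}",
                f"{'residual RMSE':<20}{self.rmse:>12.4f}   n = {self.n}",
            ]
        )


class LogLogisticModel:
    """Three-parameter log-logistic dose-response model, lower limit 0.

    ``f(x) = d / (1 + exp(b (ln x - ln e)))``; ``e`` is the IC50 and
    ``IC10 = e * 9^(-1/b)``. Zero-dose controls are kept in the fit as
    x -> 0 limit observations of the upper asymptote ``d``.
    """

    def __init__(self, dose, response):
        self.dose = np.asarray(dose, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.dose.shape != self.response.shape:
            raise ValueError("dose and response must have the same length")
        if np.unique(self.dose[self.dose > 0]).size < 4:
            raise ValueError("need >= 4 distinct positive doses")
        if np.ptp(self.response) == 0:
            raise ValueError("responses do not vary with dose: model not identifiable")

    @classmethod
    def from_curve(cls, curve) -> "LogLogisticModel":
        return cls(curve.x, curve.y)

    def fit(self) -> LogLogisticResults:
        x, y = self.dose, self.response
        d0 = float(np.percentile(y, 95))
        if d0 <= 0:
            d0 = float(max(y.max(), 1e-6))
        pos = x > 0
        # initial IC50: dose whose mean response is nearest to d0/2
        half = d0 / 2
        xs = np.unique(x[pos])
        means = np.array([y[x == xi].mean() for xi in xs])
        e0 = float(xs[np.argmin(np.abs(means - half))])
        p0 = (1.0, d0, e0)
        try:
            popt, pcov = curve_fit(
                _ll3, x, y, p0=p0,
                bounds=([1e-6, 1e-9, 1e-12], [50.0, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise RuntimeError(f"log-logistic fit did not converge (p0={p0})") from exc
        resid = y - _ll3(x, *popt)
        return LogLogisticResults(
            b=float(popt[0]),
            d=float(popt[1]),
            e=float(popt[2]),
            cov=np.asarray(pcov),
            rmse=float(np.sqrt(np.mean(resid**2))),
            n=int(x.size),
        )


def fit_log_logistic(doses, responses) -> LogLogisticResults:
    """Functional wrapper around :class:`LogLogisticModel`."""
    return LogLogisticModel(doses, responses).fit()


@dataclass
class ChromLogDRecord:
    """Chromatographic lipophilicity: ChromLogD = 0.0857 * CHI - 2."""

    CHI: float
    ChromLogD: float


def chrom_logd(CHI: float) -> ChromLogDRecord:
    """ChromLogD from the chromatographic hydrophobicity index (pH 7.4)."""
    chi = float(CHI)
    if not math.isfinite(chi):
        raise ValueError("CHI must be finite")
    return ChromLogDRecord(CHI=chi, ChromLogD=0.0857 * chi - 2.0)


def fold_change_ddct(
    ct_target_tx: float,
    ct_ref_tx: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) within each condition; the fold change
    of treatment over control is 2^-(dCt_tx - dCt_ctrl).
    """
    for v in (ct_target_tx, ct_ref_tx, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_tx - ct_ref_tx) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def ovoid_volume(length: float, width: float, height: float) -> float:
    """Ovoid tumor volume (mm^3) from caliper axes: L * W * H * 0.5236."""
    if length <= 0 or width <= 0 or height <= 0:
        raise ValueError("all axes must be positive")
    return float(length * width * height * 0.5236)
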