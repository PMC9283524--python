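"""Biochemical and cellular assay models.

One-phase exponential association fits (nucleotide-exchange fluorescence
traces; complex stability read out as the half-life t1/2 = ln2/k) and
three-parameter log(agonist)-vs-response fits with unit Hill slope
(cAMP dose-response; efficacy ratios and ECq).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AssociationTrace",
    "AssociationFit",
    "DoseResponseCurve",
    "DoseResponseFit",
    "fit_association",
    "fit_dose_response",
    "efficacy_and_potency",
    "ec_quantile",
    "summarize_time_course",
    "two_sample_ttest",
]

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class AssociationTrace:
    """A fluorescence (RFU) time course sampled from t = 0."""

    time: np.ndarray      # seconds
    rfu: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.rfu = np.asarray(self.rfu, float)
        if self.time.size != self.rfu.size:
            raise ValueError("time and rfu must have equal length")
        if self.time.size and self.time[0] != 0.0:
            raise ValueError("trace must start at t = 0")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "rfu": self.rfu})

    @classmethod
    def from_csv(cls, path, label: str = "") -> "AssociationTrace":
        df = pd.read_csv(path)
        return cls(time=df["time_s"].to_numpy(), rfu=df["rfu"].to_numpy(),
                   label=label)


@dataclass
class DoseResponseCurve:
    """Replicated responses at a set of ligand concentrations (molar)."""

    concentration: np.ndarray
    replicate: np.ndarray
    response: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, float)
        self.replicate = np.asarray(self.replicate, int)
        self.response = np.asarray(self.response, float)
        if not (self.concentration.size == self.replicate.size == self.response.size):
            raise ValueError("columns must have equal length")
        if self.concentration.size == 0:
            raise ValueError("empty dose-response data")
        if np.any(self.concentration <= 0):
            raise ValueError("concentrations must be positive")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"conc_M": self.concentration,
                             "replicate": self.replicate,
                             "response": self.response})

    @classmethod
    def from_csv(cls, path, label: str = "") -> "DoseResponseCurve":
        df = pd.read_csv(path)
        return cls(concentration=df["conc_M"].to_numpy(),
                   replicate=df["replicate"].to_numpy(),
                   response=df["response"].to_numpy(), label=label)


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------

@dataclass
class AssociationFit:
    f0: float
    plateau: float
    rate_constant_k: float
    residual_sd: float
    converged: bool
    message: str = ""
    ci: dict = field(default_factory=dict)

    @property
    def half_life(self) -> float:
        """t1/2 = ln2/k, exact by construction."""
        return LN2 / self.rate_constant_k

    def to_dict(self) -> dict:
        return {"f0": self.f0, "plateau": self.plateau,
                "rate_constant_k": self.rate_constant_k,
                "half_life": self.half_life,
                "residual_sd": self.residual_sd,
                "converged": self.converged, "message": self.message,
                "ci": self.ci}


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    log_ec50: float
    residual_sd: float
    converged: bool
    hill: float = 1.0
    message: str = ""
    ci: dict = field(default_factory=dict)

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50

    def predict(self, conc) -> np.ndarray:
        logc = np.log10(np.asarray(conc, float))
        return self.bottom + (self.top - self.bottom) / (
            1.0 + 10.0 ** (self.hill * (self.log_ec50 - logc)))

    def to_dict(self) -> dict:
        return {"bottom": self.bottom, "top": self.top,
                "log_ec50": self.log_ec50, "ec50": self.ec50,
                "hill": self.hill, "residual_sd": self.residual_sd,
                "converged": self.converged, "message": self.message,
                "ci": self.ci}


def _asymptotic_ci(popt, pcov, names, level: float = 0.95) -> dict:
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = {}
    for i, name in enumerate(names):
        se = math.sqrt(max(pcov[i, i], 0.0)) if np.all(np.isfinite(pcov)) else math.nan
        out[name] = [popt[i] - z * se, popt[i] + z * se]
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _association_model(t, f0, plateau, k):
    return f0 + (plateau - f0) * (1.0 - np.exp(-k * t))


def fit_association(trace: AssociationTrace) -> AssociationFit:
    """Least-squares one-phase exponential association fit.

    F(t) = f0 + (plateau - f0) (1 - e^{-kt}); initial guesses come from the
    data (f0 = first point, plateau = last point, k from the one-third-rise
    time). Non-convergence and monotonically decreasing traces are flagged,
    never silently defaulted.
    """
    t, y = trace.time, trace.rfu
    if t.size < 4:
        raise ValueError("need at least 4 points to fit an association curve")
    if np.all(np.diff(y) <= 0) and y[-1] < y[0]:
        return AssociationFit(f0=float(y[0]), plateau=float(y[-1]),
                              rate_constant_k=math.nan, residual_sd=math.nan,
                              converged=False, message="non-association: "
                              "monotonically decreasing trace")
    f0_guess = float(y[0])
    plateau_guess = float(y[-1])
    third = f0_guess + (plateau_guess - f0_guess) / 3.0
    above = np.nonzero(y >= third)[0]
    t13 = t[above[0]] if above.size and t[above[0]] > 0 else t[-1] / 3.0
    k_guess = math.log(1.5) / t13 if t13 > 0 else 1.0 / t[-1]
    try:
        popt, pcov = optimize.curve_fit(
            _association_model, t, y,
            p0=[f0_guess, plateau_guess, k_guess],
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except RuntimeError as exc:
        return AssociationFit(f0=f0_guess, plateau=plateau_guess,
                              rate_constant_k=math.nan, residual_sd=math.nan,
                              converged=False, message=f"no convergence: {exc}")
    resid = y - _association_model(t, *popt)
    dof = max(t.size - 3, 1)
    fit = AssociationFit(
        f0=float(popt[0]), plateau=float(popt[1]),
        rate_constant_k=float(popt[2]),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        converged=bool(popt[1] > popt[0] and popt[2] > 0),
        ci=_asymptotic_ci(popt, pcov, ["f0", "plateau", "rate_constant_k"]))
    if not fit.converged:
        fit.message = "fit converged to a non-association shape"
    return fit


def _logistic_model(logc, bottom, top, log_ec50):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (log_ec50 - logc))


def fit_dose_response(curve: DoseResponseCurve,
                      variable_slope: bool = False) -> DoseResponseFit:
    """Three-parameter log(agonist)-vs-response fit with unit Hill slope.

    Replicate points are weighted equally. ``variable_slope=True`` frees the
    Hill coefficient (off by default).
    """
    logc = np.log10(curve.concentration)
    y = curve.response
    if np.unique(curve.concentration).size < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if np.allclose(y, y[0]):
        return DoseResponseFit(bottom=float(y[0]), top=float(y[0]),
                               log_ec50=math.nan, residual_sd=0.0,
                               converged=False,
                               message="unidentifiable: all responses equal")
    b0, t0 = float(y.min()), float(y.max())
    lec0 = float(np.median(logc))
    if variable_slope:
        def model(lc, bottom, top, lec, hill):
            return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (lec - lc)))
        p0, names = [b0, t0, lec0, 1.0], ["bottom", "top", "log_ec50", "hill"]
    else:
        model, p0, names = _logistic_model, [b0, t0, lec0], ["bottom", "top", "log_ec50"]
    try:
        popt, pcov = optimize.curve_fit(model, logc, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        return DoseResponseFit(bottom=b0, top=t0, log_ec50=math.nan,
                               residual_sd=math.nan, converged=False,
                               message=f"no convergence: {exc}")
    resid = y - model(logc, *popt)
    dof = max(y.size - len(popt), 1)
    hill = float(popt[3]) if variable_slope else 1.0
    return DoseResponseFit(
        bottom=float(popt[0]), top=float(popt[1]), log_ec50=float(popt[2]),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        converged=True, hill=hill,
        ci=_asymptotic_ci(popt, pcov, names))


def efficacy_and_potency(fit: DoseResponseFit,
                         reference: DoseResponseFit) -> dict:
    """Efficacy ratio (fit top / reference top) and EC50 fold shift."""
    if not (fit.converged and reference.converged):
        raise ValueError("both fits must have converged")
    if reference.top <= 0:
        raise ValueError("reference top must be positive")
    return {
        "efficacy_ratio": fit.top / reference.top,
        "ec50": fit.ec50,
        "fold_ec50_shift": fit.ec50 / reference.ec50,
    }


def ec_quantile(fit: DoseResponseFit, q: float) -> float:
    """ECq for a unit-Hill logistic: ECq = EC50 * q / (100 - q)."""
    if not (0.0 < q < 100.0):
        raise ValueError("q must lie strictly between 0 and 100")
    return fit.ec50 * q / (100.0 - q)


# ---------------------------------------------------------------------------
# Descriptive utilities for report tables
# ---------------------------------------------------------------------------

def summarize_time_course(time: np.ndarray, value: np.ndarray,
                          tail_fraction: float = 0.2) -> dict:
    """Descriptive phase summary of a signaling time course: peak value,
    time-to-peak and terminal slope (least-squares over the final fraction
    of points)."""
    time = np.asarray(time, float)
    value = np.asarray(value, float)
    i_peak = int(np.argmax(value))
    n_tail = max(int(round(tail_fraction * time.size)), 2)
    tt, vv = time[-n_tail:], value[-n_tail:]
    slope = float(np.polyfit(tt, vv, 1)[0])
    return {"peak": float(value[i_peak]), "time_to_peak": float(time[i_peak]),
            "terminal_slope": slope}


def two_sample_ttest(a, b, equal_var: bool = False) -> dict:
    """Two-sample t test for summary tables."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                          equal_var=equal_var)
    return {"t": float(res.statistic), "p": float(res.pvalue)}


def write_fit_report(path, fits: dict) -> None:
    """JSON report of named fit objects."""
    payload = {name: fit.to_dict() for name, fit in fits.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
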