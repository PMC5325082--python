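"""Concentration-response analysis for oocyte electrophysiology.

Peak currents are normalized per oocyte to that oocyte's maximal agonist
response, then fitted with the Hill equation

    I / Imax = A^nH / (A^nH + EC50^nH)

where A is the agonist concentration (molar), EC50 the concentration giving
the half-maximal response and nH the Hill coefficient.  Also provided:
calcium-modulation profiles (per-oocyte normalization to the response at
1.8 mM Ca2+), EC50 fold-shift reporting, and specific-binding arithmetic
for radioligand assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "HillFit",
    "SpecificBinding",
    "hill_curve",
    "normalize_per_oocyte",
    "fit_hill",
    "ca_modulation_profile",
    "ec50_fold_change",
    "format_fold",
    "specific_binding",
    "triplicate_summary",
]


@dataclass
class HillFit:
    """Hill-equation fit result (concentrations in molar)."""

    ec50: float
    nh: float
    imax: float
    se_ec50: float
    se_nh: float
    se_imax: float
    converged: bool
    sse: float
    n_points: int

    def predict(self, conc) -> np.ndarray:
        return hill_curve(np.asarray(conc, float), self.ec50, self.nh, self.imax)


def hill_curve(conc, ec50: float, nh: float, imax: float = 1.0):
    """The Hill concentration-response curve Imax*A^nH/(A^nH + EC50^nH)."""
    conc = np.asarray(conc, float)
    # evaluate via the log-ratio for numerical stability at extreme A/EC50
    ratio = np.exp(nh * (np.log(conc) - np.log(ec50)))
    return imax * ratio / (1.0 + ratio)


def normalize_per_oocyte(data: pd.DataFrame, response_col: str = "current",
                         oocyte_col: str = "oocyte_id") -> pd.DataFrame:
    """Divide each oocyte's responses by that oocyte's maximum response.

    Returns a copy with a ``normalized`` column; oocytes whose maximum is
    not positive are excluded with a warning.  Idempotent on
    already-normalized data.
    """
    df = data.copy()
    maxima = df.groupby(oocyte_col)[response_col].transform("max")
    dead = df.loc[maxima <= 0, oocyte_col].unique()
    if len(dead):
        warnings.warn(f"excluding oocytes with non-positive maximum response: "
                      f"{sorted(map(str, dead))}")
        df = df[~df[oocyte_col].isin(dead)].copy()
        maxima = maxima[~data[oocyte_col].isin(dead)]
    df["normalized"] = df[response_col] / maxima
    return df


def fit_hill(data: pd.DataFrame, conc_col: str = "concentration",
             response_col: str = "normalized", oocyte_col: str = "oocyte_id",
             mode: str = "pooled",
             imax_bounds: tuple[float, float] = (0.8, 1.2)) -> HillFit:
    """Nonlinear least-squares fit of the Hill equation to normalized data.

    ``mode="pooled"`` (default) fits all normalized points together;
    ``mode="per_oocyte"`` fits each oocyte separately and averages the
    parameters.  The fit is parametrised internally in log10(EC50) for
    conditioning; start values are EC50 = geometric mean of the tested
    concentrations, nH = 1, Imax = 1, with bounds EC50 within
    [min A / 10, max A * 10], nH within [0.1, 10] and Imax within
    ``imax_bounds`` (Imax is left free because per-oocyte normalization
    uses the observed maximum, which sits below the true asymptote).
    Non-convergence yields a flagged result, not an exception; flat
    (zero-spread) responses raise.
    """
    if mode == "per_oocyte":
        fits = [fit_hill(grp, conc_col, response_col, oocyte_col, mode="pooled",
                         imax_bounds=imax_bounds)
                for _, grp in data.groupby(oocyte_col)]
        ec50s = np.array([f.ec50 for f in fits])
        nhs = np.array([f.nh for f in fits])
        imaxs = np.array([f.imax for f in fits])
        n = len(fits)
        sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        return HillFit(float(np.exp(np.mean(np.log(ec50s)))), float(nhs.mean()),
                       float(imaxs.mean()), sem(ec50s), sem(nhs), sem(imaxs),
                       converged=all(f.converged for f in fits),
                       sse=float(sum(f.sse for f in fits)),
                       n_points=sum(f.n_points for f in fits))
    if mode != "pooled":
        raise ValueError("mode must be 'pooled' or 'per_oocyte'")

    conc = np.asarray(data[conc_col], float)
    resp = np.asarray(data[response_col], float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations to fit")
    if float(np.ptp(resp)) < 1e-12:
        raise ValueError("degenerate (flat) response data")

    log_ec50_0 = float(np.mean(np.log10(conc)))
    lo = [np.log10(conc.min() / 10.0), 0.1, imax_bounds[0]]
    hi = [np.log10(conc.max() * 10.0), 10.0, imax_bounds[1]]
    p0 = [np.clip(log_ec50_0, lo[0], hi[0]), 1.0, np.clip(1.0, *imax_bounds)]

    def model(a, log_ec50, nh, imax):
        return hill_curve(a, 10.0 ** log_ec50, nh, imax)

    try:
        popt, pcov = curve_fit(model, conc, resp, p0=p0, bounds=(lo, hi),
                               maxfev=20000, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        converged = np.all(np.isfinite(popt))
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((3, 3), np.nan)
        converged = False
    ec50 = float(10.0 ** popt[0])
    nh, imax = float(popt[1]), float(popt[2])
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    se_ec50 = float(ec50 * np.log(10.0) * perr[0])  # delta method from log10 space
    sse = float(np.sum((resp - model(conc, *popt)) ** 2))
    return HillFit(ec50, nh, imax, se_ec50, float(perr[1]), float(perr[2]),
                   bool(converged), sse, len(resp))


def ca_modulation_profile(data: pd.DataFrame, ca_col: str = "ca_mm",
                          amplitude_col: str = "amplitude",
                          oocyte_col: str = "oocyte_id",
                          reference_ca: float = 1.8) -> pd.DataFrame:
    """Calcium-modulation profile: normalize to 1.8 mM per oocyte, then average.

    Each oocyte's amplitudes are divided by its own amplitude at the
    reference Ca2+ level (1.8 mM), so the reference level is exactly 1 per
    oocyte; values are then averaged across oocytes (mean ± SEM per level).
    Oocytes lacking the reference measurement are excluded with a warning.
    """
    frames = []
    for oid, grp in data.groupby(oocyte_col):
        ref_rows = grp.loc[np.isclose(grp[ca_col].astype(float), reference_ca)]
        if ref_rows.empty:
            warnings.warn(f"oocyte {oid}: no {reference_ca} mM reference; excluded")
            continue
        ref = float(ref_rows[amplitude_col].mean())
        if ref == 0:
            warnings.warn(f"oocyte {oid}: zero reference amplitude; excluded")
            continue
        g = grp.copy()
        g["normalized"] = g[amplitude_col] / ref
        frames.append(g)
    if not frames:
        raise ValueError("no oocyte has the reference Ca2+ measurement")
    norm = pd.concat(frames)
    out = (norm.groupby(ca_col)["normalized"]
           .agg(mean="mean", sem=lambda x: x.sem() if len(x) > 1 else 0.0,
                n="count").reset_index())
    return out


def _ec50_of(x) -> float:
    return float(x.ec50) if hasattr(x, "ec50") else float(x)


def ec50_fold_change(mutant, wildtype) -> float:
    """Fold-shift of a mutant's EC50 relative to wild type (EC50_mut/EC50_wt)."""
    m, w = _ec50_of(mutant), _ec50_of(wildtype)
    if m <= 0 or w <= 0:
        raise ValueError("EC50 values must be positive")
    return m / w


def format_fold(fold: float) -> str:
    """Reporting helper: '42.67' -> '43-fold'."""
    return f"{round(fold):d}-fold"


@dataclass(frozen=True)
class SpecificBinding:
    """Specific binding = total - nonspecific (fmol/mg)."""

    value: float
    raw: float
    clipped: bool


def specific_binding(total: float, nonspecific: float) -> SpecificBinding:
    """Specific radioligand binding; negative differences are clipped to 0
    and flagged rather than silently reported."""
    raw = float(total) - float(nonspecific)
    if raw < 0:
        return SpecificBinding(0.0, raw, True)
    return SpecificBinding(raw, raw, False)


def triplicate_summary(data: pd.DataFrame, group_cols, value_col: str) -> pd.DataFrame:
    """Mean ± SEM over replicate measurements (e.g. assay triplicates)."""
    return (data.groupby(group_cols)[value_col]
            .agg(mean="mean", sem=lambda x: x.sem() if len(x) > 1 else 0.0,
                 n="count").reset_index())
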