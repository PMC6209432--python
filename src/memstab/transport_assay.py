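"""Radioactive substrate-uptake analysis: normalization, initial rates, Km/Vmax.

Scintillation counts from proteoliposome (or cell-based) uptake assays are
background-subtracted (protein-free liposomes / empty-vector cells),
converted to pmol of substrate through the specific activity of the tracer
mix — which varies across titration points because the hot:cold dilution
does — and normalized to the amount of reconstituted protein estimated by
GFP fluorescence.  Initial rates come from an origin-constrained linear
fit to the 120 s and 180 s uptake points, reported per minute; the
concentration dependence of the rates is fitted with the Michaelis-Menten
law v = Vmax*c/(Km + c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "MMFit",
    "michaelis_menten",
    "normalize_uptake",
    "initial_rate",
    "fit_michaelis_menten",
]


def michaelis_menten(c, vmax: float, km: float):
    c = np.asarray(c, dtype=float)
    return vmax * c / (km + c)


@dataclass
class MMFit:
    km_uM: float
    vmax: float
    se_km: float
    se_vmax: float
    rss: float
    n: int

    def predict(self, c):
        return michaelis_menten(c, self.vmax, self.km_uM)


def normalize_uptake(
    counts: np.ndarray | float,
    background: np.ndarray | float,
    specific_activity_cpm_per_pmol: np.ndarray | float,
    protein_ug: np.ndarray | float,
) -> np.ndarray:
    """Background-subtracted uptake in pmol per ug protein.

    (counts - background) / specific_activity / protein.  Background above
    signal clamps to zero with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    background = np.asarray(background, dtype=float)
    if np.any(counts < 0) or np.any(background < 0):
        raise ValueError("counts must be non-negative")
    net = counts - background
    if np.any(net < 0):
        warnings.warn(
            "background exceeds signal for some measurements; clamping to 0",
            UserWarning,
            stacklevel=2,
        )
        net = np.clip(net, 0.0, None)
    return net / np.asarray(specific_activity_cpm_per_pmol, dtype=float) / np.asarray(
        protein_ug, dtype=float
    )


def initial_rate(times_s, uptake) -> float:
    """Origin-constrained initial transport rate, per minute.

    Least-squares slope through the origin, b = sum(t*y)/sum(t^2) (per
    second), scaled by 60.  Designed for the two-point 120 s / 180 s
    protocol but accepts any number of points.  A negative slope is
    allowed but flagged with a warning.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(uptake, dtype=float)
    if t.shape != y.shape or t.size < 1:
        raise ValueError("times and uptake must be matching non-empty arrays")
    slope = float(np.sum(t * y) / np.sum(t * t))
    if slope < 0:
        warnings.warn("negative initial transport rate", UserWarning, stacklevel=2)
    return slope * 60.0


def fit_michaelis_menten(concentrations_uM, rates, sem=None) -> MMFit:
    """Nonlinear least-squares Michaelis-Menten fit (Km > 0 enforced).

    Requires at least three distinct concentrations, one of them on the
    Km scale or above (the largest concentration must exceed the smallest
    positive one by an order of magnitude is *not* required — only that a
    saturating-side point exists per the fitted Km is checked post hoc).
    """
    c = np.asarray(concentrations_uM, dtype=float)
    v = np.asarray(rates, dtype=float)
    if c.shape != v.shape:
        raise ValueError("concentrations and rates must match")
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if not np.any(v != 0):
        raise ValueError("all rates are zero; nothing to fit")
    vmax0 = float(v.max())
    pos = c[c > 0]
    km0 = float(np.interp(vmax0 / 2.0, np.sort(v), np.sort(c))) if vmax0 > 0 else pos.mean()
    km0 = max(km0, pos.min() / 10.0)
    popt, pcov = curve_fit(
        michaelis_menten,
        c,
        v,
        p0=(vmax0, km0),
        sigma=np.asarray(sem, dtype=float) if sem is not None else None,
        bounds=([0.0, 1e-9], [np.inf, np.inf]),
        maxfev=20000,
    )
    resid = v - michaelis_menten(c, *popt)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return MMFit(
        km_uM=float(popt[1]),
        vmax=float(popt[0]),
        se_km=float(se[1]),
        se_vmax=float(se[0]),
        rss=float(resid @ resid),
        n=int(c.size),
    )


def rates_from_counts(
    table: pd.DataFrame,
    specific_activity: dict[float, float],
    protein_ug: float = 1.0,
) -> pd.DataFrame:
    """Counts table -> per-concentration initial rates (pmol ug^-1 min^-1).

    ``table`` columns: conc_uM, time_s, counts, background; ``specific_activity``
    maps concentration to cpm/pmol of the tracer mix at that titration point.
    """
    required = {"conc_uM", "time_s", "counts", "background"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    rows = []
    for conc, grp in table.groupby("conc_uM", sort=True):
        sa = specific_activity.get(float(conc))
        if sa is None:
            raise ValueError(f"no specific activity configured for {conc} uM")
        pmol = normalize_uptake(
            grp["counts"].to_numpy(), grp["background"].to_numpy(), sa, protein_ug
        )
        rows.append({"conc_uM": float(conc), "rate": initial_rate(grp["time_s"].to_numpy(), pmol)})
    return pd.DataFrame(rows)
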