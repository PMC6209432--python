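"""Hill-law melting analysis and SEC chromatogram processing.

Thermal denaturation of detergent-solubilized transporters is monitored
through some folded-population proxy measured after a temperature pre-pulse:
the trimer area fraction of a size-exclusion chromatogram, the slow
component of deuterium-uptake kinetics, or the low-m/z fraction of a
bimodal isotopic envelope.  All three are fitted with the same empirical
Hill-like melting law

    f(T) = 1 / (1 + (T50 / T)**H)

with the pre-pulse temperature T in degrees Celsius (the fitted parameter
magnitudes only make sense on the Celsius scale) and H typically negative,
so that f -> 1 for T << T50 and f -> 0 for T >> T50.  T50 is the midpoint:
f(T50) = 0.5 exactly, for any H.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Chromatogram",
    "HillFit",
    "hill_model",
    "fit_hill",
    "trimer_fraction",
    "melt_series_from_chromatograms",
    "HILL_FLAVORS",
]

# Per-flavor lower bound on the Hill coefficient.  The HDX flavors are
# constrained to H > -20; the SEC flavor is unbounded below (SEC melts are
# steeper, with reported H around -21).
HILL_FLAVORS = {
    "T50_SEC": (-np.inf, 0.0),
    "T50_HDX_Uni": (-20.0, 0.0),
    "T50_HDX_Bi": (-20.0, 0.0),
}


@dataclass
class Chromatogram:
    """A size-exclusion elution profile (fluorescence vs. volume)."""

    volume_ml: np.ndarray
    signal: np.ndarray
    temperature_C: float | None = None
    construct: str = ""
    coarse_grid: bool = False  # set by generators when peaks are under-sampled

    def __post_init__(self) -> None:
        self.volume_ml = np.asarray(self.volume_ml, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.volume_ml.ndim != 1 or self.volume_ml.shape != self.signal.shape:
            raise ValueError("volume and signal must be matching 1-D arrays")
        if not np.all(np.diff(self.volume_ml) > 0):
            raise ValueError("volume grid must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    def total_area(self) -> float:
        return float(np.trapezoid(self.signal, self.volume_ml))


@dataclass
class HillFit:
    """Result of fitting f(T) = 1/(1 + (T50/T)^H)."""

    flavor: str
    t50: float
    h: float
    se_t50: float
    se_h: float
    rss: float
    n: int
    bound_hit: bool = False
    unbracketed: bool = False
    h_bounds: tuple[float, float] = field(default=(-np.inf, 0.0))

    def predict(self, temperature_C):
        return hill_model(np.asarray(temperature_C, dtype=float), self.t50, self.h)


def hill_model(temperature_C, t50: float, h: float):
    """Hill melting law; temperature in Celsius, H dimensionless."""
    T = np.asarray(temperature_C, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive (Celsius scale, T > 0)")
    return 1.0 / (1.0 + (t50 / T) ** h)


def fit_hill(
    temperatures_C,
    fractions,
    flavor: str = "T50_SEC",
    h_bounds: tuple[float, float] | None = None,
    sem=None,
) -> HillFit:
    """Least-squares fit of the Hill melting law to a fraction-vs-T series.

    Parameters
    ----------
    temperatures_C, fractions:
        Matched 1-D arrays.  At least four temperatures are required, and
        the series should bracket the transition (values on both sides of
        0.5); an unbracketed series is fitted anyway but flagged.
    flavor:
        One of ``T50_SEC``, ``T50_HDX_Uni``, ``T50_HDX_Bi``; selects the
        default Hill-coefficient bounds (HDX flavors: H > -20).
    h_bounds:
        Override for the (lower, upper) bounds on H.
    sem:
        Optional per-point standard errors used as fit weights.
    """
    T = np.asarray(temperatures_C, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if T.shape != y.shape or T.ndim != 1:
        raise ValueError("temperatures and fractions must be matching 1-D arrays")
    if T.size < 4:
        raise ValueError("need at least 4 temperatures to fit the melting law")
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive Celsius values")
    if np.ptp(y) == 0:
        raise ValueError("all fractions equal: no transition to fit")
    if flavor not in HILL_FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}; expected one of {sorted(HILL_FLAVORS)}")
    lo, hi = h_bounds if h_bounds is not None else HILL_FLAVORS[flavor]

    unbracketed = not (y.min() < 0.5 < y.max())
    if unbracketed:
        warnings.warn(
            "melting series does not bracket f = 0.5; T50 is an extrapolation",
            UserWarning,
            stacklevel=2,
        )

    # Neutral deterministic starts: midpoint of the grid, mid-steepness.
    t50_0 = float(0.5 * (T.min() + T.max()))
    h_0 = -10.0
    if not (lo < h_0 < hi):  # keep the start strictly interior
        h_0 = 0.5 * (max(lo, -100.0) + min(hi, 0.0))
    sigma = np.asarray(sem, dtype=float) if sem is not None else None

    popt, pcov = curve_fit(
        hill_model,
        T,
        y,
        p0=(t50_0, h_0),
        bounds=([1e-3, lo], [np.inf, hi]),
        sigma=sigma,
        maxfev=20000,
    )
    t50, h = (float(popt[0]), float(popt[1]))
    resid = y - hill_model(T, t50, h)
    rss = float(resid @ resid)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    bound_hit = bool(
        (np.isfinite(lo) and abs(h - lo) < 1e-8) or (np.isfinite(hi) and abs(h - hi) < 1e-8)
    )
    return HillFit(
        flavor=flavor,
        t50=t50,
        h=h,
        se_t50=float(se[0]),
        se_h=float(se[1]),
        rss=rss,
        n=int(T.size),
        bound_hit=bound_hit,
        unbracketed=unbracketed,
        h_bounds=(float(lo), float(hi)),
    )


def trimer_fraction(
    chromatogram: Chromatogram,
    trimer_window_ml: tuple[float, float] = (2.7, 3.25),
    reference_chromatogram: Chromatogram | None = None,
) -> dict:
    """Fraction of chromatogram area inside the trimer elution window.

    The fraction is area(window)/area(total) by trapezoidal integration.
    ``total_area_norm`` is the total area relative to the (typically 4 C)
    reference run — the constancy check against aggregation/loss.
    """
    lo, hi = trimer_window_ml
    v, s = chromatogram.volume_ml, chromatogram.signal
    if lo < v[0] or hi > v[-1]:
        raise ValueError("trimer window extends beyond the volume grid")
    total = chromatogram.total_area()
    if total == 0:
        raise ValueError("chromatogram has zero total area")
    mask = (v >= lo) & (v <= hi)
    window_area = float(np.trapezoid(s[mask], v[mask]))
    out = {"fraction": window_area / total, "total_area_norm": np.nan}
    if reference_chromatogram is not None:
        ref_total = reference_chromatogram.total_area()
        if ref_total == 0:
            raise ValueError("reference chromatogram has zero total area")
        out["total_area_norm"] = total / ref_total
    return out


def melt_series_from_chromatograms(
    chromatograms: dict[float, Chromatogram],
    trimer_window_ml: tuple[float, float] = (2.7, 3.25),
    reference_temperature_C: float = 4.0,
    normalize: bool = True,
) -> dict:
    """Reduce a pre-pulse temperature series of chromatograms to fractions.

    When ``normalize`` is set the trimer fractions are divided by the value
    at the reference temperature so the cold reference reads 1 before Hill
    fitting; if the reference run is absent, raw fractions are returned
    with a warning.
    """
    temps = np.array(sorted(chromatograms), dtype=float)
    ref = chromatograms.get(reference_temperature_C)
    if normalize and ref is None:
        warnings.warn(
            f"no reference chromatogram at {reference_temperature_C} degC; "
            "returning raw fractions",
            UserWarning,
            stacklevel=2,
        )
    rows = [trimer_fraction(chromatograms[t], trimer_window_ml, ref) for t in temps]
    frac = np.array([r["fraction"] for r in rows])
    area_norm = np.array([r["total_area_norm"] for r in rows])
    if normalize and ref is not None:
        ref_frac = trimer_fraction(ref, trimer_window_ml)["fraction"]
        if ref_frac == 0:
            raise ValueError("reference trimer fraction is zero; cannot normalize")
        frac = frac / ref_frac
    return {"temperature_C": temps, "fraction": frac, "total_area_norm": area_norm}
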