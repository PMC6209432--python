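"""Isotopic m/z envelope analysis: centroids, bimodality, deconvolution.

A peptide's isotopic envelope shifts to higher m/z as backbone amides pick
up deuterium.  Under EX1-like behavior two slowly interconverting
conformations produce a *bimodal* envelope: a low-m/z component from
natively folded (protected) transporters and a high-m/z component from
locally unfolded ones.  Double-Gaussian deconvolution of the envelope
yields the area fraction of the low-m/z component, whose temperature
dependence is a melting curve (T50-HDX-Bi when fitted with the Hill law).

Envelope fits are performed in m/z space on replicate-averaged profiles;
the charge state enters only when converting centroid shifts to Daltons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "Envelope",
    "GaussianMix",
    "centroid",
    "centroid_uptake",
    "average_envelopes",
    "fit_gaussian_mixture",
    "fit_double_gaussian",
    "detect_bimodality",
    "bimodal_melt_curve",
    "melt_series_from_envelopes",
    "read_envelopes",
]

SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass
class Envelope:
    """An m/z intensity profile for one peptide under one condition."""

    mz: np.ndarray
    intensity: np.ndarray
    peptide: object | None = None
    charge: int = 1
    temperature_C: float | None = None
    time_s: float | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be matching 1-D arrays")
        if not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")

    def total_area(self) -> float:
        return float(np.trapezoid(self.intensity, self.mz))


@dataclass
class GaussianMix:
    """One- or two-component Gaussian deconvolution of an envelope."""

    n_components: int
    centers: np.ndarray  # sorted ascending for n=2 (low then high m/z)
    sigmas: np.ndarray
    areas: np.ndarray
    rss: float
    aic: float
    aic_single: float | None = None
    degenerate: bool = False
    converged: bool = True
    thresholds: dict = field(default_factory=dict)

    @property
    def fractions(self) -> np.ndarray:
        total = self.areas.sum()
        if total == 0:
            return np.full_like(self.areas, np.nan)
        return self.areas / total

    @property
    def low_fraction(self) -> float:
        """Area fraction of the low-m/z (folded-population proxy) component."""
        return float(self.fractions[0])

    def predict(self, mz):
        mz = np.asarray(mz, dtype=float)
        out = np.zeros_like(mz)
        for c, s, a in zip(self.centers, self.sigmas, self.areas):
            out += a / (s * SQRT_2PI) * np.exp(-0.5 * ((mz - c) / s) ** 2)
        return out

    @property
    def centroid(self) -> float:
        return float(np.sum(self.fractions * self.centers))


def centroid(envelope: Envelope) -> float:
    """Intensity-weighted mean m/z (trapezoid weights, so non-uniform grids work)."""
    total = envelope.total_area()
    if total == 0:
        raise ValueError("zero total intensity; centroid undefined")
    return float(np.trapezoid(envelope.mz * envelope.intensity, envelope.mz) / total)


def centroid_uptake(deuterated: Envelope, undeuterated: Envelope) -> float:
    """Deuterium uptake in Da from the centroid shift of unimodal envelopes.

    uptake = (centroid_D - centroid_U) * charge
    """
    if deuterated.charge != undeuterated.charge:
        raise ValueError("charge states differ between deuterated and undeuterated envelopes")
    return (centroid(deuterated) - centroid(undeuterated)) * deuterated.charge


def average_envelopes(replicates: list[Envelope]) -> Envelope:
    """Pointwise mean intensity of replicate envelopes on their common grid."""
    if not replicates:
        raise ValueError("no replicates to average")
    grid = replicates[0].mz
    for env in replicates[1:]:
        if env.mz.shape != grid.shape or not np.allclose(env.mz, grid):
            raise ValueError("replicate envelopes must share one m/z grid")
    mean = np.mean([e.intensity for e in replicates], axis=0)
    first = replicates[0]
    return Envelope(
        mz=grid,
        intensity=mean,
        peptide=first.peptide,
        charge=first.charge,
        temperature_C=first.temperature_C,
        time_s=first.time_s,
        replicate=0,
    )


def _gauss_sum(mz, *theta):
    out = np.zeros_like(mz)
    for i in range(0, len(theta), 3):
        a, c, s = theta[i : i + 3]
        out += a * np.exp(-0.5 * ((mz - c) / s) ** 2)
    return out


def _initial_guess(env: Envelope, n: int, init_centers=None):
    mz, inten = env.mz, env.intensity
    span = mz[-1] - mz[0]
    # sigma guess from the FWHM of the dominant peak
    imax = int(np.argmax(inten))
    half = inten[imax] / 2.0
    above = np.nonzero(inten >= half)[0]
    fwhm = mz[above[-1]] - mz[above[0]] if above.size > 1 else span / 10.0
    sigma0 = max(fwhm / 2.3548, 2.0 * np.median(np.diff(mz)))
    if init_centers is None:
        peaks, _ = find_peaks(inten, height=inten.max() * 0.02)
        if peaks.size >= n:
            order = np.argsort(inten[peaks])[::-1]
            centers = np.sort(mz[peaks[order[:n]]])
        elif n == 1:
            centers = np.array([mz[imax]])
        else:
            # one visible mode: seed the second component off to the side
            centers = np.sort(np.array([mz[imax], mz[imax] + 3.0 * sigma0]))
    else:
        centers = np.sort(np.asarray(init_centers, dtype=float))
    amps = np.interp(centers, mz, inten)
    amps = np.maximum(amps, inten.max() * 1e-3)
    return centers, np.full(n, sigma0), amps


def fit_gaussian_mixture(
    envelope: Envelope,
    n_components: int,
    init_centers=None,
    center_window: float | None = None,
) -> GaussianMix:
    """Deterministic least-squares fit of an n-component Gaussian mixture.

    Initialization: component centers at the n highest local maxima (or the
    caller-provided ``init_centers``), sigma from the FWHM of the dominant
    peak.  ``center_window`` bounds each fitted center to +/- that many m/z
    around its initial value — used when the series context pins the low
    and high component positions.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    mz, inten = envelope.mz, envelope.intensity
    if mz.size < 20:
        raise ValueError("need at least 20 grid points for envelope fitting")
    centers0, sigmas0, amps0 = _initial_guess(envelope, n_components, init_centers)

    theta0, lo, hi = [], [], []
    dstep = float(np.median(np.diff(mz)))
    for a, c, s in zip(amps0, centers0, sigmas0):
        # centers stay on the observed grid: an off-grid Gaussian could carry
        # arbitrary invisible area without penalizing the residuals
        c = float(np.clip(c, mz[0], mz[-1]))
        c_lo = mz[0] if center_window is None else max(c - center_window, mz[0])
        c_hi = mz[-1] if center_window is None else min(c + center_window, mz[-1])
        theta0 += [a, c, s]
        lo += [0.0, c_lo, dstep / 2]
        hi += [np.inf, c_hi, (mz[-1] - mz[0])]
    converged = True
    try:
        popt, _ = curve_fit(
            _gauss_sum, mz, inten, p0=theta0, bounds=(lo, hi), maxfev=40000
        )
    except RuntimeError:
        converged = False
        popt = np.asarray(theta0, dtype=float)
    resid = inten - _gauss_sum(mz, *popt)
    rss = float(resid @ resid)
    n_pts = mz.size
    k = len(popt)
    aic = n_pts * np.log(max(rss, 1e-300) / n_pts) + 2 * k

    amps = np.asarray(popt[0::3])
    centers = np.asarray(popt[1::3])
    sigmas = np.asarray(popt[2::3])
    order = np.argsort(centers)
    amps, centers, sigmas = amps[order], centers[order], sigmas[order]
    areas = amps * sigmas * SQRT_2PI

    degenerate = False
    if n_components == 2:
        total = areas.sum()
        if total == 0 or areas.min() / max(total, 1e-300) < 1e-6 or (
            abs(centers[1] - centers[0]) < 0.5 * max(sigmas)
        ):
            degenerate = True
    return GaussianMix(
        n_components=n_components,
        centers=centers,
        sigmas=sigmas,
        areas=areas,
        rss=rss,
        aic=float(aic),
        degenerate=degenerate,
        converged=converged,
    )


def fit_double_gaussian(
    envelope: Envelope, init_centers=None, center_window: float | None = None
) -> GaussianMix:
    """Two-component deconvolution; components ordered low then high m/z."""
    return fit_gaussian_mixture(envelope, 2, init_centers, center_window)


def detect_bimodality(
    envelope: Envelope,
    delta_aic_min: float = 10.0,
    separation_factor: float = 2.0,
    min_minor_fraction: float = 0.1,
) -> tuple[bool, dict]:
    """AIC-based 1-vs-2 Gaussian bimodality test.

    The envelope is called bimodal iff the two-component fit improves AIC
    by more than ``delta_aic_min`` AND the centers are separated by more
    than ``separation_factor * max(sigma)`` AND the minor component carries
    more than ``min_minor_fraction`` of the area.  A non-convergent
    two-component fit yields a unimodal verdict with a flag.  The verdict
    is invariant to uniform intensity scaling.
    """
    one = fit_gaussian_mixture(envelope, 1)
    two = fit_gaussian_mixture(envelope, 2)
    diagnostics = {
        "delta_aic": one.aic - two.aic,
        "separation": float(abs(two.centers[1] - two.centers[0])),
        "max_sigma": float(two.sigmas.max()),
        "minor_fraction": float(two.fractions.min()),
        "converged": two.converged,
        "thresholds": {
            "delta_aic_min": delta_aic_min,
            "separation_factor": separation_factor,
            "min_minor_fraction": min_minor_fraction,
        },
    }
    if not two.converged:
        return False, diagnostics
    bimodal = (
        diagnostics["delta_aic"] > delta_aic_min
        and diagnostics["separation"] > separation_factor * diagnostics["max_sigma"]
        and diagnostics["minor_fraction"] > min_minor_fraction
    )
    return bool(bimodal), diagnostics


def bimodal_melt_curve(
    mixes: dict[float, list[GaussianMix]], min_time_points: int = 4
) -> dict:
    """Per-temperature mean (and s.e.m.) of the low-m/z fraction.

    ``mixes`` maps pre-pulse temperature to the deconvolutions obtained at
    the labeling time points of that temperature; temperatures with fewer
    than ``min_time_points`` deconvolutions are excluded with a warning.
    The output feeds the Hill fit that yields T50-HDX-Bi.
    """
    temps, means, sems = [], [], []
    for t in sorted(mixes):
        fracs = np.array([m.low_fraction for m in mixes[t]], dtype=float)
        if fracs.size < min_time_points:
            warnings.warn(
                f"temperature {t} has {fracs.size} < {min_time_points} time points; excluded",
                UserWarning,
                stacklevel=2,
            )
            continue
        temps.append(t)
        means.append(fracs.mean())
        sems.append(fracs.std(ddof=1) / np.sqrt(fracs.size) if fracs.size > 1 else 0.0)
    return {
        "temperature_C": np.array(temps, dtype=float),
        "fraction": np.array(means, dtype=float),
        "sem": np.array(sems, dtype=float),
    }


def melt_series_from_envelopes(
    envelopes: dict[float, list[Envelope]],
    min_time_points: int = 4,
    center_window: float = 1.0,
) -> dict:
    """Deconvolve a temperature series of envelopes into low-m/z fractions.

    The low- and high-m/z component positions are pinned by the series
    itself: the coldest temperature's dominant peak defines the low center
    and the hottest temperature's the high center.  Each envelope is then
    fitted with a double Gaussian whose centers are bounded to
    ``center_window`` m/z around those anchors, which keeps the
    deconvolution identifiable even when one component vanishes far from
    the midpoint.
    """
    if not envelopes:
        raise ValueError("no envelopes supplied")
    temps = sorted(envelopes)
    cold = average_envelopes(envelopes[temps[0]])
    hot = average_envelopes(envelopes[temps[-1]])
    low_c = cold.mz[int(np.argmax(cold.intensity))]
    high_c = hot.mz[int(np.argmax(hot.intensity))]
    if high_c <= low_c:
        raise ValueError(
            "hottest-temperature peak is not above the coldest-temperature peak; "
            "cannot anchor low/high components"
        )
    mixes: dict[float, list[GaussianMix]] = {}
    for t in temps:
        mixes[t] = [
            fit_double_gaussian(env, init_centers=(low_c, high_c), center_window=center_window)
            for env in envelopes[t]
        ]
    curve = bimodal_melt_curve(mixes, min_time_points=min_time_points)
    curve["mixes"] = mixes
    return curve


def read_envelopes(manifest_path: str | Path) -> list[Envelope]:
    """Load envelopes listed in a manifest TSV.

    Manifest columns: file, peptide, charge, temperature_C, time_s,
    replicate.  Each envelope file is a two-column CSV (mz, intensity),
    path relative to the manifest.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"file", "peptide", "charge", "temperature_C", "time_s", "replicate"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    envelopes = []
    for row in manifest.itertuples(index=False):
        df = pd.read_csv(manifest_path.parent / row.file)
        envelopes.append(
            Envelope(
                mz=df["mz"].to_numpy(),
                intensity=df["intensity"].to_numpy(),
                peptide=row.peptide,
                charge=int(row.charge),
                temperature_C=float(row.temperature_C),
                time_s=float(row.time_s),
                replicate=int(row.replicate),
            )
        )
    return envelopes
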