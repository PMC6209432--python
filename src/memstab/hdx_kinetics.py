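"""Double-exponential deuterium-uptake kinetics and shared-rate global fits.

Uptake of a peptide is modeled as

    D(t) = A0 + A1*(1 - exp(-k1*t)) + A2*(1 - exp(-k2*t))

where A0 is the amplitude of the initial burst (uptake already complete by
the first, 10 s, time point), A1/k1 the intermediate component and A2/k2
the slow component.  k1 > k2 > 0 is enforced by disjoint rate bounds
(defaults k1 in [1e-3, 1] s^-1, k2 in [1e-6, 1e-3] s^-1, matching the
observed regimes) which prevents label swapping between the components.

The amplitude sum A0+A1+A2 is constrained to a caller-supplied ceiling —
the saturating uptake observed for the peptide at the harshest condition —
implemented as an exact equality through a simplex reparameterization
(two free fractions on [0,1] determine all three amplitudes).

For temperature pre-pulse series, a *global* fit shares k1 and k2 across
all temperatures of a peptide while fitting per-temperature amplitudes.
The slow-component fractional amplitude A2/(A0+A1+A2), normalized to its
value at the 20 degC reference, is the unimodal melting observable
(T50-HDX-Uni after Hill fitting).

Uptake values are relative (no back-exchange correction is applied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .hdx_rates import max_exchangeable

__all__ = [
    "PeptideID",
    "UptakeSeries",
    "ExpFit",
    "GlobalExpFit",
    "double_exponential",
    "fit_uptake",
    "fit_uptake_global",
    "slow_fraction_curve",
    "read_uptake_csv",
]

DEFAULT_K1_BOUNDS = (1e-3, 1.0)
DEFAULT_K2_BOUNDS = (1e-6, 1e-3)


@dataclass(frozen=True)
class PeptideID:
    """A peptic peptide located in the parent protein."""

    sequence: str
    start: int
    end: int
    charge: int = 1

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("start/end span does not match sequence length")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")

    @property
    def max_exchangeable(self) -> int:
        return max_exchangeable(self.sequence)

    @property
    def label(self) -> str:
        return f"{self.start}-{self.end}"


@dataclass
class UptakeSeries:
    """Deuterium uptake time course of one peptide under one condition."""

    peptide: PeptideID
    condition: float | str  # pre-pulse temperature (degC) or a reference label
    times_s: np.ndarray
    uptake_Da: np.ndarray
    sem: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.uptake_Da = np.asarray(self.uptake_Da, dtype=float)
        if self.times_s.shape != self.uptake_Da.shape or self.times_s.ndim != 1:
            raise ValueError("times and uptake must be matching 1-D arrays")
        if not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.uptake_Da < 0):
            raise ValueError("uptake values must be non-negative")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
        # relative values may slightly exceed the theoretical maximum
        if np.any(self.uptake_Da > self.peptide.max_exchangeable + 1e-9):
            warnings.warn(
                f"peptide {self.peptide.label}: uptake exceeds the theoretical maximum "
                f"({self.peptide.max_exchangeable} Da); values are relative, continuing",
                UserWarning,
                stacklevel=2,
            )


def double_exponential(t, a0, a1, a2, k1, k2):
    t = np.asarray(t, dtype=float)
    return a0 + a1 * (1.0 - np.exp(-k1 * t)) + a2 * (1.0 - np.exp(-k2 * t))


@dataclass
class ExpFit:
    """Single-condition double-exponential fit (amplitude sum = ceiling)."""

    peptide: PeptideID
    condition: float | str
    a0: float
    a1: float
    a2: float
    k1: float
    k2: float
    constraint_max: float
    rss: float
    dof: int
    success: bool

    @property
    def slow_fraction(self) -> float:
        return self.a2 / (self.a0 + self.a1 + self.a2)

    def predict(self, t):
        return double_exponential(t, self.a0, self.a1, self.a2, self.k1, self.k2)


@dataclass
class GlobalExpFit:
    """Shared-rate fit over all pre-pulse temperatures of one peptide."""

    peptide: PeptideID
    k1: float
    k2: float
    amplitudes: dict  # condition -> (a0, a1, a2)
    constraint_max: float
    rss: float
    dof: int
    success: bool
    dropped_conditions: list = field(default_factory=list)

    @property
    def slow_fractions(self) -> dict:
        return {
            c: a[2] / (a[0] + a[1] + a[2]) for c, a in self.amplitudes.items()
        }

    def predict(self, condition, t):
        a0, a1, a2 = self.amplitudes[condition]
        return double_exponential(t, a0, a1, a2, self.k1, self.k2)


def _amplitudes_from_simplex(ceiling: float, f0: float, f1: float):
    """Map two [0,1] fractions onto (a0, a1, a2) with a0+a1+a2 == ceiling."""
    a0 = ceiling * f0
    a1 = ceiling * (1.0 - f0) * f1
    a2 = ceiling * (1.0 - f0) * (1.0 - f1)
    return a0, a1, a2


def _add_condition_params(params: Parameters, tag: str, ceiling: float, series: UptakeSeries,
                          fix_a0: bool) -> None:
    f0_init = float(np.clip(series.uptake_Da[0] / ceiling, 1e-6, 1 - 1e-6))
    params.add(f"f0_{tag}", value=f0_init, min=0.0, max=1.0, vary=not fix_a0)
    params.add(f"f1_{tag}", value=0.5, min=0.0, max=1.0)


def _residuals(params, datasets, ceiling):
    k1 = params["k1"].value
    k2 = params["k2"].value
    out = []
    for tag, series in datasets:
        a0, a1, a2 = _amplitudes_from_simplex(
            ceiling, params[f"f0_{tag}"].value, params[f"f1_{tag}"].value
        )
        out.append(series.uptake_Da - double_exponential(series.times_s, a0, a1, a2, k1, k2))
    return np.concatenate(out)


def _run_fit(datasets, ceiling, k1_bounds, k2_bounds, fix_a0):
    params = Parameters()
    params.add("k1", value=1e-2, min=k1_bounds[0], max=k1_bounds[1])
    params.add("k2", value=1e-4, min=k2_bounds[0], max=k2_bounds[1])
    for tag, series in datasets:
        _add_condition_params(params, tag, ceiling, series, fix_a0)
    result = minimize(
        _residuals, params, args=(datasets, ceiling), method="least_squares"
    )
    return result


def fit_uptake(
    series: UptakeSeries,
    amplitude_ceiling: float,
    k1_bounds: tuple[float, float] = DEFAULT_K1_BOUNDS,
    k2_bounds: tuple[float, float] = DEFAULT_K2_BOUNDS,
    fix_a0: bool = False,
) -> ExpFit:
    """Bounded least-squares double-exponential fit of one time course.

    ``amplitude_ceiling`` is the enforced A0+A1+A2 (the saturating uptake
    observed for the peptide under reference conditions).  A0 is a free
    fitted offset initialized at the first time point; ``fix_a0`` pins it
    there instead (strict mode).
    """
    if series.times_s.size < 4:
        raise ValueError("need at least 4 time points for a double-exponential fit")
    if amplitude_ceiling <= 0:
        raise ValueError("amplitude ceiling must be positive")
    if amplitude_ceiling < series.uptake_Da.max() - 1e-9:
        raise ValueError(
            "amplitude ceiling is below the maximum observed uptake; invalid constraint"
        )
    if not np.any(series.uptake_Da > 0):
        return ExpFit(
            peptide=series.peptide,
            condition=series.condition,
            a0=0.0,
            a1=0.0,
            a2=0.0,
            k1=np.nan,
            k2=np.nan,
            constraint_max=amplitude_ceiling,
            rss=0.0,
            dof=int(series.times_s.size),
            success=True,
        )
    datasets = [("c0", series)]
    result = _run_fit(datasets, amplitude_ceiling, k1_bounds, k2_bounds, fix_a0)
    if not result.success:
        warnings.warn(
            f"double-exponential fit did not converge for peptide {series.peptide.label}",
            UserWarning,
            stacklevel=2,
        )
    a0, a1, a2 = _amplitudes_from_simplex(
        amplitude_ceiling, result.params["f0_c0"].value, result.params["f1_c0"].value
    )
    return ExpFit(
        peptide=series.peptide,
        condition=series.condition,
        a0=a0,
        a1=a1,
        a2=a2,
        k1=result.params["k1"].value,
        k2=result.params["k2"].value,
        constraint_max=amplitude_ceiling,
        rss=float(np.sum(np.asarray(result.residual) ** 2)),
        dof=int(result.nfree),
        success=bool(result.success),
    )


def fit_uptake_global(
    series_set: dict[float, UptakeSeries],
    saturating_max: float,
    k1_bounds: tuple[float, float] = DEFAULT_K1_BOUNDS,
    k2_bounds: tuple[float, float] = DEFAULT_K2_BOUNDS,
    fix_a0: bool = False,
) -> GlobalExpFit:
    """Global shared-rate fit across all pre-pulse temperatures of a peptide.

    One (k1, k2) pair is shared; each temperature gets its own amplitude
    triple with A0+A1+A2 constrained to ``saturating_max`` (the saturating
    uptake at the highest temperature measured).
    """
    if len(series_set) < 2:
        raise ValueError("global fit requires at least 2 conditions")
    peptides = {s.peptide for s in series_set.values()}
    if len(peptides) != 1:
        raise ValueError("all series in a global fit must share one peptide")
    if saturating_max <= 0:
        raise ValueError("saturating_max must be positive")

    dropped = []
    datasets = []
    for idx, cond in enumerate(sorted(series_set)):
        s = series_set[cond]
        if s.times_s.size == 0 or not np.all(np.isfinite(s.uptake_Da)):
            dropped.append(cond)
            continue
        if saturating_max < s.uptake_Da.max() - 1e-9:
            raise ValueError(
                f"saturating_max below observed uptake at condition {cond}; invalid constraint"
            )
        datasets.append((f"c{idx}", s))
    if dropped:
        warnings.warn(
            f"conditions dropped from global fit (missing data): {dropped}",
            UserWarning,
            stacklevel=2,
        )
    if len(datasets) < 2:
        raise ValueError("fewer than 2 usable conditions after dropping missing data")

    result = _run_fit(datasets, saturating_max, k1_bounds, k2_bounds, fix_a0)
    if not result.success:
        warnings.warn("global double-exponential fit did not converge", UserWarning, stacklevel=2)
    amplitudes = {}
    for tag, s in datasets:
        amplitudes[s.condition] = _amplitudes_from_simplex(
            saturating_max, result.params[f"f0_{tag}"].value, result.params[f"f1_{tag}"].value
        )
    return GlobalExpFit(
        peptide=next(iter(peptides)),
        k1=result.params["k1"].value,
        k2=result.params["k2"].value,
        amplitudes=amplitudes,
        constraint_max=saturating_max,
        rss=float(np.sum(np.asarray(result.residual) ** 2)),
        dof=int(result.nfree),
        success=bool(result.success),
        dropped_conditions=dropped,
    )


def slow_fraction_curve(global_fit: GlobalExpFit, reference_condition: float = 20.0) -> dict:
    """Slow-component fractions normalized to the reference temperature.

    normalized(T) = frac(T) / frac(T_ref); the reference reads exactly 1.
    A zero reference fraction leaves the normalization undefined and the
    peptide is flagged unanalyzable.
    """
    fracs = global_fit.slow_fractions
    if reference_condition not in fracs:
        raise ValueError(f"reference condition {reference_condition} not present in the fit")
    ref = fracs[reference_condition]
    if ref == 0:
        raise ValueError(
            f"slow fraction at the reference condition is zero; peptide "
            f"{global_fit.peptide.label} is unanalyzable"
        )
    return {c: fracs[c] / ref for c in sorted(fracs)}


def read_uptake_csv(path: str | Path) -> dict[tuple, UptakeSeries]:
    """Read uptake tables in the native schema or a DynamX-cluster-like dialect.

    Native columns: peptide, start, end, sequence, charge, temperature_C,
    time_s, uptake_Da, sd, n_rep.  DynamX-like columns: Protein, Sequence,
    Start, End, Charge, State, Exposure, Uptake (Exposure in minutes).
    Returns {(peptide_label, condition): UptakeSeries}.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"Sequence", "Start", "End", "Exposure"}.issubset(cols):
        uptake_col = "Uptake" if "Uptake" in cols else "Center"
        df = pd.DataFrame(
            {
                "sequence": df["Sequence"],
                "start": df["Start"],
                "end": df["End"],
                "charge": df.get("Charge", 1),
                "temperature_C": df["State"],
                "time_s": df["Exposure"] * 60.0,
                "uptake_Da": df[uptake_col],
                "sd": np.nan,
                "n_rep": 1,
            }
        )
    required = {"sequence", "start", "end", "charge", "temperature_C", "time_s", "uptake_Da"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"uptake table is missing columns: {sorted(missing)}")

    out: dict[tuple, UptakeSeries] = {}
    keys = ["sequence", "start", "end", "charge", "temperature_C"]
    for (seq, start, end, charge, cond), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_s")
        pep = PeptideID(sequence=seq, start=int(start), end=int(end), charge=int(charge))
        try:
            cond_key: float | str = float(cond)
        except (TypeError, ValueError):
            cond_key = str(cond)
        out[(pep.label, cond_key)] = UptakeSeries(
            peptide=pep,
            condition=cond_key,
            times_s=grp["time_s"].to_numpy(),
            uptake_Da=grp["uptake_Da"].to_numpy(),
            sem=grp["sd"].to_numpy() if "sd" in grp else None,
            n_replicates=int(grp["n_rep"].iloc[0]) if "n_rep" in grp else 1,
        )
    return out
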