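"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator draws from the analytic model of the observable it emulates
(plus additive Gaussian measurement noise on the observable) and returns
the data together with a ground-truth sidecar dictionary, so parameter
recovery is testable end to end without external measurements:

* ``gen_msa`` — alignment columns with controlled residue frequencies and
  optionally planted covarying column pairs (columns independent otherwise).
* ``gen_chromatogram`` — two-Gaussian SEC profiles (trimer ~3.0 ml,
  monomer ~3.5 ml) with a prescribed trimer area fraction.
* ``gen_uptake`` — double-exponential deuterium uptake time courses with
  shared rates and per-temperature amplitudes, replicate-averaged.
* ``gen_envelope`` — Gaussian-mixture m/z envelopes on a uniform grid
  (default 0.02 m/z spacing, >= 10 points per isotopic-width Gaussian).
* ``gen_transport`` — Michaelis-Menten rate tables.

``*_melt_series`` helpers tie a generator to the Hill melting law so that a
whole pre-pulse temperature series shares one ground-truth (T50, H).
Identical seeds give byte-identical outputs; zero noise gives the exact
model curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .envelope_analysis import Envelope
from .hdx_kinetics import PeptideID, UptakeSeries, double_exponential
from .melting_curves import Chromatogram, hill_model

__all__ = [
    "SimSpec",
    "gen_msa",
    "gen_chromatogram",
    "gen_chromatogram_melt_series",
    "gen_uptake",
    "gen_uptake_melt_series",
    "gen_envelope",
    "gen_envelope_melt_series",
    "gen_transport",
    "simulate",
]

SIM_KINDS = ("msa", "chromatogram", "uptake", "envelope", "transport")
DEFAULT_TIMES_S = (10.0, 60.0, 300.0, 1800.0, 3600.0)
DEFAULT_CONCENTRATIONS_UM = (0.0, 5.0, 50.0, 200.0)


@dataclass
class SimSpec:
    """A reproducible simulation request (kind + parameters + seed)."""

    seed: int
    kind: str
    params: dict = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SIM_KINDS:
            raise ValueError(f"kind must be one of {SIM_KINDS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _profile_to_arrays(profile: dict) -> tuple[list[str], np.ndarray]:
    letters = sorted(profile)
    probs = np.array([profile[l] for l in letters], dtype=float)
    if np.any(probs < 0):
        raise ValueError("profile with negative mass")
    total = probs.sum()
    if total > 1.0 + 1e-9:
        raise ValueError("profile mass exceeds 1")
    return letters + ["-"], np.append(probs, max(0.0, 1.0 - total))


def gen_msa(
    n_seqs: int,
    length: int,
    column_profiles: dict[int, dict[str, float]],
    coupled_pairs: list[tuple[int, int, dict[tuple[str, str], float]]] | None = None,
    target_seq: str | None = None,
    target_id: str = "TARGET",
    seed: int = 0,
):
    """Sample an alignment with prescribed column frequencies.

    ``column_profiles`` maps 1-based column index to a residue->frequency
    dict (remaining mass is gap probability); unlisted columns copy the
    target residue with probability 1.  ``coupled_pairs`` are
    (i, j, joint) triples whose joint distribution over residue pairs
    replaces the two marginal columns.  The target sequence is included as
    the first, named row; the n_seqs count includes it.

    Returns (MultipleSeqAlignment, ground_truth).
    """
    if target_seq is None or len(target_seq) != length:
        raise ValueError("target_seq of the stated length is required")
    if n_seqs < 1:
        raise ValueError("n_seqs must be >= 1")
    rng = np.random.default_rng(seed)
    n_sample = n_seqs - 1

    coupled_cols: set[int] = set()
    for i, j, _joint in coupled_pairs or []:
        if i in coupled_cols or j in coupled_cols:
            raise ValueError("overlapping coupled pairs")
        coupled_cols.update((i, j))

    cols = np.empty((n_sample, length), dtype="<U1")
    for c in range(1, length + 1):
        if c in coupled_cols:
            continue
        profile = column_profiles.get(c, {target_seq[c - 1]: 1.0})
        letters, probs = _profile_to_arrays(profile)
        cols[:, c - 1] = rng.choice(letters, size=n_sample, p=probs)
    for i, j, joint in coupled_pairs or []:
        states = sorted(joint)
        probs = np.array([joint[s] for s in states], dtype=float)
        if np.any(probs < 0):
            raise ValueError("profile with negative mass")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("coupled-pair joint distribution must sum to 1")
        draws = rng.choice(len(states), size=n_sample, p=probs)
        cols[:, i - 1] = [states[d][0] for d in draws]
        cols[:, j - 1] = [states[d][1] for d in draws]

    records = [SeqRecord(Seq(target_seq), id=target_id, description="")]
    records += [
        SeqRecord(Seq("".join(cols[r])), id=f"seq{r + 1:05d}", description="")
        for r in range(n_sample)
    ]
    truth = {
        "column_profiles": {int(k): dict(v) for k, v in column_profiles.items()},
        "coupled_pairs": [
            {"i": i, "j": j, "joint": {f"{a}{b}": p for (a, b), p in joint.items()}}
            for i, j, joint in coupled_pairs or []
        ],
        "target_id": target_id,
        "n_seqs": n_seqs,
        "seed": seed,
    }
    return MultipleSeqAlignment(records), truth


def gen_chromatogram(
    trimer_fraction: float,
    trimer_center_ml: float = 3.0,
    monomer_center_ml: float = 3.5,
    widths_ml: tuple[float, float] = (0.08, 0.08),
    total_area: float = 1.0,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    temperature_C: float | None = None,
):
    """Two-Gaussian SEC profile with a prescribed trimer area fraction."""
    if not 0.0 <= trimer_fraction <= 1.0:
        raise ValueError("trimer_fraction must lie in [0, 1]")
    if any(w <= 0 for w in widths_ml):
        raise ValueError("peak widths must be positive")
    v = np.arange(2.0, 4.5001, 0.005) if grid is None else np.asarray(grid, dtype=float)
    if not (v[0] <= trimer_center_ml <= v[-1] and v[0] <= monomer_center_ml <= v[-1]):
        raise ValueError("peak centers must lie within the volume grid")
    wt, wm = widths_ml
    step = float(np.max(np.diff(v)))
    coarse = step > min(wt, wm) / 10.0  # fewer than 10 points per width

    def gauss(x, mu, sig):
        return np.exp(-0.5 * ((x - mu) / sig) ** 2) / (sig * np.sqrt(2 * np.pi))

    signal = total_area * (
        trimer_fraction * gauss(v, trimer_center_ml, wt)
        + (1.0 - trimer_fraction) * gauss(v, monomer_center_ml, wm)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=v.size)
    truth = {
        "trimer_fraction": trimer_fraction,
        "trimer_center_ml": trimer_center_ml,
        "monomer_center_ml": monomer_center_ml,
        "widths_ml": list(widths_ml),
        "total_area": total_area,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return (
        Chromatogram(
            volume_ml=v,
            signal=signal,
            temperature_C=temperature_C,
            coarse_grid=coarse,
        ),
        truth,
    )


def gen_chromatogram_melt_series(
    t50: float,
    h: float,
    temperatures_C,
    noise_sd: float = 0.0,
    seed: int = 0,
    **chromatogram_kwargs,
):
    """SEC melt series whose trimer fraction follows the Hill law."""
    rng = np.random.default_rng(seed)
    out: dict[float, Chromatogram] = {}
    for t in temperatures_C:
        frac = float(hill_model(t, t50, h))
        chrom, _ = gen_chromatogram(
            trimer_fraction=frac,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            temperature_C=float(t),
            **chromatogram_kwargs,
        )
        out[float(t)] = chrom
    truth = {"t50": t50, "h": h, "noise_sd": noise_sd, "seed": seed}
    return out, truth


def gen_uptake(
    peptide: PeptideID,
    per_temperature_params: dict[float, tuple[float, float, float]],
    shared_rates: tuple[float, float],
    times_s=DEFAULT_TIMES_S,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
):
    """Double-exponential uptake series per pre-pulse temperature.

    Rates follow the decay convention D(t) = A0 + A1(1-e^{-k1 t}) +
    A2(1-e^{-k2 t}) with k1, k2 > 0.  Replicates are averaged; the s.e.m.
    of the replicates is carried on each point.
    """
    k1, k2 = shared_rates
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rates must be positive (decay convention)")
    t = np.asarray(times_s, dtype=float)
    rng = np.random.default_rng(seed)
    out: dict[float, UptakeSeries] = {}
    for temp in sorted(per_temperature_params):
        a0, a1, a2 = per_temperature_params[temp]
        if min(a0, a1, a2) < 0:
            raise ValueError("negative amplitudes")
        if a0 + a1 + a2 > peptide.max_exchangeable + 1e-9:
            raise ValueError(
                "A0+A1+A2 exceeds the exchangeable amides of the peptide"
            )
        model = double_exponential(t, a0, a1, a2, k1, k2)
        if noise_sd > 0:
            reps = model[None, :] + rng.normal(0.0, noise_sd, size=(n_replicates, t.size))
            reps = np.clip(reps, 0.0, None)
            mean = reps.mean(axis=0)
            sem = reps.std(axis=0, ddof=1) / np.sqrt(n_replicates) if n_replicates > 1 else None
        else:
            mean, sem = model, None
        out[float(temp)] = UptakeSeries(
            peptide=peptide,
            condition=float(temp),
            times_s=t,
            uptake_Da=mean,
            sem=sem,
            n_replicates=n_replicates if noise_sd > 0 else 1,
        )
    truth = {
        "per_temperature_params": {
            float(k): list(map(float, v)) for k, v in per_temperature_params.items()
        },
        "shared_rates": [k1, k2],
        "noise_sd": noise_sd,
        "n_replicates": n_replicates,
        "seed": seed,
    }
    return out, truth


def gen_uptake_melt_series(
    peptide: PeptideID,
    t50: float,
    h: float,
    temperatures_C,
    shared_rates: tuple[float, float] = (0.05, 5e-4),
    total_uptake: float | None = None,
    slow_fraction_ref: float = 0.85,
    burst_share: float = 0.3,
    times_s=DEFAULT_TIMES_S,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
):
    """Uptake melt series whose slow-fraction amplitude follows the Hill law.

    At each temperature T the slow amplitude is
    A2 = M * slow_fraction_ref * f(T; T50, H); the remainder is split
    between the burst (A0, ``burst_share`` of it) and the intermediate
    component, so A0+A1+A2 = M (the saturating maximum) at every
    temperature.
    """
    M = float(total_uptake) if total_uptake is not None else 0.8 * peptide.max_exchangeable
    params: dict[float, tuple[float, float, float]] = {}
    for t in temperatures_C:
        slow = M * slow_fraction_ref * float(hill_model(t, t50, h))
        rest = M - slow
        params[float(t)] = (burst_share * rest, (1.0 - burst_share) * rest, slow)
    series, truth = gen_uptake(
        peptide,
        params,
        shared_rates,
        times_s=times_s,
        noise_sd=noise_sd,
        n_replicates=n_replicates,
        seed=seed,
    )
    truth.update(
        {
            "t50": t50,
            "h": h,
            "total_uptake": M,
            "slow_fraction_ref": slow_fraction_ref,
            "burst_share": burst_share,
        }
    )
    return series, truth


def gen_envelope(
    components: list[tuple[float, float, float]],
    charge: int = 1,
    grid_mz: np.ndarray | None = None,
    grid_step: float = 0.02,
    total_intensity: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    temperature_C: float | None = None,
    time_s: float | None = None,
    replicate: int = 1,
    peptide: PeptideID | None = None,
):
    """Gaussian-mixture m/z envelope from (center, sigma, area_fraction) triples."""
    if not components:
        raise ValueError("empty component list")
    fractions = np.array([c[2] for c in components], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("component area fractions must sum to 1")
    if any(c[1] <= 0 for c in components):
        raise ValueError("component widths must be positive")
    if grid_mz is None:
        lo = min(c[0] - 5 * c[1] for c in components)
        hi = max(c[0] + 5 * c[1] for c in components)
        grid_mz = np.arange(lo, hi + grid_step / 2, grid_step)
    mz = np.asarray(grid_mz, dtype=float)
    intensity = np.zeros_like(mz)
    for center, sigma, frac in components:
        intensity += (
            total_intensity
            * frac
            / (sigma * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * ((mz - center) / sigma) ** 2)
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = np.clip(intensity + rng.normal(0.0, noise_sd, size=mz.size), 0.0, None)
    truth = {
        "components": [list(map(float, c)) for c in components],
        "charge": charge,
        "total_intensity": total_intensity,
        "noise_sd": noise_sd,
        "seed": seed,
        "centroid": float(np.sum(fractions * np.array([c[0] for c in components]))),
    }
    env = Envelope(
        mz=mz,
        intensity=intensity,
        peptide=peptide,
        charge=charge,
        temperature_C=temperature_C,
        time_s=time_s,
        replicate=replicate,
    )
    return env, truth


def gen_envelope_melt_series(
    t50: float,
    h: float,
    temperatures_C,
    low_center_mz: float = 600.0,
    high_center_mz: float = 603.0,
    sigma_mz: float = 0.5,
    charge: int = 2,
    times_s=DEFAULT_TIMES_S,
    noise_sd: float = 0.0,
    seed: int = 0,
    peptide: PeptideID | None = None,
):
    """Bimodal envelope series whose low-m/z fraction follows the Hill law.

    One envelope per (temperature, labeling time); the low/high area split
    is constant across the labeling times of a temperature (EX1-like
    two-state picture), so the per-temperature averages recover the Hill
    fractions.
    """
    rng = np.random.default_rng(seed)
    grid = np.arange(
        low_center_mz - 5 * sigma_mz, high_center_mz + 5 * sigma_mz + 0.01, 0.02
    )
    out: dict[float, list[Envelope]] = {}
    for t in temperatures_C:
        frac_low = float(hill_model(t, t50, h))
        envs = []
        for time in times_s:
            env, _ = gen_envelope(
                components=[
                    (low_center_mz, sigma_mz, frac_low),
                    (high_center_mz, sigma_mz, 1.0 - frac_low),
                ],
                charge=charge,
                grid_mz=grid,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                temperature_C=float(t),
                time_s=float(time),
                peptide=peptide,
            )
            envs.append(env)
        out[float(t)] = envs
    truth = {
        "t50": t50,
        "h": h,
        "low_center_mz": low_center_mz,
        "high_center_mz": high_center_mz,
        "sigma_mz": sigma_mz,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return out, truth


def gen_transport(
    km_uM: float,
    vmax: float,
    concentrations_uM=DEFAULT_CONCENTRATIONS_UM,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
):
    """Michaelis-Menten rate table: rate(c) = Vmax*c/(Km+c) + noise."""
    if km_uM <= 0:
        raise ValueError("Km must be positive")
    if vmax < 0:
        raise ValueError("Vmax must be non-negative")
    c = np.asarray(concentrations_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative concentration")
    model = vmax * c / (km_uM + c)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        reps = model[None, :] + rng.normal(0.0, noise_sd, size=(n_replicates, c.size))
        rate = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros_like(c)
    else:
        rate, sd = model, np.zeros_like(c)
    table = pd.DataFrame({"conc_uM": c, "rate": rate, "sd": sd})
    truth = {
        "km_uM": km_uM,
        "vmax": vmax,
        "noise_sd": noise_sd,
        "n_replicates": n_replicates,
        "seed": seed,
    }
    return table, truth


def _write_sidecar(outdir: Path, stem: str, truth: dict) -> None:
    (outdir / f"{stem}.truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def simulate(spec: SimSpec, outdir: str | Path) -> dict:
    """Run one SimSpec and write data + ground-truth sidecar to ``outdir``.

    Output formats: FASTA for MSAs; CSV for chromatograms (volume_ml,
    signal), uptake tables, envelopes (mz, intensity) and transport rates;
    JSON sidecar with the generator's ground truth.  Returns a manifest of
    the written files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    p = dict(spec.params)

    if spec.kind == "msa":
        coupled = [
            (cp["i"], cp["j"], {(k[0], k[1]): v for k, v in cp["joint"].items()})
            for cp in p.pop("coupled_pairs", [])
        ]
        profiles = {int(k): v for k, v in p.pop("column_profiles", {}).items()}
        aln, truth = gen_msa(
            coupled_pairs=coupled, column_profiles=profiles, seed=spec.seed, **p
        )
        path = outdir / "msa.fasta"
        with open(path, "w", encoding="utf-8") as fh:
            for rec in aln:
                fh.write(f">{rec.id}\n{rec.seq}\n")
        written.append(path.name)
        _write_sidecar(outdir, "msa", truth)
    elif spec.kind == "chromatogram":
        temps = p.pop("temperatures_C")
        series, truth = gen_chromatogram_melt_series(
            noise_sd=spec.noise_sd, seed=spec.seed, temperatures_C=temps, **p
        )
        for t, chrom in series.items():
            path = outdir / f"sec_{t:g}C.csv"
            pd.DataFrame({"volume_ml": chrom.volume_ml, "signal": chrom.signal}).to_csv(
                path, index=False
            )
            written.append(path.name)
        _write_sidecar(outdir, "sec", truth)
    elif spec.kind == "uptake":
        pep = PeptideID(**p.pop("peptide"))
        temps = p.pop("temperatures_C")
        series, truth = gen_uptake_melt_series(
            pep, temperatures_C=temps, noise_sd=spec.noise_sd, seed=spec.seed, **p
        )
        rows = []
        for t, s in series.items():
            for time, up in zip(s.times_s, s.uptake_Da):
                rows.append(
                    {
                        "peptide": pep.label,
                        "start": pep.start,
                        "end": pep.end,
                        "sequence": pep.sequence,
                        "charge": pep.charge,
                        "temperature_C": t,
                        "time_s": time,
                        "uptake_Da": up,
                        "sd": np.nan,
                        "n_rep": s.n_replicates,
                    }
                )
        path = outdir / "uptake.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path.name)
        _write_sidecar(outdir, "uptake", truth)
    elif spec.kind == "envelope":
        temps = p.pop("temperatures_C")
        pep = PeptideID(**p.pop("peptide")) if "peptide" in p else None
        series, truth = gen_envelope_melt_series(
            temperatures_C=temps, noise_sd=spec.noise_sd, seed=spec.seed, peptide=pep, **p
        )
        manifest_rows = []
        for t, envs in series.items():
            for env in envs:
                fname = f"env_{t:g}C_{env.time_s:g}s.csv"
                pd.DataFrame({"mz": env.mz, "intensity": env.intensity}).to_csv(
                    outdir / fname, index=False
                )
                manifest_rows.append(
                    {
                        "file": fname,
                        "peptide": pep.label if pep else "pep",
                        "charge": env.charge,
                        "temperature_C": t,
                        "time_s": env.time_s,
                        "replicate": env.replicate,
                    }
                )
                written.append(fname)
        pd.DataFrame(manifest_rows).to_csv(outdir / "envelopes.tsv", sep="\t", index=False)
        written.append("envelopes.tsv")
        _write_sidecar(outdir, "envelopes", truth)
    elif spec.kind == "transport":
        table, truth = gen_transport(noise_sd=spec.noise_sd, seed=spec.seed, **p)
        path = outdir / "transport.csv"
        table.to_csv(path, index=False)
        written.append(path.name)
        _write_sidecar(outdir, "transport", truth)
    return {"kind": spec.kind, "files": written, "outdir": str(outdir)}
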