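"""Intrinsic (unprotected) backbone amide exchange rates in D2O.

Implements the standard empirical scheme for sequence-specific intrinsic
exchange rates built on the poly-DL-alanine reference: per-amide rates are
the acid-, base- and water-catalyzed reference rates, each scaled by
log-additive side-chain factors of the residue carrying the amide and of
the preceding residue, with extra terms for free chain termini, and an
Arrhenius correction away from the 20 degC reference temperature.

    k_int = kA*FA*[D+] + kB*FB*[OD-] + kW*FB

with [D+] = 10^-pD, [OD-] = 10^(pD - pKD), pKD = 15.05 (D2O), and
log10 FA = lambda_A(res_i) + rho_A(res_{i-1}) (+ terminal terms),
log10 FB likewise with the base factors.

Side-chain ionization is fixed at the near-neutral state (Asp/Glu
carboxylates deprotonated, His neutral, Cys reduced), appropriate for the
pD 7.4 labeling conditions this package models; the scheme is not valid at
strongly acidic pD.  The first amide of a peptide carries no measurable
deuterium (it back-exchanges during analysis) and is excluded throughout,
as are prolines, which have no amide hydrogen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IntrinsicReference", "intrinsic_reference", "max_exchangeable", "per_amide_rates"]

# log10 side-chain factors: (acid_lambda, acid_rho, base_lambda, base_rho).
# lambda applies to the amide of the residue itself, rho to the amide of
# the following residue.  Near-neutral ionization states.
_FACTORS: dict[str, tuple[float, float, float, float]] = {
    "A": (0.00, 0.00, 0.00, 0.00),
    "C": (-0.54, -0.46, 0.62, 0.55),
    "D": (0.90, 0.58, -0.30, -0.18),  # carboxylate
    "E": (-0.90, 0.31, -0.51, -0.15),  # carboxylate
    "F": (-0.52, -0.43, -0.24, 0.06),
    "G": (-0.22, 0.22, 0.27, 0.17),
    "H": (0.00, 0.00, -0.10, 0.14),  # neutral imidazole
    "I": (-0.91, -0.59, -0.73, -0.23),
    "K": (-0.56, -0.29, -0.04, 0.12),
    "L": (-0.57, -0.13, -0.58, -0.21),
    "M": (-0.64, -0.28, -0.01, 0.11),
    "N": (-0.58, -0.13, 0.49, 0.32),
    "P": (0.00, -0.19, 0.00, -0.24),  # trans; no amide H of its own
    "Q": (-0.47, -0.27, 0.06, 0.20),
    "R": (-0.59, -0.32, 0.08, 0.22),
    "S": (-0.44, -0.39, 0.37, 0.30),
    "T": (-0.79, -0.47, -0.07, 0.20),
    "V": (-0.74, -0.30, -0.70, -0.14),
    "W": (-0.40, -0.44, -0.41, -0.11),
    "Y": (-0.41, -0.37, -0.27, 0.05),
}

# Free-terminus corrections: the protonated N-terminal amine acts on the
# second residue's amide (rho position); the C-terminal carboxylate acts on
# the last residue's own amide (lambda position).
_NTERM_RHO = (-1.32, 1.62)  # (acid, base)
_CTERM_LAMBDA = (0.96, -1.80)  # (acid, base), carboxylate form

# Poly-DL-alanine reference rate constants in D2O at 20 degC
# (units: kA, kB in M^-1 min^-1; kW in min^-1) and activation energies
# (kcal/mol) for the Arrhenius temperature correction.
_LOG_KA, _LOG_KB, _LOG_KW = 1.62, 10.18, -1.5
_PKD = 15.05
_EA = {"acid": 14.0, "base": 17.0, "water": 19.0}
_R_KCAL = 1.987e-3
_T_REF_K = 293.15


def max_exchangeable(sequence: str) -> int:
    """Number of backbone amides available for exchange in a peptide.

    length - 1 (first amide systematically excluded) minus prolines at
    positions >= 2, which carry no amide hydrogen.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(_FACTORS)
    if bad:
        raise ValueError(f"non-standard residue letters: {sorted(bad)}")
    return len(seq) - 1 - seq[1:].count("P")


def _arrhenius(temperature_C: float) -> tuple[float, float, float]:
    T = temperature_C + 273.15
    corr = lambda ea: np.exp(-ea / _R_KCAL * (1.0 / T - 1.0 / _T_REF_K))
    return corr(_EA["acid"]), corr(_EA["base"]), corr(_EA["water"])


def per_amide_rates(
    sequence: str,
    pD: float = 7.4,
    temperature_C: float = 20.0,
    free_termini: bool = True,
) -> dict[int, float]:
    """Intrinsic exchange rate (s^-1) per amide of an unstructured peptide.

    Keys are 1-based positions within the peptide; position 1 and prolines
    are absent (no reportable amide).
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    if not 0.0 <= pD <= 14.0:
        raise ValueError("pD out of range")
    bad = set(seq) - set(_FACTORS)
    if bad:
        raise ValueError(f"no tabulated factors for residues: {sorted(bad)}")

    d_conc = 10.0 ** (-pD)
    od_conc = 10.0 ** (pD - _PKD)
    fa_T, fb_T, fw_T = _arrhenius(temperature_C)

    rates: dict[int, float] = {}
    for i in range(2, len(seq) + 1):  # first amide excluded
        res = seq[i - 1]
        prev = seq[i - 2]
        if res == "P":
            continue
        la, _, lb, _ = _FACTORS[res]
        _, ra, _, rb = _FACTORS[prev]
        log_fa = la + ra
        log_fb = lb + rb
        if free_termini and i == 2:
            log_fa += _NTERM_RHO[0]
            log_fb += _NTERM_RHO[1]
        if free_termini and i == len(seq):
            log_fa += _CTERM_LAMBDA[0]
            log_fb += _CTERM_LAMBDA[1]
        k_acid = 10.0 ** (_LOG_KA + log_fa) * d_conc * fa_T
        k_base = 10.0 ** (_LOG_KB + log_fb) * od_conc * fb_T
        k_water = 10.0 ** (_LOG_KW + log_fb) * fw_T
        rates[i] = (k_acid + k_base + k_water) / 60.0  # per minute -> per second
    return rates


@dataclass
class IntrinsicReference:
    """Unprotected-exchange reference for one peptide."""

    sequence: str
    pD: float
    temperature_C: float
    per_amide: dict[int, float]  # s^-1, 1-based peptide positions

    @property
    def overall_rate(self) -> float:
        """Sum of the per-amide rates (s^-1)."""
        return float(sum(self.per_amide.values()))

    @property
    def n_exchangeable(self) -> int:
        return len(self.per_amide)

    def predicted_curve(self, times_s, mode: str = "sum"):
        """Expected uptake (Da) of the fully unprotected peptide.

        mode='sum' (default): sum_i (1 - exp(-k_i t)) over amides.
        mode='single': N * (1 - exp(-k_overall t)), a one-exponential
        approximation using the summed overall rate.
        """
        t = np.asarray(times_s, dtype=float)
        if mode == "sum":
            out = np.zeros_like(t)
            for k in self.per_amide.values():
                out += 1.0 - np.exp(-k * t)
            return out
        if mode == "single":
            return self.n_exchangeable * (1.0 - np.exp(-self.overall_rate * t))
        raise ValueError("mode must be 'sum' or 'single'")


def intrinsic_reference(
    peptide, pD: float = 7.4, temperature_C: float = 20.0, free_termini: bool = True
) -> IntrinsicReference:
    """Build the unprotected-exchange reference for a peptide.

    ``peptide`` may be a sequence string or any object with a ``sequence``
    attribute.
    """
    sequence = getattr(peptide, "sequence", peptide)
    return IntrinsicReference(
        sequence=sequence,
        pD=pD,
        temperature_C=temperature_C,
        per_amide=per_amide_rates(sequence, pD, temperature_C, free_termini),
    )
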