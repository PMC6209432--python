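"""Consensus substitution design from a multiple sequence alignment.

A column-wise residue frequency profile is computed over the alignment,
mapped onto the coordinates of a chosen target sequence (columns where the
target has a gap are dropped — consensus design introduces substitutions,
never indels).  A consensus substitution is called at a position when the
most frequent non-gap residue differs from the target residue, exceeds a
minimum total frequency (default > 0.20) and exceeds the target residue's
own frequency by at least ``delta`` (default >= 0.10, in percentage
points).  Calls are then restricted to declared structured regions
(helices), and applied to the base sequence to produce a design variant.

Frequencies are computed with the total sequence count as denominator by
default (gapped rows depress all residue frequencies, the convention of
common alignment viewers); ``denominator='nongap'`` switches to counting
over non-gap rows only.  Modal ties suppress a call: "the most frequent
amino acid" is undefined under a tie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

__all__ = [
    "AMINO_ACIDS",
    "SIMILARITY_GROUPS",
    "MSAProfile",
    "ConsensusCall",
    "Region",
    "RegionSet",
    "DesignVariant",
    "build_profile",
    "call_consensus",
    "restrict_to_regions",
    "apply_design",
    "calls_to_tsv",
    "read_calls_tsv",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
GAP_CHARS = {"-", "."}
OTHER = "X"  # bin for non-standard letters

# Conservative similarity partition used for percent-similarity bookkeeping;
# recorded in output metadata since different groupings exist in the field.
SIMILARITY_GROUPS = ("ILVM", "FWY", "KRH", "DE", "ST", "NQ", "AG", "C", "P")
_GROUP_OF = {aa: grp for grp in SIMILARITY_GROUPS for aa in grp}


@dataclass
class MSAProfile:
    """Per-column residue frequencies in target-sequence coordinates."""

    target_id: str
    target_sequence: str
    n_sequences: int
    frequencies: pd.DataFrame  # index: 1-based target position; cols: AAs + OTHER
    gap_fraction: pd.Series
    denominator: str = "all"

    def __post_init__(self) -> None:
        total = self.frequencies.sum(axis=1) + (
            self.gap_fraction if self.denominator == "all" else 0.0
        )
        if self.denominator == "all" and not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("frequencies + gap fraction must sum to 1 per column")
        if len(self.frequencies) != len(self.target_sequence):
            raise ValueError("profile must have one column per target residue")

    @property
    def positions(self) -> np.ndarray:
        return self.frequencies.index.to_numpy()


@dataclass(frozen=True)
class ConsensusCall:
    """A proposed substitution target_aa -> consensus_aa at one position."""

    position: int  # 1-based in the ungapped target
    target_aa: str
    consensus_aa: str
    f_consensus: float
    f_target: float
    f_min: float
    delta: float
    in_region: bool = False
    domain: str = "none"

    def __post_init__(self) -> None:
        if self.consensus_aa == self.target_aa:
            raise ValueError("a consensus call must change the residue")


@dataclass(frozen=True)
class Region:
    name: str
    start: int  # 1-based inclusive
    end: int
    domain: str = "none"  # ScaD | TranD | none

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class RegionSet:
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        spans = sorted((r.start, r.end, r.name) for r in self.regions)
        for r in self.regions:
            if r.start < 1 or r.end < r.start:
                raise ValueError(f"invalid interval in region {r.name!r}")
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"regions {n1!r} and {n2!r} overlap")

    def validate_against(self, target_length: int) -> None:
        for r in self.regions:
            if r.end > target_length:
                raise ValueError(f"region {r.name!r} extends beyond the target sequence")

    def find(self, position: int) -> Region | None:
        for r in self.regions:
            if position in r:
                return r
        return None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionSet":
        """Read a region table (columns: name, start, end, domain).

        Coordinates are 1-based inclusive target positions — unlike BED
        proper, which is 0-based half-open.
        """
        df = pd.read_csv(path, sep="\t")
        missing = {"name", "start", "end"} - set(df.columns)
        if missing:
            raise ValueError(f"region table missing columns: {sorted(missing)}")
        regions = [
            Region(
                name=str(row["name"]),
                start=int(row["start"]),
                end=int(row["end"]),
                domain=str(row.get("domain", "none")),
            )
            for _, row in df.iterrows()
        ]
        return cls(regions)


@dataclass
class DesignVariant:
    """A named variant sequence produced by applying consensus calls."""

    name: str
    base_sequence: str
    substitutions: list[ConsensusCall]
    variant_sequence: str
    percent_identity: float
    percent_similarity: float
    similarity_groups: tuple[str, ...] = SIMILARITY_GROUPS

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.variant_sequence), 60):
                fh.write(self.variant_sequence[i : i + 60] + "\n")


def _load_alignment(msa) -> MultipleSeqAlignment:
    if isinstance(msa, MultipleSeqAlignment):
        return msa
    return AlignIO.read(str(msa), "fasta")


def build_profile(msa, target_id: str, denominator: str = "all") -> MSAProfile:
    """Column frequency profile of an alignment, in target coordinates.

    Columns where the target row carries a gap are dropped.  Non-standard
    letters are pooled in an 'X' bin with a warning.
    """
    aln = _load_alignment(msa)
    if denominator not in ("all", "nongap"):
        raise ValueError("denominator must be 'all' or 'nongap'")
    ids = [rec.id for rec in aln]
    if target_id not in ids:
        raise ValueError(f"target {target_id!r} not found in the alignment")
    lengths = {len(rec.seq) for rec in aln}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: rows differ in length")

    matrix = np.array([list(str(rec.seq).upper()) for rec in aln])
    target_row = matrix[ids.index(target_id)]
    keep = ~np.isin(target_row, list(GAP_CHARS))
    matrix = matrix[:, keep]
    target_seq = "".join(target_row[keep])

    letters = set(matrix.ravel())
    nonstandard = letters - set(AMINO_ACIDS) - GAP_CHARS
    if nonstandard:
        warnings.warn(
            f"non-standard residue letters pooled into '{OTHER}': {sorted(nonstandard)}",
            UserWarning,
            stacklevel=2,
        )

    n_seq = len(aln)
    n_cols = matrix.shape[1]
    counts = pd.DataFrame(
        0.0, index=np.arange(1, n_cols + 1), columns=list(AMINO_ACIDS) + [OTHER]
    )
    gap_counts = np.zeros(n_cols)
    for j in range(n_cols):
        col = matrix[:, j]
        for ch, n in zip(*np.unique(col, return_counts=True)):
            if ch in GAP_CHARS:
                gap_counts[j] += n
            elif ch in AMINO_ACIDS:
                counts.loc[j + 1, ch] += n
            else:
                counts.loc[j + 1, OTHER] += n
    gap_fraction = pd.Series(gap_counts / n_seq, index=counts.index)
    if denominator == "all":
        freqs = counts / n_seq
    else:
        nongap = (n_seq - gap_counts).clip(min=1)
        freqs = counts.div(nongap, axis=0)
    return MSAProfile(
        target_id=target_id,
        target_sequence=target_seq,
        n_sequences=n_seq,
        frequencies=freqs,
        gap_fraction=gap_fraction,
        denominator=denominator,
    )


def call_consensus(
    profile: MSAProfile, f_min: float = 0.20, delta: float = 0.10
) -> list[ConsensusCall]:
    """Call consensus substitutions under the frequency rule.

    A call is emitted at position p iff the modal non-gap residue c differs
    from the target residue, f(c) > f_min (strict), and
    f(c) - f(target) >= delta (inclusive).  Ties for the mode suppress the
    call.  The 'X' (non-standard) bin never nominates a consensus residue.
    """
    if not (0.0 <= f_min <= 1.0 and 0.0 <= delta <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    calls: list[ConsensusCall] = []
    freq_aa = profile.frequencies[list(AMINO_ACIDS)]
    for pos, row in freq_aa.iterrows():
        target_aa = profile.target_sequence[pos - 1]
        order = row.sort_values(ascending=False)
        mode_aa, f_mode = order.index[0], float(order.iloc[0])
        if len(order) > 1 and float(order.iloc[1]) == f_mode:
            continue  # modal tie: consensus undefined
        if mode_aa == target_aa:
            continue
        f_target = float(row.get(target_aa, 0.0))
        if f_mode > f_min and f_mode - f_target >= delta:
            calls.append(
                ConsensusCall(
                    position=int(pos),
                    target_aa=target_aa,
                    consensus_aa=mode_aa,
                    f_consensus=f_mode,
                    f_target=f_target,
                    f_min=f_min,
                    delta=delta,
                )
            )
    return calls


def restrict_to_regions(calls: list[ConsensusCall], regions: RegionSet) -> list[ConsensusCall]:
    """Keep only calls inside a declared region; tag them with the domain."""
    out = []
    for call in calls:
        region = regions.find(call.position)
        if region is not None:
            out.append(
                ConsensusCall(
                    position=call.position,
                    target_aa=call.target_aa,
                    consensus_aa=call.consensus_aa,
                    f_consensus=call.f_consensus,
                    f_target=call.f_target,
                    f_min=call.f_min,
                    delta=call.delta,
                    in_region=True,
                    domain=region.domain,
                )
            )
    return out


def apply_design(base_sequence: str, calls: list[ConsensusCall], name: str) -> DesignVariant:
    """Apply consensus calls to a base sequence and score identity/similarity.

    percent_identity = 100 * (L - n_subs) / L; a substitution also counts
    as similar when the two residues share a similarity group.
    """
    seq = list(base_sequence)
    length = len(seq)
    seen = set()
    for call in calls:
        if call.position in seen:
            raise ValueError(f"duplicate call at position {call.position}")
        seen.add(call.position)
        if call.position < 1 or call.position > length:
            raise ValueError(f"call position {call.position} outside the base sequence")
        if seq[call.position - 1] != call.target_aa:
            raise ValueError(
                f"call at position {call.position} expects {call.target_aa} but base has "
                f"{seq[call.position - 1]} (stale coordinates?)"
            )
        seq[call.position - 1] = call.consensus_aa
    variant = "".join(seq)
    n_sub = len(calls)
    n_dissimilar = sum(
        1
        for c in calls
        if _GROUP_OF.get(c.target_aa) != _GROUP_OF.get(c.consensus_aa)
    )
    return DesignVariant(
        name=name,
        base_sequence=base_sequence,
        substitutions=sorted(calls, key=lambda c: c.position),
        variant_sequence=variant,
        percent_identity=100.0 * (length - n_sub) / length,
        percent_similarity=100.0 * (length - n_dissimilar) / length,
    )


def calls_to_tsv(calls: list[ConsensusCall], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "position": [c.position for c in calls],
            "wt": [c.target_aa for c in calls],
            "mut": [c.consensus_aa for c in calls],
            "f_cons": [c.f_consensus for c in calls],
            "f_wt": [c.f_target for c in calls],
            "region": [c.in_region for c in calls],
            "domain": [c.domain for c in calls],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path, f_min: float = 0.20, delta: float = 0.10):
    df = pd.read_csv(path, sep="\t")
    return [
        ConsensusCall(
            position=int(r["position"]),
            target_aa=str(r["wt"]),
            consensus_aa=str(r["mut"]),
            f_consensus=float(r["f_cons"]),
            f_target=float(r["f_wt"]),
            f_min=f_min,
            delta=delta,
            in_region=bool(r.get("region", False)),
            domain=str(r.get("domain", "none")),
        )
        for _, r in df.iterrows()
    ]
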