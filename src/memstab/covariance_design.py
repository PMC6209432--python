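"""Amino-acid covariance scoring, contact validation, covariant designs.

Covarying alignment columns are a proxy for physically contacting residue
pairs.  The default scorer is mutual information with average-product
correction (MI-APC) computed on sequence-reweighted counts (weights
1/n_neighbors at an 80% identity threshold, the standard correction for
phylogenetic bias); a mean-field DCA scorer (one-hot covariance inversion
with ridge regularization, Frobenius-norm couplings, APC) and an importer
for externally computed score tables are also provided.  Scored pairs are
restricted to a minimum sequence separation (default 5) to remove trivial
neighbor signal.

Top-ranked pairs are validated against a structural contact map (minimum
heavy-atom distance over all chain pairs of the reference structure, which
captures inter-subunit contacts of a trimer) and pairs beyond the distance
cutoff can be removed as false positives before the final cut.  The
covariant design keeps exactly the consensus calls whose positions occur
in the surviving top pairs — the design is always a subset of its input
calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment, PairwiseAligner

from .msa_consensus import AMINO_ACIDS, GAP_CHARS, ConsensusCall, _load_alignment

__all__ = [
    "CovarianceScoreTable",
    "ContactMap",
    "filter_alignment",
    "score_covariance",
    "read_score_table",
    "write_score_table",
    "build_contact_map",
    "validate_pairs",
    "select_covariant_design",
]

_STATES = list(AMINO_ACIDS) + ["-"]  # non-standard letters are mapped to gap
_STATE_INDEX = {s: i for i, s in enumerate(_STATES)}
_N_STATES = len(_STATES)


@dataclass
class CovarianceScoreTable:
    """Ranked column-pair covariance scores in target coordinates."""

    method: str  # mi_apc | mf_dca | imported
    pairs: pd.DataFrame  # columns: i, j (1-based target positions, i<j), score
    n_sequences: int = 0
    effective_n: float = 0.0

    def __post_init__(self) -> None:
        df = self.pairs
        if not (df["i"] < df["j"]).all():
            raise ValueError("pairs must satisfy i < j")
        if df.duplicated(subset=["i", "j"]).any():
            raise ValueError("duplicate pairs in score table")
        if not np.all(np.isfinite(df["score"])):
            raise ValueError("scores must be finite")

    def top(self, k: int) -> pd.DataFrame:
        return self.pairs.sort_values(
            ["score", "i", "j"], ascending=[False, True, True]
        ).head(k)


@dataclass
class ContactMap:
    """Minimum inter-residue distances of a structure, in target coordinates."""

    source: str
    distances: dict  # (i, j) with i<j -> min distance (Angstrom)
    mapped_positions: set
    unmapped_residues: list = field(default_factory=list)
    distance_cap: float = np.inf  # pairs above the cap are not stored

    def distance(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        d = self.distances.get((i, j))
        if d is not None:
            return d
        if i in self.mapped_positions and j in self.mapped_positions:
            return np.inf  # mapped but farther than the cap
        return np.nan  # unmappable

    def is_mapped(self, i: int, j: int) -> bool:
        return i in self.mapped_positions and j in self.mapped_positions


def _alignment_to_matrix(aln: MultipleSeqAlignment) -> tuple[np.ndarray, list[str]]:
    matrix = np.array([list(str(rec.seq).upper()) for rec in aln])
    return matrix, [rec.id for rec in aln]


def filter_alignment(msa, target_id: str, min_coverage: float = 0.70):
    """Drop rows covering less than ``min_coverage`` of the target sequence.

    Coverage of a row is the fraction of target (non-gap) columns where the
    row is also non-gap.  Returns (filtered_alignment, n_removed).
    """
    aln = _load_alignment(msa)
    matrix, ids = _alignment_to_matrix(aln)
    if target_id not in ids:
        raise ValueError(f"target {target_id!r} not in alignment")
    target_row = matrix[ids.index(target_id)]
    target_cols = ~np.isin(target_row, list(GAP_CHARS))
    nongap = ~np.isin(matrix[:, target_cols], list(GAP_CHARS))
    coverage = nongap.mean(axis=1)
    keep = coverage >= min_coverage
    keep[ids.index(target_id)] = True  # the target row is never removed
    kept = MultipleSeqAlignment([rec for rec, k in zip(aln, keep) if k])
    return kept, int((~keep).sum())


def sequence_weights(matrix: np.ndarray, identity_threshold: float = 0.8) -> np.ndarray:
    """Standard phylogenetic reweighting: w_i = 1 / #{j : id(i,j) >= theta}."""
    n = matrix.shape[0]
    counts = np.zeros(n)
    for i in range(n):
        ident = (matrix == matrix[i]).mean(axis=1)
        counts[i] = np.sum(ident >= identity_threshold)
    return 1.0 / counts


def _encode(matrix: np.ndarray) -> np.ndarray:
    flat = np.array(
        [_STATE_INDEX.get(c, _STATE_INDEX["-"]) for c in matrix.ravel()], dtype=np.int64
    )
    return flat.reshape(matrix.shape)


def _mi_apc(encoded: np.ndarray, weights: np.ndarray, pseudocount: float = 0.01) -> np.ndarray:
    """Weighted mutual information between all column pairs, APC-corrected."""
    n_seq, n_col = encoded.shape
    neff = weights.sum()
    onehot = np.zeros((n_seq, n_col, _N_STATES))
    onehot[np.arange(n_seq)[:, None], np.arange(n_col)[None, :], encoded] = 1.0
    w = weights / neff
    fi = np.tensordot(w, onehot, axes=(0, 0))  # (n_col, states)
    fi = (1 - pseudocount) * fi + pseudocount / _N_STATES

    mi = np.zeros((n_col, n_col))
    flat = onehot * w[:, None, None]
    for a in range(n_col):
        # joint frequencies of column a with all columns at once
        fij = np.tensordot(flat[:, a, :], onehot, axes=(0, 0))  # (states, n_col, states)
        fij = (1 - pseudocount) * fij + pseudocount / _N_STATES**2
        denom = fi[a][:, None, None] * fi[None, :, :]
        mi[a] = np.sum(fij * np.log(fij / denom), axis=(0, 2))
    np.fill_diagonal(mi, 0.0)
    mi = 0.5 * (mi + mi.T)

    # average-product correction
    col_mean = mi.sum(axis=0) / (n_col - 1)
    overall = mi.sum() / (n_col * (n_col - 1))
    apc = np.outer(col_mean, col_mean) / overall
    return mi - apc


def _mf_dca(encoded: np.ndarray, weights: np.ndarray, pseudocount: float = 0.5,
            ridge: float = 1e-4) -> np.ndarray:
    """Mean-field DCA: ridge-regularized inverse of the one-hot covariance."""
    n_seq, n_col = encoded.shape
    q = _N_STATES - 1  # drop the gap state per column for invertibility
    neff = weights.sum()
    onehot = np.zeros((n_seq, n_col, q))
    mask = encoded < q
    idx_seq, idx_col = np.nonzero(mask)
    onehot[idx_seq, idx_col, encoded[idx_seq, idx_col]] = 1.0
    w = weights / neff
    fi = np.tensordot(w, onehot, axes=(0, 0))
    X = onehot.reshape(n_seq, n_col * q)
    fij = X.T @ (X * w[:, None])
    fi_flat = fi.reshape(-1)
    lam = pseudocount
    fij = (1 - lam) * fij + lam / (q * q)
    fi_flat = (1 - lam) * fi_flat + lam / q
    C = fij - np.outer(fi_flat, fi_flat)
    C += ridge * np.eye(n_col * q)
    J = -np.linalg.inv(C)
    scores = np.zeros((n_col, n_col))
    for a in range(n_col):
        for b in range(a + 1, n_col):
            block = J[a * q : (a + 1) * q, b * q : (b + 1) * q]
            block = block - block.mean(axis=0, keepdims=True) - block.mean(
                axis=1, keepdims=True
            ) + block.mean()
            scores[a, b] = scores[b, a] = np.linalg.norm(block)
    col_mean = scores.sum(axis=0) / (n_col - 1)
    overall = scores.sum() / (n_col * (n_col - 1))
    return scores - np.outer(col_mean, col_mean) / overall


def score_covariance(
    msa,
    target_id: str,
    method: str = "mi_apc",
    weighting_identity: float = 0.8,
    min_separation: int = 5,
) -> CovarianceScoreTable:
    """Score covariance between target-mapped column pairs of an alignment.

    Pairs closer than ``min_separation`` residues in the target sequence
    are excluded, and pairs where either column has fewer than two non-gap
    states are skipped.
    """
    aln = _load_alignment(msa)
    if len(aln) < 2:
        raise ValueError("cannot score covariance on a single-row alignment")
    matrix, ids = _alignment_to_matrix(aln)
    if target_id not in ids:
        raise ValueError(f"target {target_id!r} not in alignment")
    target_row = matrix[ids.index(target_id)]
    keep = ~np.isin(target_row, list(GAP_CHARS))
    matrix = matrix[:, keep]
    positions = np.arange(1, keep.sum() + 1)

    weights = sequence_weights(matrix, weighting_identity)
    encoded = _encode(matrix)
    if method == "mi_apc":
        scores = _mi_apc(encoded, weights)
    elif method == "mf_dca":
        scores = _mf_dca(encoded, weights)
    else:
        raise ValueError("method must be 'mi_apc' or 'mf_dca'")

    gap_idx = _STATE_INDEX["-"]
    informative = np.array(
        [len(set(encoded[:, c]) - {gap_idx}) >= 2 for c in range(encoded.shape[1])]
    )
    rows = []
    n_col = encoded.shape[1]
    for a in range(n_col):
        if not informative[a]:
            continue
        for b in range(a + 1, n_col):
            if not informative[b]:
                continue
            if positions[b] - positions[a] < min_separation:
                continue
            rows.append((int(positions[a]), int(positions[b]), float(scores[a, b])))
    pairs = pd.DataFrame(rows, columns=["i", "j", "score"])
    return CovarianceScoreTable(
        method=method,
        pairs=pairs,
        n_sequences=matrix.shape[0],
        effective_n=float(weights.sum()),
    )


def read_score_table(path: str | Path, method: str = "imported") -> CovarianceScoreTable:
    """Import an externally computed score table (CSV: i, A_i, j, A_j, score)."""
    df = pd.read_csv(path)
    missing = {"i", "j", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    ij = df[["i", "j"]].to_numpy()
    lo, hi = ij.min(axis=1), ij.max(axis=1)
    pairs = pd.DataFrame({"i": lo, "j": hi, "score": df["score"].to_numpy()})
    return CovarianceScoreTable(method=method, pairs=pairs)


def write_score_table(table: CovarianceScoreTable, path: str | Path,
                      target_sequence: str | None = None) -> None:
    """Write scores in the external-server CSV dialect (i, A_i, j, A_j, score)."""
    df = table.pairs.copy()
    if target_sequence is not None:
        df["A_i"] = [target_sequence[i - 1] for i in df["i"]]
        df["A_j"] = [target_sequence[j - 1] for j in df["j"]]
    else:
        df["A_i"] = "-"
        df["A_j"] = "-"
    df[["i", "A_i", "j", "A_j", "score"]].to_csv(path, index=False)


def _map_by_alignment(structure_seq: str, resnums: list[int], target_seq: str) -> dict[int, int]:
    """Fallback structure->target mapping by global pairwise alignment."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    alignment = aligner.align(structure_seq, target_seq)[0]
    mapping: dict[int, int] = {}
    for (s_start, s_end), (t_start, t_end) in zip(*alignment.aligned):
        for off in range(s_end - s_start):
            mapping[resnums[s_start + off]] = t_start + off + 1
    return mapping


_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def build_contact_map(
    structure_path: str | Path,
    chain_set: set[str] | None = None,
    target_mapping: dict[str, int] | str = "align",
    target_sequence: str | None = None,
    heavy_atoms: bool = True,
    distance_cap: float = 12.0,
) -> ContactMap:
    """Minimum inter-atomic distance per target-position pair from a PDB file.

    The minimum is taken over all atoms (heavy atoms by default; set
    ``heavy_atoms=False`` for Calpha-only) and over *all* chain pairs, so
    inter-subunit contacts of an oligomer are captured.  ``target_mapping``
    is either a per-chain residue-number offset table
    ({chain: offset} with target_pos = resnum + offset) or ``"align"``, in
    which case each chain's sequence is globally aligned to
    ``target_sequence``.  Residues that cannot be mapped are reported in
    ``unmapped_residues``, never silently dropped.  Pairs farther apart
    than ``distance_cap`` are not stored (their distance reads +inf).
    """
    import gemmi

    structure = gemmi.read_structure(str(structure_path))
    structure.setup_entities()
    model = structure[0]

    coords: list[np.ndarray] = []
    residue_pos: list[int] = []
    unmapped: list[tuple[str, int]] = []

    for chain in model:
        if chain_set is not None and chain.name not in chain_set:
            continue
        if target_mapping == "align":
            if target_sequence is None:
                raise ValueError("alignment-based mapping requires target_sequence")
            seq, resnums = "", []
            for res in chain:
                one = _AA3TO1.get(res.name)
                if one:
                    seq += one
                    resnums.append(res.seqid.num)
            mapping = _map_by_alignment(seq, resnums, target_sequence)
        for res in chain:
            if res.name not in _AA3TO1:
                continue
            if target_mapping == "align":
                pos = mapping.get(res.seqid.num)
            else:
                offset = target_mapping.get(chain.name)
                pos = res.seqid.num + offset if offset is not None else None
            if pos is None:
                unmapped.append((chain.name, res.seqid.num))
                continue
            for atom in res:
                if atom.altloc not in ("", "\x00", "A"):
                    continue
                if atom.element.is_hydrogen:
                    continue
                if not heavy_atoms and atom.name != "CA":
                    continue
                coords.append(np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
                residue_pos.append(pos)

    if unmapped:
        warnings.warn(
            f"{len(unmapped)} residues could not be mapped to the target", UserWarning,
            stacklevel=2,
        )
    if not coords:
        raise ValueError("no mappable atoms found in the structure")

    xyz = np.vstack(coords)
    pos_arr = np.array(residue_pos)
    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    sparse = tree.sparse_distance_matrix(tree, max_distance=distance_cap, output_type="coo_matrix")
    distances: dict[tuple[int, int], float] = {}
    for a, b, d in zip(sparse.row, sparse.col, sparse.data):
        pi, pj = int(pos_arr[a]), int(pos_arr[b])
        if pi == pj:
            continue
        key = (pi, pj) if pi < pj else (pj, pi)
        if d < distances.get(key, np.inf):
            distances[key] = float(d)
    return ContactMap(
        source=str(structure_path),
        distances=distances,
        mapped_positions=set(pos_arr.tolist()),
        unmapped_residues=unmapped,
        distance_cap=distance_cap,
    )


def validate_pairs(
    scores: CovarianceScoreTable,
    contact_map: ContactMap,
    cutoff_A: float = 6.0,
    top_k: int = 100,
) -> dict:
    """Precision of the top covariance pairs against a structural contact map.

    precision = fraction of the top_k *mapped* pairs with minimum distance
    below ``cutoff_A``; unmapped pairs are counted separately and excluded
    from the denominator.  Per-pair verdicts list the pairs that failed the
    contact check (candidates for false-positive removal).
    """
    if top_k > len(scores.pairs):
        raise ValueError("top_k exceeds the number of scored pairs")
    ranked = scores.pairs.sort_values(
        ["score", "i", "j"], ascending=[False, True, True]
    )
    verdicts = []
    n_contact = n_mapped = n_unmapped = 0
    for row in ranked.itertuples(index=False):
        if n_mapped + n_unmapped >= top_k:
            break
        i, j = int(row.i), int(row.j)
        if not contact_map.is_mapped(i, j):
            n_unmapped += 1
            verdicts.append({"i": i, "j": j, "score": row.score, "verdict": "unmapped"})
            continue
        d = contact_map.distance(i, j)
        n_mapped += 1
        in_contact = d < cutoff_A
        n_contact += int(in_contact)
        verdicts.append(
            {
                "i": i,
                "j": j,
                "score": row.score,
                "distance_A": None if np.isinf(d) else d,
                "verdict": "contact" if in_contact else "no_contact",
            }
        )
    if n_mapped == 0:
        raise ValueError("no scored pair could be mapped onto the structure")
    return {
        "precision": n_contact / n_mapped,
        "n_contact": n_contact,
        "n_mapped": n_mapped,
        "n_unmapped": n_unmapped,
        "cutoff_A": cutoff_A,
        "top_k": top_k,
        "verdicts": verdicts,
        "removal_list": [
            (v["i"], v["j"]) for v in verdicts if v["verdict"] == "no_contact"
        ],
    }


def select_covariant_design(
    consensus_calls: list[ConsensusCall],
    scores: CovarianceScoreTable,
    top_pairs: int = 100,
    contact_filter: list[tuple[int, int]] | None = None,
    remove_before_cut: bool = True,
) -> list[ConsensusCall]:
    """Restrict consensus calls to positions in the top covariant pairs.

    ``contact_filter`` is an optional list of (i, j) pairs flagged as
    non-contacts to be removed; by default they are removed *before* the
    top-``top_pairs`` cut (``remove_before_cut=False`` removes them after).
    The result is always a subset of the input calls, with call identities
    unchanged.
    """
    flagged = {tuple(sorted(p)) for p in (contact_filter or [])}
    ranked = scores.pairs.sort_values(
        ["score", "i", "j"], ascending=[False, True, True]
    )
    if remove_before_cut and flagged:
        mask = [
            (int(r.i), int(r.j)) not in flagged for r in ranked.itertuples(index=False)
        ]
        ranked = ranked[mask]
    top = ranked.head(top_pairs)
    if not remove_before_cut and flagged:
        mask = [(int(r.i), int(r.j)) not in flagged for r in top.itertuples(index=False)]
        top = top[mask]
    covariant_positions = set(top["i"]).union(top["j"])
    return [c for c in consensus_calls if c.position in covariant_positions]
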