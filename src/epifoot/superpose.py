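"""Rigid-body CA superposition: residue pairing, Kabsch fit, RMSD, TM-score.

Superposition is CA-only, which is the standard granularity for
domain-level bound-vs-free comparisons.  The TM-score is evaluated on a
fixed residue correspondence (no iterative fragment search):

    TM = (1 / L_target) * sum_i 1 / (1 + (d_i / d0)^2),
    d0 = 1.24 * (L_target - 15)^(1/3) - 1.8

with d_i the post-superposition CA–CA distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Residue, Structure

__all__ = [
    "ResiduePairing",
    "Superposition",
    "pair_residues",
    "kabsch_superpose",
    "tm_score",
    "DegenerateGeometryError",
]


class DegenerateGeometryError(ValueError):
    """Fewer than 3 pairs, or a collinear/degenerate point set."""


@dataclass
class ResiduePairing:
    pairs: list[tuple[Residue, Residue]]
    source: str  # by_number | by_alignment

    def __post_init__(self) -> None:
        if not self.pairs:
            raise DegenerateGeometryError("empty residue pairing")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def ca_coords(self) -> tuple[np.ndarray, np.ndarray]:
        xa = np.array([ra.atom("CA").xyz for ra, _ in self.pairs])
        xb = np.array([rb.atom("CA").xyz for _, rb in self.pairs])
        return xa, xb


@dataclass
class Superposition:
    rotation: np.ndarray  # 3x3, proper
    translation: np.ndarray  # 3-vector, maps B onto A: x' = R @ x + t
    rmsd: float
    n_pairs: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _ca_residues(structure: Structure) -> list[Residue]:
    return [r for r in structure.residues() if not r.is_hetero and r.atom("CA") is not None]


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def sequence_of(residues: list[Residue]) -> str:
    return "".join(THREE_TO_ONE.get(r.res_name, "X") for r in residues)


def _align_pair(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Global alignment (BLOSUM62, open 10 / extend 0.5) -> index pairs."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a.replace("X", "A"), seq_b.replace("X", "A"))[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def pair_residues(
    a: Structure,
    b: Structure,
    mode: str = "by_number",
    alignment: list[tuple[int, int]] | None = None,
) -> ResiduePairing:
    """Pair CA-bearing residues of two structures.

    ``by_number`` matches on (seq_id, insertion_code); ``by_alignment``
    maps through gapless columns of a global sequence alignment (computed
    internally unless explicit index ``alignment`` pairs are supplied).
    """
    res_a, res_b = _ca_residues(a), _ca_residues(b)
    if not res_a or not res_b:
        raise DegenerateGeometryError("a structure has no CA atoms")
    if mode == "by_number":
        index_b = {(r.seq_id, r.insertion_code): r for r in res_b}
        pairs = [
            (ra, index_b[(ra.seq_id, ra.insertion_code)])
            for ra in res_a
            if (ra.seq_id, ra.insertion_code) in index_b
        ]
    elif mode == "by_alignment":
        idx = alignment if alignment is not None else _align_pair(sequence_of(res_a), sequence_of(res_b))
        pairs = [(res_a[i], res_b[j]) for i, j in idx if i < len(res_a) and j < len(res_b)]
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")
    if len(pairs) < 3:
        raise DegenerateGeometryError(f"only {len(pairs)} residue pairs; need >= 3")
    return ResiduePairing(pairs=pairs, source=mode)


def kabsch_superpose(pairing: ResiduePairing) -> Superposition:
    """Least-squares optimal rigid transform of B onto A over paired CAs.

    SVD-based with reflection correction (the smallest singular axis is
    negated when the determinant is negative), so the rotation is proper.
    """
    xa, xb = pairing.ca_coords()
    if len(xa) < 3:
        raise DegenerateGeometryError("need >= 3 CA pairs")
    ca_, cb_ = xa.mean(axis=0), xb.mean(axis=0)
    pa, pb = xa - ca_, xb - cb_
    if np.linalg.matrix_rank(pa, tol=1e-8) < 2 or np.linalg.matrix_rank(pb, tol=1e-8) < 2:
        raise DegenerateGeometryError("collinear CA point set; rotation is underdetermined")
    h = pb.T @ pa
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ca_ - rot @ cb_
    diff = pa - pb @ rot.T
    rmsd = float(np.sqrt((diff**2).sum() / len(xa)))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_pairs=len(xa))


def tm_score(pairing: ResiduePairing, superposition: Superposition, l_target: int | None = None) -> float:
    """Length-normalised structural similarity of the fixed pairing in (0, 1]."""
    if l_target is None:
        l_target = pairing.n_pairs
    if l_target < 16:
        raise ValueError(f"l_target={l_target} < 16: d0 normalisation undefined")
    d0 = 1.24 * (l_target - 15) ** (1.0 / 3.0) - 1.8
    xa, xb = pairing.ca_coords()
    d = np.linalg.norm(xa - superposition.transform(xb), axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_target)
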