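"""Interface footprints and geometric contact classification.

A footprint is the one-sided buried surface of a *target* chain group
(the antigen) against a *binder* group (e.g. Fab heavy + light chains):
per residue, ΔSASA = SASA(target alone) − SASA(target in complex),
clamped at zero.  Buried area is partitioned among binder chains by
attributing each target atom's loss to the chain owning the nearest
binder atom, so the per-chain attribution sums to the total exactly.

Contacts are classified from heavy-atom geometry alone (appropriate for
moderate-resolution crystal structures without modelled hydrogens):
hydrogen bonds from an embedded donor/acceptor chemistry table, pi
stacking and cation-pi from aromatic ring centroids, hydrophobic
contacts from apolar carbon proximity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .sasa import SASAParams, compute_sasa
from .structure import Residue, Structure, StructureError, select

__all__ = [
    "FootprintResult",
    "ContactCriteria",
    "Contact",
    "AtomRef",
    "compute_footprint",
    "classify_contacts",
    "footprint_report",
]

# ----------------------------------------------------------------------------
# heavy-atom hydrogen-bond chemistry (donor/acceptor capability per atom name)

BACKBONE_DONORS = {"N"}      # except proline
BACKBONE_ACCEPTORS = {"O", "OXT"}

SIDECHAIN_DONORS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}

SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
    "CYS": {"SG"},
}

AROMATIC_RINGS: dict[str, list[tuple[str, ...]]] = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [
        ("CG", "CD1", "CD2", "NE1", "CE2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ],
}

CATION_ATOMS: dict[str, set[str]] = {"LYS": {"NZ"}, "ARG": {"CZ"}}

# carbons whose covalent neighbours are all carbon/hydrogen
APOLAR_CARBONS: dict[str, set[str]] = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "TRP": {"CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "PRO": {"CB", "CG"},
    "LYS": {"CB", "CG", "CD"},
    "ARG": {"CB", "CG"},
    "GLN": {"CB", "CG"},
    "GLU": {"CB", "CG"},
    "THR": {"CG2"},
    "HIS": {"CB"},
    "ASP": {"CB"},
    "ASN": {"CB"},
    "CYS": {"CB"},
}

_COVALENT_MAX = 1.9  # Å, heavy-atom bond detection within a residue


@dataclass(frozen=True)
class ContactCriteria:
    hbond_da_max: float = 3.5
    hbond_angle_min: float = 90.0   # degrees at the donor, heavy-atom proxy
    hydrophobic_cc_max: float = 4.5
    pi_centroid_max: float = 5.5
    pi_angle_parallel_max: float = 30.0
    cation_pi_max: float = 6.0

    def __post_init__(self) -> None:
        for name in ("hbond_da_max", "hydrophobic_cc_max", "pi_centroid_max", "cation_pi_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("hbond_angle_min", "pi_angle_parallel_max"):
            if not (0.0 <= getattr(self, name) <= 180.0):
                raise ValueError(f"{name} must be in [0, 180] degrees")


@dataclass(frozen=True)
class AtomRef:
    """An atom, or an aromatic ring centroid, on one side of a contact."""

    chain_id: str
    seq_id: int
    res_name: str
    atom: str   # atom name, or 'ring(CG-CD1-...)' for a centroid

    def label(self) -> str:
        return f"{self.chain_id}/{self.res_name}{self.seq_id}/{self.atom}"


@dataclass(frozen=True)
class Contact:
    kind: str  # hbond | hydrophobic | pi_stack | cation_pi
    partner_a: AtomRef  # binder / group_a side
    partner_b: AtomRef  # target / group_b side
    distance: float
    angle: float | None = None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "partner_a": self.partner_a.label(),
            "partner_b": self.partner_b.label(),
            "distance": round(self.distance, 3),
            "angle": None if self.angle is None else round(self.angle, 1),
        }


@dataclass
class FootprintResult:
    target_group: frozenset[str]
    binder_group: frozenset[str]
    per_residue_buried: dict[tuple[str, int, str], float]
    epitope_residues: set[tuple[str, int, str]]
    partition: dict[str, float]
    total_buried: float
    epitope_threshold: float
    residue_names: dict[tuple[str, int, str], str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def epitope_seq_ids(self) -> set[int]:
        return {seq_id for (_, seq_id, _) in self.epitope_residues}


def _group_structure(structure: Structure, group: set[str], include_hetero: bool) -> Structure:
    return select(
        structure,
        chain_ids=group,
        exclude_waters=True,
        exclude_hetero=not include_hetero,
    )


def compute_footprint(
    structure: Structure,
    target_group: set[str] | list[str],
    binder_group: set[str] | list[str],
    sasa_params: SASAParams | None = None,
    epitope_threshold: float = 1.0,
    partition_mode: str = "nearest_chain",
    include_hetero: bool = False,
) -> FootprintResult:
    """One-sided buried-surface footprint of ``target_group`` against ``binder_group``.

    Waters are always excluded; non-polymer heteroatoms (e.g. glycans) are
    excluded unless ``include_hetero`` so the footprint describes
    protein–protein burial.
    """
    target_group = frozenset(target_group)
    binder_group = frozenset(binder_group)
    if not target_group or not binder_group:
        raise StructureError("target and binder chain groups must be non-empty")
    if target_group & binder_group:
        raise StructureError(f"chain groups overlap: {sorted(target_group & binder_group)}")
    if partition_mode != "nearest_chain":
        raise ValueError(f"unknown partition_mode {partition_mode!r}")
    sasa_params = sasa_params or SASAParams()

    target = _group_structure(structure, set(target_group), include_hetero)
    binder = _group_structure(structure, set(binder_group), include_hetero)
    complex_st = Structure(
        id=structure.id, chains=list(target.chains) + list(binder.chains)
    )

    alone = compute_sasa(target, sasa_params)
    bound = compute_sasa(complex_st, sasa_params)

    # per-atom ΔSASA on the target side, clamped at zero
    per_atom_delta: dict[tuple[tuple[str, int, str], str], float] = {}
    for key, area in alone.per_atom.items():
        per_atom_delta[key] = max(0.0, area - bound.per_atom[key])

    per_residue: dict[tuple[str, int, str], float] = {}
    res_names: dict[tuple[str, int, str], str] = {}
    for res in target.residues():
        res_names[res.key] = res.res_name
    for (rkey, _), d in per_atom_delta.items():
        per_residue[rkey] = per_residue.get(rkey, 0.0) + d

    # nearest-binder-chain attribution of each buried target atom's area
    binder_coords, binder_chain = [], []
    for cid, residues in binder.chains:
        for res in residues:
            for at in res.atoms:
                binder_coords.append(at.coord)
                binder_chain.append(cid)
    tree = cKDTree(np.asarray(binder_coords, float))
    target_atom_coords = {
        (res.key, at.name): at.coord for res in target.residues() for at in res.atoms
    }
    partition = {cid: 0.0 for cid in sorted(binder_group)}
    for key, d in per_atom_delta.items():
        if d <= 0.0:
            continue
        _, j = tree.query(np.asarray(target_atom_coords[key], float))
        partition[binder_chain[int(j)]] += d

    total = float(sum(per_residue.values()))
    warnings = []
    if total == 0.0:
        warnings.append("zero total buried area: chain groups do not touch")
    epitope = {k for k, v in per_residue.items() if v >= epitope_threshold}
    return FootprintResult(
        target_group=target_group,
        binder_group=binder_group,
        per_residue_buried=per_residue,
        epitope_residues=epitope,
        partition=partition,
        total_buried=total,
        epitope_threshold=epitope_threshold,
        residue_names=res_names,
        warnings=warnings,
    )


# ----------------------------------------------------------------------------
# contact classification


def _bonded_antecedents(res: Residue, atom_name: str) -> list[np.ndarray]:
    a = res.atom(atom_name)
    out = []
    for other in res.atoms:
        if other.name == atom_name:
            continue
        if np.linalg.norm(other.xyz - a.xyz) <= _COVALENT_MAX:
            out.append(other.xyz)
    return out


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _donor_ok(res: Residue, donor_name: str, acceptor_xyz: np.ndarray, min_angle: float) -> tuple[bool, float | None]:
    """Heavy-atom proxy: every bonded antecedent X must give angle(X, D, A) >= min."""
    donor = res.atom(donor_name)
    angles = [
        _angle_deg(x - donor.xyz, acceptor_xyz - donor.xyz)
        for x in _bonded_antecedents(res, donor_name)
    ]
    if not angles:
        return True, None
    return (min(angles) >= min_angle), min(angles)


def _donor_atoms(res: Residue) -> list[str]:
    names = set()
    if res.res_name != "PRO" and res.atom("N") is not None:
        names |= BACKBONE_DONORS & {a.name for a in res.atoms}
    names |= SIDECHAIN_DONORS.get(res.res_name, set()) & {a.name for a in res.atoms}
    return sorted(names)


def _acceptor_atoms(res: Residue) -> list[str]:
    present = {a.name for a in res.atoms}
    names = BACKBONE_ACCEPTORS & present
    names |= SIDECHAIN_ACCEPTORS.get(res.res_name, set()) & present
    return sorted(names)


def _rings(res: Residue) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """(label, centroid, unit normal) for each complete aromatic ring."""
    out = []
    for names in AROMATIC_RINGS.get(res.res_name, []):
        atoms = [res.atom(n) for n in names]
        if any(a is None for a in atoms):
            continue
        pts = np.array([a.xyz for a in atoms])
        centroid = pts.mean(axis=0)
        # normal = smallest principal axis of the ring points
        _, _, vt = np.linalg.svd(pts - centroid)
        out.append((f"ring({'-'.join(names)})", centroid, vt[2]))
    return out


def classify_contacts(
    structure: Structure,
    group_a: set[str] | list[str],
    group_b: set[str] | list[str],
    criteria: ContactCriteria | None = None,
) -> list[Contact]:
    """Classify inter-group contacts: hbond, hydrophobic, pi_stack, cation_pi.

    ``group_a`` is conventionally the binder (antibody) side and ``group_b``
    the target (antigen) side; the list is sorted by (kind, distance).
    """
    group_a, group_b = frozenset(group_a), frozenset(group_b)
    if group_a & group_b:
        raise StructureError(f"chain groups overlap: {sorted(group_a & group_b)}")
    criteria = criteria or ContactCriteria()
    sa = _group_structure(structure, set(group_a), include_hetero=False)
    sb = _group_structure(structure, set(group_b), include_hetero=False)
    res_a, res_b = sa.residues(), sb.residues()

    # prune residue pairs by CB/CA proximity before atom-level tests
    max_cut = max(
        criteria.hbond_da_max, criteria.hydrophobic_cc_max,
        criteria.pi_centroid_max, criteria.cation_pi_max,
    )
    cent_a = np.array([np.mean([at.xyz for at in r.atoms], axis=0) for r in res_a])
    cent_b = np.array([np.mean([at.xyz for at in r.atoms], axis=0) for r in res_b])
    pairs = cKDTree(cent_a).query_ball_tree(cKDTree(cent_b), r=max_cut + 8.0)

    contacts: list[Contact] = []
    for ia, blist in enumerate(pairs):
        ra = res_a[ia]
        for ib in blist:
            rb = res_b[ib]
            contacts.extend(_pair_contacts(ra, rb, criteria))
    contacts.sort(key=lambda c: (c.kind, c.distance, c.partner_a.label(), c.partner_b.label()))
    return contacts


def _ref(res: Residue, atom: str) -> AtomRef:
    return AtomRef(res.chain_id, res.seq_id, res.res_name, atom)


def _pair_contacts(ra: Residue, rb: Residue, cr: ContactCriteria) -> list[Contact]:
    out: list[Contact] = []

    # hydrogen bonds, both donor orientations
    for donor_res, acc_res, a_is_donor in ((ra, rb, True), (rb, ra, False)):
        for dn in _donor_atoms(donor_res):
            d_atom = donor_res.atom(dn)
            for an in _acceptor_atoms(acc_res):
                a_atom = acc_res.atom(an)
                dist = float(np.linalg.norm(d_atom.xyz - a_atom.xyz))
                if dist > cr.hbond_da_max:
                    continue
                ok, ang = _donor_ok(donor_res, dn, a_atom.xyz, cr.hbond_angle_min)
                if not ok:
                    continue
                pa = _ref(ra, dn if a_is_donor else an)
                pb = _ref(rb, an if a_is_donor else dn)
                out.append(Contact("hbond", pa, pb, dist, ang))

    # hydrophobic carbon-carbon
    for na in APOLAR_CARBONS.get(ra.res_name, ()):  # noqa: B007
        aa = ra.atom(na)
        if aa is None:
            continue
        for nb in APOLAR_CARBONS.get(rb.res_name, ()):
            ab = rb.atom(nb)
            if ab is None:
                continue
            dist = float(np.linalg.norm(aa.xyz - ab.xyz))
            if dist <= cr.hydrophobic_cc_max:
                out.append(Contact("hydrophobic", _ref(ra, na), _ref(rb, nb), dist))

    rings_a, rings_b = _rings(ra), _rings(rb)

    # pi stacking (near-parallel rings)
    for la, ca, na_ in rings_a:
        for lb, cb, nb_ in rings_b:
            dist = float(np.linalg.norm(ca - cb))
            if dist > cr.pi_centroid_max:
                continue
            ang = _angle_deg(na_, nb_)
            ang = min(ang, 180.0 - ang)
            if ang <= cr.pi_angle_parallel_max:
                out.append(Contact("pi_stack", _ref(ra, la), _ref(rb, lb), dist, ang))

    # cation-pi, both orientations
    for cat_res, ring_res, cat_rings, a_is_cat in (
        (ra, rb, rings_b, True),
        (rb, ra, rings_a, False),
    ):
        for cn in CATION_ATOMS.get(cat_res.res_name, ()):  # noqa: B007
            cat = cat_res.atom(cn)
            if cat is None:
                continue
            for lbl, centroid, _ in cat_rings:
                dist = float(np.linalg.norm(cat.xyz - centroid))
                if dist <= cr.cation_pi_max:
                    pa = _ref(ra, cn) if a_is_cat else _ref(ra, lbl)
                    pb = _ref(rb, lbl) if a_is_cat else _ref(rb, cn)
                    out.append(Contact("cation_pi", pa, pb, dist))
    return out


def footprint_report(footprint: FootprintResult, contacts: list[Contact]) -> dict:
    """JSON-ready report combining per-residue ΔSASA, partition and contacts."""
    rows = [
        {
            "chain": k[0],
            "seq_id": k[1],
            "insertion_code": k[2],
            "res_name": footprint.residue_names.get(k, ""),
            "buried_area": round(v, 3),
            "in_epitope": k in footprint.epitope_residues,
        }
        for k, v in sorted(footprint.per_residue_buried.items())
        if v > 0.0
    ]
    return {
        "target_group": sorted(footprint.target_group),
        "binder_group": sorted(footprint.binder_group),
        "total_buried_area": round(footprint.total_buried, 3),
        "epitope_threshold": footprint.epitope_threshold,
        "partition": {k: round(v, 3) for k, v in sorted(footprint.partition.items())},
        "n_epitope_residues": len(footprint.epitope_residues),
        "residues": rows,
        "contacts": [c.to_dict() for c in contacts],
        "warnings": list(footprint.warnings),
    }


def footprint_from_report(report: dict) -> FootprintResult:
    """Rebuild a FootprintResult from a :func:`footprint_report` document."""
    per_res = {
        (r["chain"], r["seq_id"], r.get("insertion_code", "")): float(r["buried_area"])
        for r in report["residues"]
    }
    names = {
        (r["chain"], r["seq_id"], r.get("insertion_code", "")): r.get("res_name", "")
        for r in report["residues"]
    }
    thr = float(report["epitope_threshold"])
    return FootprintResult(
        target_group=frozenset(report["target_group"]),
        binder_group=frozenset(report["binder_group"]),
        per_residue_buried=per_res,
        epitope_residues={k for k, v in per_res.items() if v >= thr},
        partition={k: float(v) for k, v in report["partition"].items()},
        total_buried=float(report["total_buried_area"]),
        epitope_threshold=thr,
        residue_names=names,
        warnings=list(report.get("warnings", [])),
    )


def report_to_json(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)
        fh.write("\n")
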