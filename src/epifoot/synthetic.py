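"""Deterministic synthetic fixtures for every pipeline stage.

Three generators, all pure functions of their seed and spec:

* two-helix toy complexes with side chains placed by explicit
  internal-coordinate rules to realise planted interface contacts at
  exact target distances (the construction is the oracle for contact
  classification);
* KIR-like multiple sequence alignments with variant tables split
  between epitope and non-epitope positions, plus the expected
  intersection report;
* simulated biolayer-interferometry dilution series written as trace
  CSVs with a manifest.

Toy structures are emitted as standard PDB so the structure reader is
exercised on its real input format rather than an internal shortcut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .interface import ContactCriteria, FootprintResult
from .kinetics import KineticsParams, simulate_trace, write_trace_csv
from .structure import Atom, Residue, Structure, write_pdb
from .variants import MSA

__all__ = [
    "ToyComplexSpec",
    "PlantedContact",
    "make_toy_complex",
    "make_kir_like_msa",
    "make_bli_dataset",
    "make_synthetic_footprint",
]

# ideal backbone internal coordinates (Å, degrees); alpha-helix phi/psi
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O, _A_N_CA_CB = 121.7, 111.2, 116.2, 120.5, 110.5
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


class ConstructionError(ValueError):
    """A planted contact geometry is infeasible for the requested complex."""


@dataclass(frozen=True)
class PlantedContact:
    kind: str  # hbond | hydrophobic | pi_stack | cation_pi
    distance: float


@dataclass(frozen=True)
class ToyComplexSpec:
    n_residues_per_chain: int = 25
    inter_chain_gap: float = 12.0  # CA-to-CA separation between facing residues, Å
    planted_contacts: tuple[PlantedContact, ...] = ()
    seed: int = 1
    criteria: ContactCriteria = field(default_factory=ContactCriteria)

    def __post_init__(self) -> None:
        if self.inter_chain_gap <= 0:
            raise ConstructionError("inter_chain_gap must be > 0")
        cutoffs = {
            "hbond": self.criteria.hbond_da_max,
            "hydrophobic": self.criteria.hydrophobic_cc_max,
            "pi_stack": self.criteria.pi_centroid_max,
            "cation_pi": self.criteria.cation_pi_max,
        }
        for pc in self.planted_contacts:
            if pc.kind not in cutoffs:
                raise ConstructionError(f"unknown contact kind {pc.kind!r}")
            if not (0.5 < pc.distance <= cutoffs[pc.kind]):
                raise ConstructionError(
                    f"planted {pc.kind} distance {pc.distance} outside (0.5, {cutoffs[pc.kind]}]"
                )


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to a-b-c."""
    theta, chi = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc_n = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc_n)
    d_local = np.array(
        [-bond * math.cos(theta), bond * math.sin(theta) * math.cos(chi), bond * math.sin(theta) * math.sin(chi)]
    )
    return c + d_local[0] * bc_n + d_local[1] * m + d_local[2] * n


def _helix_backbone(n_res: int) -> list[dict[str, np.ndarray]]:
    """Ideal alpha-helix N/CA/C/O/CB coordinates, axis rotated onto z."""
    ang = math.radians(_A_N_CA_C)
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    c0 = ca0 + _B_CA_C * np.array([math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0])
    res = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, n_res):
        prev = res[-1]
        n_i = _nerf(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, _PSI)
        ca_i = _nerf(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_i = _nerf(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, _PHI)
        res.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, r in enumerate(res):
        nxt_tor = _PSI + 180.0
        r["O"] = _nerf(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, nxt_tor)
        r["CB"] = _nerf(r["C"], r["N"], r["CA"], _B_CA_CB, _A_N_CA_CB, 122.7)
    # rotate principal CA axis onto z for a predictable layout
    cas = np.array([r["CA"] for r in res])
    center = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - center)
    axis = vt[0]
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(np.dot(axis, z))
    if s < 1e-12:
        rot = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    for r in res:
        for k in r:
            r[k] = rot @ (r[k] - center)
    return res


_ELEMENT = {"N": "N", "O": "O", "S": "S"}


def _element_of(name: str) -> str:
    return _ELEMENT.get(name[0], "C")


_RING6 = ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")  # Trp benzene ring
_PHE_RING = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
_RING_RADIUS = 1.39


def _hexagon(centroid: np.ndarray, normal: np.ndarray) -> list[np.ndarray]:
    normal = normal / np.linalg.norm(normal)
    ref = np.array([0.0, 0.0, 1.0]) if abs(normal[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return [
        centroid + _RING_RADIUS * (math.cos(a) * e1 + math.sin(a) * e2)
        for a in (k * math.pi / 3.0 for k in range(6))
    ]


def _plant_device(
    kind: str,
    d: float,
    ca_a: np.ndarray,
    ca_b: np.ndarray,
    gap: float,
) -> tuple[str, dict[str, np.ndarray], str, dict[str, np.ndarray], tuple[str, str]]:
    """Side-chain atoms for one planted contact across the chain gap.

    Returns (resname_a, atoms_a, resname_b, atoms_b, (atom_label_a, atom_label_b)).
    All device atoms lie on (or around) the CA_A -> CA_B axis; the
    interacting atoms are placed at exactly the target separation.
    """
    u = (ca_b - ca_a) / np.linalg.norm(ca_b - ca_a)
    if kind == "hbond":
        # Ser OG donor -> Asp OD1 acceptor, collinear so the donor-angle
        # proxy is exactly 180 degrees
        reach = 2.94 + d
        if reach > gap - 1.5:
            raise ConstructionError(f"hbond at {d} Å does not fit a {gap} Å gap")
        og = ca_a + (1.53 + 1.41) * u
        od1 = og + d * u
        return (
            "SER", {"CB": ca_a + 1.53 * u, "OG": og},
            "ASP", {"CB": ca_b - 1.53 * u, "CG": od1 + 1.25 * u, "OD1": od1},
            ("OG", "OD1"),
        )
    if kind == "hydrophobic":
        cd1_a = ca_a + 4.26 * u
        if 4.26 + d > gap - 1.5:
            raise ConstructionError(f"hydrophobic at {d} Å does not fit a {gap} Å gap")
        return (
            "LEU", {"CB": ca_a + 1.53 * u, "CG": ca_a + 2.83 * u, "CD1": cd1_a},
            "LEU", {"CB": ca_b - 1.53 * u, "CG": ca_b - 2.83 * u, "CD1": cd1_a + d * u},
            ("CD1", "CD1"),
        )
    if kind == "cation_pi":
        nz = ca_a + 3.53 * u
        centroid = nz + d * u
        if 3.53 + d > gap - 1.5:
            raise ConstructionError(f"cation_pi at {d} Å does not fit a {gap} Å gap")
        ring = dict(zip(_RING6, _hexagon(centroid, u)))
        ring["CB"] = ca_b - 1.53 * u
        return ("LYS", {"CB": ca_a + 1.53 * u, "NZ": nz}, "TRP", ring, ("NZ", f"ring({'-'.join(_RING6)})"))
    if kind == "pi_stack":
        cen_a = ca_a + 3.5 * u
        cen_b = cen_a + d * u
        if 3.5 + d > gap - 1.5:
            raise ConstructionError(f"pi_stack at {d} Å does not fit a {gap} Å gap")
        ring_a = dict(zip(_PHE_RING, _hexagon(cen_a, u)))
        ring_a["CB"] = ca_a + 1.53 * u
        ring_b = dict(zip(_PHE_RING, _hexagon(cen_b, u)))
        ring_b["CB"] = ca_b - 1.53 * u
        lbl = f"ring({'-'.join(_PHE_RING)})"
        return ("PHE", ring_a, "PHE", ring_b, (lbl, lbl))
    raise ConstructionError(f"unknown contact kind {kind!r}")


def make_toy_complex(spec: ToyComplexSpec, out_path: str | None = None) -> tuple[Structure, list[dict]]:
    """Two-helix complex (chains A and B) with planted interface contacts.

    Returns the structure and a machine-readable ground-truth contact list
    (kind, chain/residue pair, exact distance).  With ``out_path`` the
    structure is also written as PDB.
    """
    n = spec.n_residues_per_chain
    devices = list(spec.planted_contacts)
    spacing = 6  # residues between devices: keeps them outside each other's cutoffs
    first = 4
    if devices and first + spacing * (len(devices) - 1) > n - 3:
        raise ConstructionError(
            f"{len(devices)} planted contacts do not fit in {n} residues per chain"
        )
    backbone = _helix_backbone(n)
    offset = np.array([spec.inter_chain_gap, 0.0, 0.0])

    seq: dict[int, tuple[str, dict, str, dict, tuple[str, str]]] = {}
    truth: list[dict] = []
    for k, pc in enumerate(devices):
        i = first + spacing * k
        ca_a = backbone[i]["CA"]
        ca_b = ca_a + offset
        device = _plant_device(pc.kind, pc.distance, ca_a, ca_b, spec.inter_chain_gap)
        seq[i] = device
        truth.append(
            {
                "kind": pc.kind,
                "chain_a": "A",
                "res_a": i + 1,
                "res_name_a": device[0],
                "atom_a": device[4][0],
                "chain_b": "B",
                "res_b": i + 1,
                "res_name_b": device[2],
                "atom_b": device[4][1],
                "distance": pc.distance,
            }
        )

    serial = [0]

    def _mk_res(chain_id: str, i: int, name: str, coords: dict[str, np.ndarray]) -> Residue:
        atoms = []
        for aname, xyz in coords.items():
            serial[0] += 1
            atoms.append(
                Atom(
                    serial=serial[0],
                    name=aname,
                    element=_element_of(aname),
                    coord=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                )
            )
        return Residue(chain_id=chain_id, seq_id=i + 1, res_name=name, atoms=tuple(atoms))

    # residues flanking a device become glycine so their CB atoms cannot
    # wander into a planted contact's cutoff shell
    flank = {i + di for i in seq for di in (-2, -1, 1, 2)} - set(seq)

    chain_a, chain_b = [], []
    for i, bb in enumerate(backbone):
        coords_a = {k: v for k, v in bb.items()}
        coords_b = {k: v + offset for k, v in bb.items()}
        name_a = name_b = "ALA"
        if i in flank:
            name_a = name_b = "GLY"
            coords_a.pop("CB", None)
            coords_b.pop("CB", None)
        elif i in seq:
            name_a, side_a, name_b, side_b, _ = seq[i]
            coords_a.pop("CB", None)
            coords_b.pop("CB", None)
            coords_a.update(side_a)
            coords_b.update(side_b)
        chain_a.append(_mk_res("A", i, name_a, coords_a))
        chain_b.append(_mk_res("B", i, name_b, coords_b))

    structure = Structure(id="toy_complex", chains=[("A", chain_a), ("B", chain_b)])
    if out_path is not None:
        write_pdb(structure, out_path)
    return structure, truth


# ----------------------------------------------------------------------------
# KIR-like MSA + variants

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_RECEPTOR_NAMES = ["KIR2DL3", "KIR2DL1", "KIR2DL2", "KIR2DS1", "KIR2DS3", "KIR2DS4", "KIR2DS5"]


def make_kir_like_msa(
    n_receptors: int = 7,
    n_variants: int = 12,
    epitope_positions: set[int] | None = None,
    seed: int = 1,
    length: int = 200,
    divergence: float = 0.05,
) -> tuple[MSA, pd.DataFrame, pd.DataFrame]:
    """Gapless KIR2D-like family alignment plus a planted variant table.

    The first record is the reference (KIR2DL3-like); other receptors
    differ from it at a seeded ~``divergence`` fraction of columns.
    Variants alternate between epitope and non-epitope positions, so the
    expected intersection report is known by construction.

    Returns (msa, variant table, expected report with columns
    variant/receptor/reference_position/in_epitope).
    """
    if epitope_positions is None:
        epitope_positions = {41, 45, 46, 47, 48, 50, 65, 72, 87, 88}
    if any(p < 1 or p > length for p in epitope_positions):
        raise ValueError("epitope positions must lie within the sequence length")
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list(_AA20), size=length))
    names = [_RECEPTOR_NAMES[i % len(_RECEPTOR_NAMES)] + ("" if i < len(_RECEPTOR_NAMES) else f"_{i}")
             for i in range(n_receptors)]
    records = [(names[0], base)]
    for name in names[1:]:
        seq = list(base)
        n_mut = max(1, int(round(divergence * length)))
        for col in rng.choice(length, size=n_mut, replace=False):
            seq[col] = rng.choice([a for a in _AA20 if a != seq[col]])
        records.append((name, "".join(seq)))
    msa = MSA(records=records)

    inside = sorted(epitope_positions)
    outside = [p for p in range(1, length + 1) if p not in epitope_positions]
    rows, expected = [], []
    for i in range(n_variants):
        receptor = names[i % n_receptors]
        own = msa.ungapped(receptor)
        if i % 2 == 0:
            pos = inside[(i // 2) % len(inside)]
        else:
            pos = int(outside[int(rng.integers(0, len(outside)))])
        ref = own[pos - 1]
        alt = str(rng.choice([a for a in _AA20 if a != ref]))
        freq = round(float(rng.uniform(1e-4, 0.15)), 5)
        rows.append(
            {"receptor": receptor, "position": pos, "ref": ref, "alt": alt,
             "rs_id": f"rs{900000 + i}", "frequency": freq}
        )
        expected.append(
            {"variant": f"{receptor} {ref}{pos}{alt}", "receptor": receptor,
             "reference_position": pos, "in_epitope": pos in epitope_positions}
        )
    variants = pd.DataFrame(rows, columns=["receptor", "position", "ref", "alt", "rs_id", "frequency"])
    return msa, variants, pd.DataFrame(expected)


def make_synthetic_footprint(
    epitope_positions: set[int],
    chain_id: str = "C",
    area: float = 20.0,
    threshold: float = 1.0,
) -> FootprintResult:
    """A footprint fixture in reference numbering: ``area`` Å² buried at each
    epitope position, nothing elsewhere.  Synthetic stand-in for a measured
    footprint when only the membership pattern matters."""
    per_res = {(chain_id, p, ""): float(area) for p in sorted(epitope_positions)}
    return FootprintResult(
        target_group=frozenset({chain_id}),
        binder_group=frozenset({"H", "L"}),
        per_residue_buried=per_res,
        epitope_residues={k for k, v in per_res.items() if v >= threshold},
        partition={"H": area * len(per_res) * 0.7, "L": area * len(per_res) * 0.3},
        total_buried=float(area * len(per_res)),
        epitope_threshold=threshold,
        residue_names={k: "ALA" for k in per_res},
    )


# ----------------------------------------------------------------------------
# BLI datasets


def make_bli_dataset(
    params: KineticsParams,
    out_dir: str,
    top_concentration: float = 250e-9,
    n_dilutions: int = 6,
    t_assoc: float = 300.0,
    t_dissoc: float = 600.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 1,
) -> dict:
    """Two-fold dilution series of simulated sensorgrams, written as one
    CSV per well plus a manifest (file, concentration_M, t_assoc_end_s)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    concentrations = [top_concentration / 2.0**k for k in range(n_dilutions)]
    rows = []
    for k, c in enumerate(concentrations):
        tr = simulate_trace(
            params, c, t_assoc=t_assoc, t_dissoc=t_dissoc, dt=dt,
            noise_sd=noise_sd, seed=seed * 1000 + k,
        )
        fname = f"well_{k:02d}.csv"
        write_trace_csv(tr, out / fname)
        rows.append({"file": fname, "concentration_M": f"{c:.9e}", "t_assoc_end_s": t_assoc})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return {
        "manifest": str(manifest),
        "n_traces": n_dilutions,
        "concentrations_M": concentrations,
        "insufficient_for_global_fit": n_dilutions < 2,
        "seed": seed,
    }
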