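"""Minimal hierarchical macromolecular structure model with PDB/mmCIF I/O.

The model is deliberately small: a :class:`Structure` is an ordered list of
chains, each chain an ordered list of :class:`Residue` objects carrying
:class:`Atom` records.  Author numbering (as deposited) is the canonical
residue coordinate system throughout the package; mapping to mature-protein
numbering happens only in the variant-mapping layer.

Reading and writing go through :mod:`gemmi`; on read, alternate conformers
are collapsed to the highest-occupancy one (ties broken toward altloc 'A')
and hydrogens are dropped, so all downstream geometry is single-conformer
and heavy-atom based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "StructureError",
    "EmptySelectionError",
    "read_structure",
    "write_pdb",
    "select",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(ValueError):
    """Raised for unreadable files, unknown formats or invalid selections."""


class EmptySelectionError(StructureError):
    """Raised when a selection matches no atoms."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: non-finite coordinates {self.coord}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass(frozen=True)
class Residue:
    chain_id: str
    seq_id: int
    res_name: str
    atoms: tuple[Atom, ...]
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(
                f"residue {self.res_name} {self.chain_id}{self.seq_id}: no atoms"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.res_name in _WATER_NAMES

    @property
    def is_hetero(self) -> bool:
        return all(a.is_hetero for a in self.atoms)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    id: str
    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.chains]
        if len(ids) != len(set(ids)):
            raise StructureError(f"duplicate chain ids in structure {self.id}: {ids}")

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise StructureError(f"chain {chain_id!r} not in structure {self.id}")

    def residues(self) -> list[Residue]:
        return [r for _, res in self.chains for r in res]

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues() for a in r.atoms]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms())

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) array, chain order."""
        ats = self.atoms()
        if not ats:
            return np.empty((0, 3))
        return np.array([a.coord for a in ats], dtype=float)


def _pick_conformer(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolve toward altloc 'A' (blank sorts first,
    # which only happens when a lone blank-altloc copy duplicates a name)
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def _from_gemmi(st: gemmi.Structure, keep_hydrogens: bool) -> Structure:
    if len(st) == 0:
        raise StructureError(f"{st.name}: no models in file")
    model = st[0]  # NMR ensembles: model 1 only
    chains: list[tuple[str, list[Residue]]] = []
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            het = res.het_flag == "H"
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                if not keep_hydrogens and at.element.is_hydrogen:
                    continue
                by_name.setdefault(at.name, []).append(at)
            atoms = []
            for name in by_name:
                at = _pick_conformer(by_name[name])
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=name,
                        element=at.element.name.upper(),
                        coord=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        altloc="",
                        is_hetero=het,
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        seq_id=res.seqid.num,
                        insertion_code=(res.seqid.icode or " ").strip(),
                        res_name=res.name,
                        atoms=tuple(atoms),
                    )
                )
        if residues:
            chains.append((chain.name, residues))
    out = Structure(id=st.name or "structure", chains=chains)
    if out.n_atoms == 0:
        raise StructureError(f"{st.name}: no atoms after parsing")
    return out


def read_structure(path: str, format: str = "auto", keep_hydrogens: bool = False) -> Structure:
    """Read a PDB or mmCIF file into the hierarchical model.

    Altloc duplicates are resolved to the highest-occupancy conformer
    (tie -> altloc 'A'); hydrogens are dropped unless ``keep_hydrogens``;
    waters and other heteroatoms are retained but flagged.
    """
    fmt = format.lower()
    if fmt == "auto":
        lowered = str(path).lower()
        fmt = "mmcif" if lowered.endswith((".cif", ".cif.gz", ".mmcif")) else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureError(f"unknown structure format {format!r} (use pdb, mmcif or auto)")
    except StructureError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError with line info
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    return _from_gemmi(st, keep_hydrogens)


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for cid, residues in structure.chains:
        chain = gemmi.Chain(cid)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            gres.het_flag = "H" if res.is_hetero else "A"
            for at in res.atoms:
                gat = gemmi.Atom()
                gat.name = at.name
                gat.element = gemmi.Element(at.element)
                gat.pos = gemmi.Position(*at.coord)
                gat.occ = at.occupancy
                gat.serial = at.serial
                gres.add_atom(gat)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path: str) -> None:
    """Write the structure as fixed-column PDB (3-decimal coordinates)."""
    _to_gemmi(structure).write_pdb(str(path))


def select(
    structure: Structure,
    chain_ids: set[str] | list[str] | None = None,
    residue_range: tuple[int, int] | None = None,
    exclude_waters: bool = False,
    exclude_hetero: bool = False,
) -> Structure:
    """Return a new Structure restricted to the requested chains/residues.

    ``residue_range`` is an inclusive (lo, hi) interval on author seq ids.
    Raises :class:`EmptySelectionError` rather than returning silently empty.
    """
    wanted = set(chain_ids) if chain_ids is not None else set(structure.chain_ids)
    missing = wanted - set(structure.chain_ids)
    if missing:
        raise StructureError(
            f"chains {sorted(missing)} not present in structure {structure.id} "
            f"(has {structure.chain_ids})"
        )
    chains: list[tuple[str, list[Residue]]] = []
    for cid, residues in structure.chains:
        if cid not in wanted:
            continue
        kept = []
        for res in residues:
            if residue_range is not None and not (residue_range[0] <= res.seq_id <= residue_range[1]):
                continue
            if exclude_waters and res.is_water:
                continue
            if exclude_hetero and res.is_hetero:
                continue
            kept.append(res)
        if kept:
            chains.append((cid, kept))
    out = Structure(id=structure.id, chains=chains, metadata=dict(structure.metadata))
    if out.n_atoms == 0:
        raise EmptySelectionError(
            f"selection (chains={sorted(wanted)}, range={residue_range}) matched no atoms"
        )
    return out
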