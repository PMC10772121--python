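"""Shrake–Rupley solvent-accessible surface area.

Test points are a deterministic golden-section spiral on the unit sphere,
so areas are bit-reproducible for fixed parameters — no RNG is involved
anywhere.  Per-atom area is

    (exposed points / total points) * 4 * pi * (r_vdw + r_probe)**2

and neighbour occlusion queries run on a uniform spatial grid with cell
size 2 * (max radius + probe), which makes the sweep O(n) in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Structure

__all__ = ["SASAParams", "SASAResult", "MissingRadiusError", "compute_sasa", "sphere_points"]

# Bondi-style van der Waals radii (Å); single embedded set, overridable.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}
DEFAULT_RADIUS = 1.80  # fallback for elements outside the table


class MissingRadiusError(KeyError):
    """An element has no van der Waals radius and no fallback is allowed."""


@dataclass(frozen=True)
class SASAParams:
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    default_radius: float | None = DEFAULT_RADIUS  # None -> unknown element is an error

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if self.n_sphere_points < 24:
            raise ValueError("n_sphere_points must be >= 24")
        if any(r <= 0 for r in self.radii_table.values()):
            raise ValueError("all van der Waals radii must be > 0")

    def radius_of(self, element: str, atom_label: str = "") -> float:
        r = self.radii_table.get(element.upper())
        if r is None:
            if self.default_radius is None:
                raise MissingRadiusError(
                    f"no van der Waals radius for element {element!r}"
                    + (f" (atom {atom_label})" if atom_label else "")
                )
            r = self.default_radius
        return r


@dataclass
class SASAResult:
    per_atom: dict[tuple[tuple[str, int, str], str], float]
    per_residue: dict[tuple[str, int, str], float]
    total: float
    params: SASAParams

    def residue_area(self, chain_id: str, seq_id: int, icode: str = "") -> float:
        return self.per_residue.get((chain_id, seq_id, icode), 0.0)


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere via the golden-section spiral."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _grid_neighbours(coords: np.ndarray, cell: float):
    """Map each atom to candidate occluders via a uniform grid (27-cell probe)."""
    keys = np.floor(coords / cell).astype(np.int64)
    buckets: dict[tuple[int, int, int], list[int]] = {}
    for idx, k in enumerate(map(tuple, keys)):
        buckets.setdefault(k, []).append(idx)
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]

    def neighbours(idx: int) -> np.ndarray:
        kx, ky, kz = keys[idx]
        out: list[int] = []
        for dx, dy, dz in offsets:
            out.extend(buckets.get((kx + dx, ky + dy, kz + dz), ()))
        arr = np.asarray(out, dtype=np.int64)
        return arr[arr != idx]

    return neighbours


def sasa_per_atom_array(coords: np.ndarray, radii: np.ndarray, params: SASAParams) -> np.ndarray:
    """Per-atom SASA (Å²) for raw coordinates/radii; the numeric core."""
    n = len(coords)
    if n == 0:
        return np.empty(0)
    pts = sphere_points(params.n_sphere_points)
    probe = params.probe_radius
    extended = radii + probe
    neighbours = _grid_neighbours(coords, cell=2.0 * (float(radii.max()) + probe))
    areas = np.empty(n)
    for i in range(n):
        nb = neighbours(i)
        if nb.size:
            d = np.linalg.norm(coords[nb] - coords[i], axis=1)
            nb = nb[d < extended[i] + extended[nb]]
        if nb.size == 0:
            exposed_frac = 1.0
        else:
            test = coords[i] + extended[i] * pts  # (p, 3)
            d2 = np.sum((test[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < extended[nb][None, :] ** 2, axis=1)
            exposed_frac = 1.0 - buried.mean()
        areas[i] = exposed_frac * 4.0 * np.pi * extended[i] ** 2
    return areas


def compute_sasa(structure: Structure, params: SASAParams | None = None) -> SASAResult:
    """Shrake–Rupley SASA of every atom in ``structure``.

    Deterministic for fixed params.  Callers wanting waters or hetero groups
    excluded should pre-filter with :func:`epifoot.structure.select`.
    """
    params = params or SASAParams()
    residues = structure.residues()
    if not residues:
        raise ValueError("cannot compute SASA of an empty structure")
    atom_keys: list[tuple[tuple[str, int, str], str]] = []
    coords = []
    radii = []
    for res in residues:
        for at in res.atoms:
            atom_keys.append((res.key, at.name))
            coords.append(at.coord)
            radii.append(params.radius_of(at.element, f"{res.res_name} {res.chain_id}{res.seq_id} {at.name}"))
    areas = sasa_per_atom_array(np.asarray(coords, float), np.asarray(radii, float), params)
    per_atom = dict(zip(atom_keys, areas.tolist()))
    per_residue: dict[tuple[str, int, str], float] = {}
    for (rkey, _), a in per_atom.items():
        per_residue[rkey] = per_residue.get(rkey, 0.0) + a
    return SASAResult(per_atom=per_atom, per_residue=per_residue, total=float(areas.sum()), params=params)
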