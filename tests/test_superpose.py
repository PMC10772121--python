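import math

import numpy as np
import pytest

from epifoot.structure import Atom, Residue, Structure
from epifoot.superpose import (
    DegenerateGeometryError,
    ResiduePairing,
    Superposition,
    kabsch_superpose,
    pair_residues,
    tm_score,
)
from epifoot.synthetic import ToyComplexSpec, make_toy_complex

from conftest import random_rotation, transform_structure


def _ca_chain(points, chain="A", offset=0, icode=""):
    residues = [
        Residue(chain, i + 1 + offset, "ALA", (Atom(i + 1, "CA", "C", tuple(p)),), icode)
        for i, p in enumerate(points)
    ]
    return Structure(id="pts", chains=[(chain, residues)])


@pytest.fixture(scope="module")
def helix():
    st, _ = make_toy_complex(ToyComplexSpec(n_residues_per_chain=30))
    from epifoot.structure import select

    return select(st, {"A"})


def test_identical_chains_fully_paired(helix):
    pairing = pair_residues(helix, helix, "by_number")
    assert pairing.n_pairs == 30


def test_exact_rigid_copy_gives_zero_rmsd(helix, rng):
    moved = transform_structure(helix, random_rotation(rng), np.array([4.0, 5.0, -6.0]))
    pairing = pair_residues(helix, moved, "by_number")
    sup = kabsch_superpose(pairing)
    assert sup.rmsd <= 1e-6
    assert np.abs(sup.rotation.T @ sup.rotation - np.eye(3)).max() < 1e-8
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)
    assert tm_score(pairing, sup) == pytest.approx(1.0, abs=1e-9)


def test_four_point_fit_matches_rotation_grid_oracle():
    """Planar 4-point problem: the optimal rotation is about z, so an
    exhaustive 1D grid search over the angle is an independent oracle."""
    a_pts = np.array([[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 0], [0, -1.0, 0]])
    theta = math.radians(25.0)
    rot_z = np.array(
        [[math.cos(theta), -math.sin(theta), 0], [math.sin(theta), math.cos(theta), 0], [0, 0, 1.0]]
    )
    b_pts = a_pts @ rot_z.T
    b_pts[0] += np.array([0.6, 0.8, 0.0])  # displace one point by 1.0 Å

    pairing = ResiduePairing(
        pairs=list(zip(_ca_chain(a_pts).residues(), _ca_chain(b_pts).residues())),
        source="by_number",
    )
    sup = kabsch_superpose(pairing)

    best = np.inf
    ca, cb = a_pts.mean(axis=0), b_pts.mean(axis=0)
    for ang_deg in np.arange(0.0, 360.0, 0.005):
        ang = math.radians(ang_deg)
        r = np.array(
            [[math.cos(ang), -math.sin(ang), 0], [math.sin(ang), math.cos(ang), 0], [0, 0, 1.0]]
        )
        d = (a_pts - ca) - (b_pts - cb) @ r.T
        best = min(best, math.sqrt((d**2).sum() / 4))
    assert sup.rmsd == pytest.approx(best, abs=1e-4)


def test_rmsd_invariant_under_pre_rotation(helix, rng):
    moved = transform_structure(helix, random_rotation(rng), np.zeros(3))
    jittered = transform_structure(helix, np.eye(3), np.zeros(3))
    base = kabsch_superpose(pair_residues(helix, moved, "by_number")).rmsd
    pre = transform_structure(moved, random_rotation(rng), np.array([1.0, 2.0, 3.0]))
    again = kabsch_superpose(pair_residues(jittered, pre, "by_number")).rmsd
    assert again == pytest.approx(base, abs=1e-6)


def test_kabsch_is_a_local_optimum(helix, rng):
    moved = transform_structure(helix, random_rotation(rng), np.array([2.0, 0.0, 0.0]))
    # perturb a few CA positions so rmsd > 0
    pairing = pair_residues(helix, moved, "by_number")
    xa, xb = pairing.ca_coords()
    xb = xb + rng.normal(scale=0.4, size=xb.shape)
    pairing = ResiduePairing(
        pairs=list(zip(_ca_chain(xa).residues(), _ca_chain(xb).residues())), source="by_number"
    )
    sup = kabsch_superpose(pairing)

    def rmsd_with(rot):
        cb = xb.mean(axis=0)
        tr = xa.mean(axis=0) - rot @ cb
        d = xa - (xb @ rot.T + tr)
        return math.sqrt((d**2).sum() / len(xa))

    for _ in range(50):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(0.001, 0.2)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        perturb = np.eye(3) + math.sin(ang) * k + (1 - math.cos(ang)) * (k @ k)
        assert rmsd_with(perturb @ sup.rotation) >= sup.rmsd - 1e-9


def test_tm_score_is_one_for_identity(helix):
    pairing = pair_residues(helix, helix, "by_number")
    sup = kabsch_superpose(pairing)
    assert tm_score(pairing, sup) == pytest.approx(1.0, abs=1e-12)


def test_tm_score_closed_form_at_d0():
    n, l_target = 20, 30
    d0 = 1.24 * (l_target - 15) ** (1 / 3) - 1.8
    rng = np.random.default_rng(3)
    pts = rng.normal(scale=8.0, size=(n, 3))
    shifted = pts + np.array([d0, 0.0, 0.0])  # every d_i exactly d0
    pairing = ResiduePairing(
        pairs=list(zip(_ca_chain(pts).residues(), _ca_chain(shifted).residues())),
        source="by_number",
    )
    identity = Superposition(rotation=np.eye(3), translation=np.zeros(3), rmsd=d0, n_pairs=n)
    assert tm_score(pairing, identity, l_target) == pytest.approx(n / (2 * l_target), abs=1e-12)


def test_tm_score_decreases_when_deviations_grow():
    n = 25
    rng = np.random.default_rng(4)
    pts = rng.normal(scale=8.0, size=(n, 3))
    identity = Superposition(rotation=np.eye(3), translation=np.zeros(3), rmsd=0.0, n_pairs=n)
    scores = []
    for scale in (0.5, 1.0, 2.0, 4.0):
        moved = pts + scale * np.array([1.0, 0.0, 0.0])
        pairing = ResiduePairing(
            pairs=list(zip(_ca_chain(pts).residues(), _ca_chain(moved).residues())),
            source="by_number",
        )
        scores.append(tm_score(pairing, identity, n))
    assert all(a > b for a, b in zip(scores, scores[1:]))


def test_l_target_below_16_rejected(helix):
    pairing = pair_residues(helix, helix, "by_number")
    sup = kabsch_superpose(pairing)
    with pytest.raises(ValueError, match="l_target"):
        tm_score(pairing, sup, l_target=15)


def test_by_alignment_bridges_numbering_offset(helix):
    shifted = Structure(
        id="off",
        chains=[
            (
                "A",
                [
                    Residue(r.chain_id, r.seq_id + 5, r.res_name, r.atoms, r.insertion_code)
                    for r in helix.residues()
                ],
            )
        ],
    )
    # identical sequences -> alignment is the identity, full pairing
    pairing = pair_residues(helix, shifted, "by_alignment")
    assert pairing.n_pairs == 30
    assert kabsch_superpose(pairing).rmsd <= 1e-6
    # by_number sees the offset and pairs only the overlap
    assert pair_residues(helix, shifted, "by_number").n_pairs == 25


def test_explicit_alignment_gap_columns_produce_no_pairs(helix):
    idx = [(i, i) for i in range(30) if i not in (10, 11, 12)]
    pairing = pair_residues(helix, helix, "by_alignment", alignment=idx)
    assert pairing.n_pairs == 27
    paired_a = {ra.seq_id for ra, _ in pairing.pairs}
    assert {11, 12, 13}.isdisjoint(paired_a)


def test_degenerate_geometry_rejected():
    line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
    pairing = ResiduePairing(
        pairs=list(zip(_ca_chain(line).residues(), _ca_chain(line + 1.0).residues())),
        source="by_number",
    )
    with pytest.raises(DegenerateGeometryError):
        kabsch_superpose(pairing)
    two = np.array([[0.0, 0, 0], [1.0, 1, 0]])
    with pytest.raises(DegenerateGeometryError):
        pair_residues(_ca_chain(two), _ca_chain(two[:1]), "by_number")
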