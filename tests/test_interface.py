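import numpy as np
import pytest

from epifoot.interface import (
    ContactCriteria,
    classify_contacts,
    compute_footprint,
    footprint_from_report,
    footprint_report,
)
from epifoot.sasa import compute_sasa
from epifoot.structure import Atom, Residue, Structure, StructureError, select
from epifoot.synthetic import PlantedContact, ToyComplexSpec, make_toy_complex

from conftest import random_rotation, transform_structure


def test_distant_chains_bury_nothing():
    st, _ = make_toy_complex(ToyComplexSpec(inter_chain_gap=100.0, n_residues_per_chain=10))
    fp = compute_footprint(st, {"A"}, {"B"})
    assert fp.total_buried == 0.0
    assert fp.epitope_residues == set()
    assert fp.warnings  # warning-tagged empty footprint


def test_footprint_matches_double_sasa_oracle(touching_complex):
    """ΔSASA must equal a direct two-evaluation recomputation per residue."""
    fp = compute_footprint(touching_complex, {"A"}, {"B"})
    target = select(touching_complex, {"A"}, exclude_waters=True, exclude_hetero=True)
    alone = compute_sasa(target)
    together = compute_sasa(select(touching_complex, {"A", "B"}, exclude_waters=True,
                                   exclude_hetero=True))
    for res in target.residues():
        expected = 0.0
        for at in res.atoms:
            key = (res.key, at.name)
            expected += max(0.0, alone.per_atom[key] - together.per_atom[key])
        assert fp.per_residue_buried[res.key] == pytest.approx(expected, abs=1e-9)
    assert fp.total_buried > 0


def test_partition_is_exhaustive_and_exact(touching_complex):
    fp = compute_footprint(touching_complex, {"A"}, {"B"})
    assert sum(fp.partition.values()) == pytest.approx(fp.total_buried, abs=1e-6)
    assert all(v >= 0 for v in fp.per_residue_buried.values())


def test_one_sided_totals_bounded_by_two_sided(touching_complex):
    ab = compute_footprint(touching_complex, {"A"}, {"B"})
    ba = compute_footprint(touching_complex, {"B"}, {"A"})
    two_sided = ab.total_buried + ba.total_buried
    assert ab.total_buried >= 0 and ba.total_buried >= 0
    assert ab.total_buried <= two_sided and ba.total_buried <= two_sided


def test_overlapping_groups_rejected(touching_complex):
    with pytest.raises(StructureError, match="overlap"):
        compute_footprint(touching_complex, {"A"}, {"A", "B"})
    with pytest.raises(StructureError):
        classify_contacts(touching_complex, {"A"}, {"A"})


def _gly(chain, seq, xyz):
    x, y, z = xyz
    atoms = (
        Atom(1, "N", "N", (x, y, z)),
        Atom(2, "CA", "C", (x + 1.46, y, z)),
        Atom(3, "C", "C", (x + 2.0, y + 1.3, z)),
        Atom(4, "O", "O", (x + 3.2, y + 1.4, z)),
    )
    return Residue(chain, seq, "GLY", atoms)


def test_far_glycines_make_no_contacts():
    st = Structure(
        id="gly",
        chains=[("A", [_gly("A", 1, (0, 0, 0))]), ("B", [_gly("B", 1, (20.0, 0, 0))])],
    )
    assert classify_contacts(st, {"A"}, {"B"}) == []


@pytest.mark.parametrize(
    "kind,distance",
    [("hbond", 2.9), ("cation_pi", 4.5), ("pi_stack", 5.0), ("hydrophobic", 4.0)],
)
def test_single_planted_contact_recovered_exactly(kind, distance):
    st, truth = make_toy_complex(
        ToyComplexSpec(planted_contacts=(PlantedContact(kind, distance),))
    )
    contacts = classify_contacts(st, {"A"}, {"B"})
    assert [c.kind for c in contacts] == [kind]
    assert contacts[0].distance == pytest.approx(distance, abs=0.1)
    assert contacts[0].partner_a.seq_id == truth[0]["res_a"]
    assert contacts[0].partner_b.seq_id == truth[0]["res_b"]


def test_all_planted_contacts_recovered(planted_complex):
    st, truth = planted_complex
    got = {
        (c.kind, c.partner_a.seq_id, c.partner_b.seq_id)
        for c in classify_contacts(st, {"A"}, {"B"})
    }
    want = {(t["kind"], t["res_a"], t["res_b"]) for t in truth}
    assert got == want


def test_hbond_requires_donor_geometry():
    """An N···O pair at 2.9 Å with the acceptor behind the donor's bond
    (angle < 90°) must not count as a hydrogen bond."""
    # Ser with OG; acceptor placed so that CB-OG-acceptor angle ≈ 30°
    ser = Residue(
        "A", 1, "SER",
        (
            Atom(1, "CB", "C", (0.0, 0.0, 0.0)),
            Atom(2, "OG", "O", (1.41, 0.0, 0.0)),
        ),
    )
    asp = Residue(
        "B", 1, "ASP",
        (Atom(3, "OD1", "O", (1.41 - 2.9 * np.cos(np.radians(30)), 2.9 * np.sin(np.radians(30)), 0.0)),),
    )
    st = Structure(id="hb", chains=[("A", [ser]), ("B", [asp])])
    assert all(c.kind != "hbond" for c in classify_contacts(st, {"A"}, {"B"}))
    # and the well-oriented pair at the same distance does qualify
    asp_ok = Residue("B", 1, "ASP", (Atom(3, "OD1", "O", (1.41 + 2.9, 0.0, 0.0)),))
    st_ok = Structure(id="hb2", chains=[("A", [ser]), ("B", [asp_ok])])
    kinds = [c.kind for c in classify_contacts(st_ok, {"A"}, {"B"})]
    assert kinds == ["hbond"]


def test_contacts_invariant_under_rigid_motion(planted_complex, rng):
    st, _ = planted_complex
    before = [
        (c.kind, c.partner_a.label(), c.partner_b.label())
        for c in classify_contacts(st, {"A"}, {"B"})
    ]
    moved = transform_structure(st, random_rotation(rng), np.array([13.0, -6.0, 4.0]))
    after = [
        (c.kind, c.partner_a.label(), c.partner_b.label())
        for c in classify_contacts(moved, {"A"}, {"B"})
    ]
    assert before == after


def test_contact_list_sorted_by_kind_then_distance(planted_complex):
    st, _ = planted_complex
    contacts = classify_contacts(st, {"A"}, {"B"})
    keys = [(c.kind, c.distance) for c in contacts]
    assert keys == sorted(keys)


def test_report_round_trips_footprint(touching_complex):
    fp = compute_footprint(touching_complex, {"A"}, {"B"})
    contacts = classify_contacts(touching_complex, {"B"}, {"A"})
    report = footprint_report(fp, contacts)
    assert report["total_buried_area"] == pytest.approx(fp.total_buried, abs=1e-3)
    assert sum(report["partition"].values()) == pytest.approx(fp.total_buried, abs=1e-2)
    back = footprint_from_report(report)
    assert back.epitope_residues == fp.epitope_residues
    assert back.total_buried == pytest.approx(fp.total_buried, abs=1e-3)


def test_empty_footprint_reports_zero_totals():
    st, _ = make_toy_complex(ToyComplexSpec(inter_chain_gap=100.0, n_residues_per_chain=10))
    fp = compute_footprint(st, {"A"}, {"B"})
    report = footprint_report(fp, [])
    assert report["total_buried_area"] == 0.0
    assert report["residues"] == []
    assert report["contacts"] == []


def test_criteria_validation():
    with pytest.raises(ValueError):
        ContactCriteria(hbond_da_max=-1.0)
    with pytest.raises(ValueError):
        ContactCriteria(hbond_angle_min=200.0)
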