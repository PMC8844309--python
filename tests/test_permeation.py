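"""Compartment labeling, crossing detection and trajectory analyses."""

import re

import numpy as np
import pytest

import porepass as pp
from porepass.permeation import (
    Compartment,
    CrossingEvent,
    PermeationError,
    chi1_series,
    contact_ladder,
    dihedral,
    wetting_occupancy,
)

from .conftest import scripted_trajectory


def containment_oracle(point, geom):
    """Independent scalar re-implementation of the compartment rules."""
    x, y, z = point
    r = np.hypot(x, y)
    if r <= geom.cylinder_radius and geom.z_pore_bottom <= z <= geom.z_pore_top:
        return Compartment.PORE
    if r <= geom.cylinder_radius and geom.z_cage_bottom <= z < geom.z_pore_bottom:
        return Compartment.CAGE
    for p in geom.portals:
        if (p.r_range[0] <= r <= p.r_range[1]
                and p.z_range[0] <= z <= p.z_range[1]):
            return Compartment.PORTAL
    if z > geom.z_extracellular:
        return Compartment.BULK_EXT
    return Compartment.BULK_CYT


def regex_oracle(label_row, times):
    """Exhaustive event finder on one ion's label string.

    Events are maximal non-overlapping matches of
    PORTAL [^BULK_CYT]*? PORE [^BULK_CYT]*? BULK_EXT.
    """
    chars = {Compartment.BULK_CYT: "C", Compartment.PORTAL: "T",
             Compartment.CAGE: "G", Compartment.PORE: "P",
             Compartment.BULK_EXT: "E"}
    s = "".join(chars[Compartment(l)] for l in label_row)
    out = []
    for m in re.finditer(r"T[^C]*?P[^C]*?E", s):
        out.append((float(times[m.start()]), float(times[m.end() - 1])))
    return out


class TestAssignCompartments:
    def test_scripted_positions_hit_expected_labels(self, cage_geometry):
        traj = scripted_trajectory(
            ["BULK_CYT", "PORTAL", "CAGE", "PORE", "BULK_EXT"], cage_geometry
        )
        series = pp.assign_compartments(traj, cage_geometry)
        got = [Compartment(v).name for v in series.labels[:, 0]]
        assert got == ["BULK_CYT", "PORTAL", "CAGE", "PORE", "BULK_EXT"]

    def test_pore_bottom_boundary_tie_prefers_pore(self, cage_geometry):
        pos = np.array([[[0.0, 0.0, cage_geometry.z_pore_bottom]]])
        traj = pp.IonTrajectory(times=[0.0], ion_positions=pos,
                                axis=pp.ChannelAxis(np.zeros(3), [0, 0, 1.0]))
        series = pp.assign_compartments(traj, cage_geometry)
        assert Compartment(series.labels[0, 0]) == Compartment.PORE

    def test_random_points_match_containment_oracle_exactly(self, cage_geometry):
        rng = np.random.default_rng(21)
        pts = rng.uniform([-20, -20, -50], [20, 20, 40], size=(1000, 3))
        traj = pp.IonTrajectory(
            times=[0.0], ion_positions=pts[None, :, :],
            axis=pp.ChannelAxis(np.zeros(3), [0, 0, 1.0]),
        )
        series = pp.assign_compartments(traj, cage_geometry)
        expected = [int(containment_oracle(p, cage_geometry)) for p in pts]
        np.testing.assert_array_equal(series.labels[0], expected)

    def test_nan_coordinate_reports_frame(self, cage_geometry):
        pos = np.zeros((2, 1, 3))
        pos[1, 0, 0] = np.nan
        traj = pp.IonTrajectory(times=[0.0, 0.1], ion_positions=pos,
                                axis=pp.ChannelAxis(np.zeros(3), [0, 0, 1.0]))
        with pytest.raises(PermeationError, match="frame 1"):
            pp.assign_compartments(traj, cage_geometry)


class TestDetectCrossings:
    def test_complete_passage_yields_one_event(self, cage_geometry):
        traj = scripted_trajectory(
            ["BULK_CYT", "PORTAL", "CAGE", "PORE", "BULK_EXT"], cage_geometry
        )
        series = pp.assign_compartments(traj, cage_geometry)
        events = pp.detect_crossings(series)
        assert len(events) == 1
        ev = events[0]
        assert ev.t_entry == pytest.approx(0.1)
        assert ev.t_exit == pytest.approx(0.4)
        assert ev.transit == pytest.approx(0.3)
        assert ev.portal == 0

    def test_incomplete_passage_yields_no_event(self, cage_geometry):
        traj = scripted_trajectory(
            ["PORTAL", "CAGE", "PORTAL", "BULK_CYT"], cage_geometry
        )
        series = pp.assign_compartments(traj, cage_geometry)
        assert pp.detect_crossings(series) == []

    def test_pore_retreat_and_reentry_restarts_machine(self, cage_geometry):
        traj = scripted_trajectory(
            ["PORTAL", "PORE", "BULK_CYT", "PORTAL", "CAGE", "PORE", "BULK_EXT"],
            cage_geometry,
        )
        series = pp.assign_compartments(traj, cage_geometry)
        events = pp.detect_crossings(series)
        assert len(events) == 1
        assert events[0].t_entry == pytest.approx(0.3)

    def test_random_walk_labels_match_regex_oracle(self):
        rng = np.random.default_rng(5)
        n_ions, n_frames = 200, 300
        labels = rng.integers(0, 5, size=(n_frames, n_ions), dtype=np.int8)
        times = np.arange(n_frames) * 0.1
        series = pp.permeation.CompartmentSeries(
            times=times, labels=labels,
            portal_index=np.where(labels == int(Compartment.PORTAL), 0, -1).astype(np.int16),
            ion_ids=list(range(n_ions)), ion_charge=np.full(n_ions, -1.0),
        )
        events = pp.detect_crossings(series)
        got = {}
        for e in events:
            got.setdefault(e.ion, []).append((e.t_entry, e.t_exit))
        for j in range(n_ions):
            assert got.get(j, []) == regex_oracle(labels[:, j], times), f"ion {j}"

    def test_no_overlapping_events_per_ion(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 5, size=(500, 50), dtype=np.int8)
        times = np.arange(500) * 0.1
        series = pp.permeation.CompartmentSeries(
            times=times, labels=labels,
            portal_index=np.full((500, 50), -1, dtype=np.int16),
            ion_ids=list(range(50)), ion_charge=np.full(50, -1.0),
        )
        by_ion = {}
        for e in pp.detect_crossings(series):
            by_ion.setdefault(e.ion, []).append(e)
        for evs in by_ion.values():
            evs.sort(key=lambda e: e.t_entry)
            for a, b in zip(evs, evs[1:]):
                assert a.t_exit <= b.t_entry


class TestEstimateConductance:
    def test_unit_event_arithmetic(self):
        est = pp.estimate_conductance(1, 1.0, 1.0, 1000.0)
        assert est.conductance == pytest.approx(160.218, abs=5e-4)

    def test_pooled_simulation_totals(self):
        est = pp.estimate_conductance(36, 1.0, 300.0, 425.0)
        assert est.conductance == pytest.approx(45.2, abs=0.05)

    def test_linearity_and_scaling(self):
        base = pp.estimate_conductance(10, 1.0, 100.0, 200.0).conductance
        assert pp.estimate_conductance(20, 1.0, 100.0, 200.0).conductance == pytest.approx(
            2 * base, rel=1e-12
        )
        assert pp.estimate_conductance(10, 1.0, 200.0, 200.0).conductance == pytest.approx(
            base / 2, rel=1e-12
        )
        assert pp.estimate_conductance(10, 1.0, 100.0, 400.0).conductance == pytest.approx(
            base / 2, rel=1e-12
        )

    def test_sign_of_potential_discarded(self):
        a = pp.estimate_conductance(5, -1.0, 10.0, -425.0)
        b = pp.estimate_conductance(5, 1.0, 10.0, 425.0)
        assert a.conductance == pytest.approx(b.conductance, rel=1e-12)

    def test_zero_duration_or_potential_rejected(self):
        with pytest.raises(PermeationError):
            pp.estimate_conductance(1, 1.0, 0.0, 100.0)
        with pytest.raises(PermeationError):
            pp.estimate_conductance(1, 1.0, 10.0, 0.0)


class TestZTracks:
    def test_uniform_motion_gives_arithmetic_progression(self):
        pos = np.array([[[0.0, 0.0, float(k)]] for k in range(10)])
        traj = pp.IonTrajectory(times=np.arange(10) * 0.1, ion_positions=pos,
                                axis=pp.ChannelAxis(np.zeros(3), [0, 0, 1.0]))
        t, z = pp.z_tracks(traj)[0]
        np.testing.assert_allclose(np.diff(z), 1.0)

    def test_axis_flip_negates_series(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(20, 4, 3))
        up = pp.IonTrajectory(times=np.arange(20) * 0.1, ion_positions=pos,
                              axis=pp.ChannelAxis(np.zeros(3), [0, 0, 1.0]))
        dn = pp.IonTrajectory(times=np.arange(20) * 0.1, ion_positions=pos,
                              axis=pp.ChannelAxis(np.zeros(3), [0, 0, -1.0]))
        for ion in range(4):
            _, zu = pp.z_tracks(up)[ion]
            _, zd = pp.z_tracks(dn)[ion]
            np.testing.assert_allclose(zd, -zu, atol=1e-12)

    def test_periodic_unwrap_matches_hand_oracle(self):
        box = np.array([100.0, 100.0, 100.0])
        true_z = np.cumsum(np.full(40, 7.0)) - 7.0  # 0, 7, ..., 273
        wrapped = np.mod(true_z + 50.0, 100.0) - 50.0
        pos = np.zeros((40, 1, 3))
        pos[:, 0, 2] = wrapped
        traj = pp.IonTrajectory(times=np.arange(40) * 0.1, ion_positions=pos,
                                axis=pp.ChannelAxis(np.zeros(3), [0, 0, 1.0]), box=box)
        _, z = pp.z_tracks(traj)[0]
        assert np.max(np.abs(np.diff(z))) < 50.0
        np.testing.assert_allclose(z - z[0], true_z - true_z[0], atol=1e-9)

    def test_unknown_ion_rejected(self):
        pos = np.zeros((3, 1, 3))
        traj = pp.IonTrajectory(times=np.arange(3) * 0.1, ion_positions=pos,
                                axis=pp.ChannelAxis(np.zeros(3), [0, 0, 1.0]))
        with pytest.raises(PermeationError, match="99"):
            pp.z_tracks(traj, ions=[99])


def lysine_like(serial, resnum, pos, chain="A"):
    return pp.AtomRecord(serial=serial, name="NZ", element="N", residue_name="LYS",
                         residue_number=resnum, chain=chain,
                         position=np.asarray(pos, float), vdw_radius=1.55)


class TestContactLadder:
    def build(self, ion_path, residues_positions, dt=0.1):
        """ion_path: (n,3); residues_positions: {resnum: (3,)}"""
        frames = []
        atoms = [lysine_like(i + 1, num, p) for i, (num, p) in
                 enumerate(residues_positions.items())]
        protein = pp.MolecularStructure(atoms=atoms)
        n = len(ion_path)
        frames = [protein] * n
        traj = pp.IonTrajectory(
            times=np.arange(n) * dt, ion_positions=np.asarray(ion_path)[:, None, :],
            axis=pp.ChannelAxis(np.zeros(3), [0, 0, 1.0]),
            protein_frames=frames,
        )
        return traj

    # K624-analog at 624, R599-analog at 599, K606-analog at 606
    RESIDUES = {624: (0.0, 0.0, 0.0), 599: (10.0, 0.0, 0.0), 606: (20.0, 0.0, 0.0)}

    def path_through(self, *xs):
        return [(x, 3.0, 0.0) for x in xs]

    def test_ordered_ladder_and_unidirectional_handover(self):
        traj = self.build(self.path_through(0, 5, 10, 15, 20), self.RESIDUES)
        event = CrossingEvent(ion=0, t_entry=0.0, t_exit=0.4, portal=0)
        ladder, uni = contact_ladder(
            traj, event, [("A", 624), ("A", 599), ("A", 606)], cutoff=4.0
        )
        assert [sel for sel, _ in ladder] == [("A", 624), ("A", 599), ("A", 606)]
        assert uni is True

    def test_bounce_back_to_donor_is_not_unidirectional(self):
        traj = self.build(self.path_through(0, 10, 20, 10, 25), self.RESIDUES)
        event = CrossingEvent(ion=0, t_entry=0.0, t_exit=0.4, portal=0)
        _, uni = contact_ladder(
            traj, event, [("A", 624), ("A", 599), ("A", 606)], cutoff=4.0
        )
        assert uni is False

    def test_wider_cutoff_never_delays_first_contact(self):
        path = [(x, 3.0, 0.0) for x in np.linspace(-5, 25, 31)]
        traj = self.build(path, self.RESIDUES)
        event = CrossingEvent(ion=0, t_entry=0.0, t_exit=3.0, portal=0)
        sel = [("A", 624), ("A", 599), ("A", 606)]
        t4 = dict(contact_ladder(traj, event, sel, cutoff=4.0)[0])
        t6 = dict(contact_ladder(traj, event, sel, cutoff=6.0)[0])
        for key in t4:
            assert t6[key] <= t4[key]
        # oracle: first frame within cutoff by direct distance scan
        for key, t_first in t6.items():
            res_pos = np.array(self.RESIDUES[key[1]])
            d = np.linalg.norm(np.array(path) - res_pos, axis=1)
            expected = traj.times[np.flatnonzero(d <= 6.0)[0]]
            assert t_first == pytest.approx(expected)

    def test_requires_protein_frames(self):
        traj = pp.IonTrajectory(
            times=np.arange(3) * 0.1, ion_positions=np.zeros((3, 1, 3)),
            axis=pp.ChannelAxis(np.zeros(3), [0, 0, 1.0]),
        )
        event = CrossingEvent(ion=0, t_entry=0.0, t_exit=0.2, portal=0)
        with pytest.raises(PermeationError):
            contact_ladder(traj, event, [("A", 1), ("A", 2)])


def residue_frame(chi_target_deg):
    """Place N, CA, CB, CG so that χ1 equals the requested value.

    The CG position is rotated about the CA→CB bond starting from the cis
    (χ1 = 0) position; the mapping angle → χ1 is fixed by the standard
    right-hand convention (verified against Biopython in the oracle test).
    """
    theta = np.radians(chi_target_deg)
    atoms = [
        pp.AtomRecord(serial=1, name="N", element="N", residue_name="PHE",
                      residue_number=572, chain="A",
                      position=np.array([1.5, 0.0, -0.5])),
        pp.AtomRecord(serial=2, name="CA", element="C", residue_name="PHE",
                      residue_number=572, chain="A", position=np.zeros(3)),
        pp.AtomRecord(serial=3, name="CB", element="C", residue_name="PHE",
                      residue_number=572, chain="A",
                      position=np.array([0.0, 0.0, 1.5])),
        pp.AtomRecord(serial=4, name="CG", element="C", residue_name="PHE",
                      residue_number=572, chain="A",
                      position=np.array([1.2 * np.cos(theta), 1.2 * np.sin(theta), 2.0])),
    ]
    return pp.MolecularStructure(atoms=atoms)


class TestChi1:
    def test_dihedral_matches_biopython_oracle(self):
        from Bio.PDB.vectors import Vector, calc_dihedral
        rng = np.random.default_rng(17)
        for _ in range(50):
            p = rng.normal(size=(4, 3)) * 3
            ours = dihedral(*p)
            ref = np.degrees(calc_dihedral(*(Vector(*q) for q in p)))
            assert ours == pytest.approx(ref, abs=1e-9)

    @pytest.mark.parametrize("chi,label", [
        (-178.0, "trans"), (178.0, "trans"), (-60.0, "gauche-"),
        (60.0, "gauche+"), (-120.0, "gauche-"), (125.0, "trans"),
    ])
    def test_rotamer_bins(self, chi, label):
        series = chi1_series([residue_frame(chi)], ("A", 572))
        assert series.chi1[0] == pytest.approx(chi, abs=1e-6)
        assert series.labels == [label]

    def test_missing_atom_named_in_error(self):
        st = residue_frame(60.0)
        st = pp.MolecularStructure(atoms=[a for a in st.atoms if a.name != "CG"])
        with pytest.raises(PermeationError, match="CG"):
            chi1_series([st], ("A", 572))


class TestWetting:
    def axis_traj(self, pos):
        return pp.IonTrajectory(
            times=np.arange(len(pos)) * 0.1, ion_positions=np.asarray(pos, float),
            axis=pp.ChannelAxis(np.zeros(3), [0, 0, 1.0]), ion_charge=0.0,
        )

    REGION = ((-2.0, 2.0), (0.0, 3.0))

    def test_always_wet_is_one(self):
        pos = np.tile(np.array([[[1.0, 0.0, 0.0], [0.5, 0.5, 1.0]]]), (5, 1, 1))
        assert wetting_occupancy(self.axis_traj(pos), self.REGION, min_waters=2) == 1.0

    def test_never_wet_is_zero(self):
        pos = np.tile(np.array([[[10.0, 0.0, 0.0]]]), (5, 1, 1))
        assert wetting_occupancy(self.axis_traj(pos), self.REGION) == 0.0

    def test_alternating_frames_match_counting_oracle(self):
        pos = np.zeros((10, 1, 3))
        pos[1::2, 0, 0] = 50.0  # outside on odd frames
        traj = self.axis_traj(pos)
        assert wetting_occupancy(traj, self.REGION) == pytest.approx(0.5)
        # oracle: count frames directly
        inside = [
            1 if (abs(p[0, 2]) <= 2 and np.hypot(p[0, 0], p[0, 1]) <= 3) else 0
            for p in pos
        ]
        assert wetting_occupancy(traj, self.REGION) == pytest.approx(np.mean(inside))

    def test_empty_region_rejected(self):
        pos = np.zeros((2, 1, 3))
        with pytest.raises(PermeationError):
            wetting_occupancy(self.axis_traj(pos), ((2.0, -2.0), (0.0, 3.0)))
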