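"""Distance series, occupancies, bond modes and the salt-bridge network."""

import numpy as np
import pytest

import quartersite as qs
from quartersite.errors import MappingError
from quartersite.interface_contacts import (
    MAJOR_GROOVE_ACCEPTORS,
    saltbridge_contacts,
)

from conftest import apply_rigid, random_rigid

FULL = qs.FrameWindow.tail(1.0)


def brute_force_min_distances(ens, don_idx, acc_idx):
    """Frame-by-frame, pair-by-pair loop — the independent oracle."""
    out = []
    for f in range(ens.n_frames):
        best = np.inf
        for i in don_idx:
            for j in acc_idx:
                d = float(np.linalg.norm(ens.coords[f, i] - ens.coords[f, j]))
                best = min(best, d)
        out.append(best)
    return np.array(out)


@pytest.fixture()
def two_atom_ensemble():
    top = qs.Topology.from_records(
        [(1, "NZ", "LYS", 120, "A", "N"), (2, "O6", "DG", 8, "E", "O"),
         (3, "N7", "DG", 8, "E", "N")]
    )
    coords = np.zeros((3, 3, 3))
    coords[:, 1, 0] = 3.0  # O6 fixed at (3, 0, 0)
    coords[:, 2, 0] = 5.0  # N7 at (5, 0, 0)
    return qs.Ensemble(topology=top, coords=coords)


class TestDistanceSeries:
    def test_constant_geometry(self, two_atom_ensemble):
        contact = qs.ContactDefinition(
            label="t",
            donors=qs.SelectionSpec(atom_name="NZ"),
            acceptors=qs.SelectionSpec(atom_name="O6"),
        )
        series = qs.distance_series(two_atom_ensemble, contact, FULL)
        np.testing.assert_allclose(series.values, 3.0)

    def test_min_rule_over_acceptors(self, two_atom_ensemble):
        contact = qs.ContactDefinition(
            label="t",
            donors=qs.SelectionSpec(atom_name="NZ"),
            acceptors=qs.SelectionSpec(atom_name=("O6", "N7")),
        )
        series = qs.distance_series(two_atom_ensemble, contact, FULL)
        np.testing.assert_allclose(series.values, 3.0)

    def test_matches_brute_force_oracle(self, small_ensemble):
        ens, _ = small_ensemble
        contact = qs.ContactDefinition(
            label="R280-G",
            donors=qs.SelectionSpec(chain_id="A", res_id=280, atom_name=("NH1", "NH2")),
            acceptors=qs.SelectionSpec(chain_id="F", atom_name=("O6", "N7")),
        )
        series = qs.distance_series(ens, contact, FULL)
        don = qs.select(ens, contact.donors)
        acc = qs.select(ens, contact.acceptors)
        np.testing.assert_allclose(
            series.values, brute_force_min_distances(ens, don, acc), atol=0
        )

    def test_unresolvable_selection_names_contact(self, two_atom_ensemble):
        contact = qs.ContactDefinition(
            label="ghost",
            donors=qs.SelectionSpec(atom_name="XX"),
            acceptors=qs.SelectionSpec(atom_name="O6"),
        )
        with pytest.raises(MappingError, match="ghost"):
            qs.distance_series(two_atom_ensemble, contact, FULL)


class TestOccupancy:
    def test_extremes(self):
        s = qs.DistanceSeries("t", np.arange(4), np.full(4, 2.9))
        assert qs.occupancy(s) == 100.0
        s = qs.DistanceSeries("t", np.arange(4), np.full(4, 9.9))
        assert qs.occupancy(s) == 0.0

    def test_boundary_counts_as_bonded(self):
        s = qs.DistanceSeries("t", np.arange(2), np.array([3.5, 3.6]))
        assert qs.occupancy(s, cutoff=3.5) == 50.0
        assert qs.occupancy(s, cutoff=3.5, boundary="lt") == 0.0

    def test_monotone_in_cutoff(self, small_ensemble):
        ens, _ = small_ensemble
        contact = qs.ContactDefinition(
            label="m",
            donors=qs.SelectionSpec(chain_id="A", res_id=273, atom_name=("NH1", "NH2")),
            acceptors=qs.SelectionSpec(chain_id="E", atom_name=("O1P", "O2P")),
        )
        series = qs.distance_series(ens, contact, FULL)
        occs = [qs.occupancy(series, c) for c in np.linspace(1.0, 8.0, 20)]
        assert (np.diff(occs) >= 0).all()

    def test_bernoulli_planting_within_binomial_interval(self, template):
        """Bernoulli(p=0.75) bonding at n=2000 recovers 75 % within 99 % CI."""
        truth = qs.PlantedTruth(
            contacts=[qs.ContactPlant("Q1", "D", 0.75)],
            n_frames=2000, bend_deg=0.0, corr_pair=None,
        )
        ens, _ = qs.generate(template, truth, seed=13)
        contact = saltbridge_contacts(ens, template.mapping, "Q1")["D"]
        occ = qs.occupancy(qs.distance_series(ens, contact, FULL))
        half_width = 100 * 2.576 * np.sqrt(0.75 * 0.25 / 2000)
        assert abs(occ - 75.0) < half_width

    def test_rigid_motion_invariance(self, small_ensemble):
        ens, _ = small_ensemble
        rng = np.random.default_rng(5)
        rot, trans = random_rigid(rng)
        moved = qs.Ensemble(
            topology=ens.topology, coords=apply_rigid(ens.coords, rot, trans)
        )
        contact = qs.ContactDefinition(
            label="inv",
            donors=qs.SelectionSpec(chain_id="A", res_id=120, atom_name="NZ"),
            acceptors=qs.SelectionSpec(chain_id="E", atom_name=("O6", "N7")),
        )
        a = qs.distance_series(ens, contact, FULL)
        b = qs.distance_series(moved, contact, FULL)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)
        assert qs.occupancy(a) == qs.occupancy(b)


class TestBondMode:
    @pytest.mark.parametrize(
        "distances,base,expected",
        [
            ({"O6": 2.8, "N7": 3.1}, "G", qs.HBondMode.THREE_CENTERED),
            ({"O6": 2.8, "N7": 4.0}, "G", qs.HBondMode.TWO_CENTERED),
            ({"O4": 3.0}, "T", qs.HBondMode.TWO_CENTERED),
            ({"N7": 4.2}, "A", qs.HBondMode.NONE),
            ({}, "C", qs.HBondMode.NONE),
        ],
    )
    def test_classification(self, distances, base, expected):
        assert qs.classify_mode(distances, base) == expected


class TestFingerprints:
    def test_initial_frame_is_fully_bonded_at_position2(self, template):
        lys = qs.lys120_fingerprint(
            template.ensemble, template.re, template.mapping, FULL
        )
        assert lys["Q1:2a"].occupancy == 100.0
        for row in lys.rows:
            if row.label not in ("Q1:2a", "Q2:1a", "Q2:2b"):
                assert row.occupancy == 0.0

    def test_cytosine_rows_are_structural_zero(self, template):
        lys = qs.lys120_fingerprint(
            template.ensemble, template.re, template.mapping, FULL
        )
        assert "no major-groove acceptor" in lys["Q1:2b"].note
        assert lys["Q1:2b"].occupancy == 0.0

    def test_planted_occupancies_recovered(self, template):
        """Planted (0.0, 0.9, 0.3) at positions 1-3 recovered within binomial noise."""
        truth = qs.PlantedTruth(
            contacts=[
                qs.ContactPlant("Q1", "lys120", 0.0, position=1),
                qs.ContactPlant("Q1", "lys120", 0.9, position=2),
                qs.ContactPlant("Q1", "lys120", 0.3, position=3),
            ],
            n_frames=2000, bend_deg=0.0, corr_pair=None,
        )
        ens, record = qs.generate(template, truth, seed=17)
        lys = qs.lys120_fingerprint(ens, template.re, template.mapping, FULL)
        for position, planted in ((1, 0.0), (2, 90.0), (3, 30.0)):
            measured = lys[f"Q1:{position}a"].occupancy
            drawn = record.planted_occupancy(f"Q1:lys120:p{position}")
            assert measured == pytest.approx(drawn, abs=0.31)
            assert measured == pytest.approx(planted, abs=3.0)

    def test_arg280_per_pair_decomposition(self, template):
        table, series = qs.arg280_contact(
            template.ensemble, template.re, template.mapping, "Q1", FULL
        )
        assert table["Q1:R280:min"].occupancy == 100.0
        assert set(series) == {"NH1-O6", "NH2-N7", "min", "mean"}
        np.testing.assert_allclose(
            series["mean"].values,
            (series["NH1-O6"].values + series["NH2-N7"].values) / 2,
        )
        assert (series["min"].values <= series["mean"].values + 1e-12).all()


class TestSaltBridges:
    def test_template_network_fully_formed(self, template):
        net = qs.saltbridge_network(template.ensemble, template.mapping, FULL)
        assert net["Q1"].as_tuple() == (100.0, 100.0, 100.0, 100.0)
        assert net["Q2"].as_tuple() == (100.0, 100.0, 100.0, 100.0)

    def test_published_shape_recovered(self, template):
        """The A-D pattern (1.0, 0.0, 0.96, 0.91) is recovered within binomial noise."""
        truth = qs.PlantedTruth(
            contacts=[
                qs.ContactPlant("Q1", "A", 1.0),
                qs.ContactPlant("Q1", "B", 0.0),
                qs.ContactPlant("Q1", "C", 0.96),
                qs.ContactPlant("Q1", "D", 0.91),
            ],
            n_frames=2000, bend_deg=0.0, corr_pair=None,
        )
        ens, record = qs.generate(template, truth, seed=19)
        net = qs.saltbridge_network(ens, template.mapping, FULL)["Q1"]
        for key, occ, planted in zip("ABCD", net.as_tuple(), (100, 0, 96, 91)):
            assert occ == pytest.approx(planted, abs=3.0)
            assert occ == pytest.approx(
                record.planted_occupancy(f"Q1:{key}"), abs=0.2
            )

    def test_oracle_equality_on_small_fixture(self, small_ensemble, template):
        ens, _ = small_ensemble
        contacts = saltbridge_contacts(ens, template.mapping, "Q2")
        for contact in contacts.values():
            series = qs.distance_series(ens, contact, FULL)
            don = np.concatenate(
                [qs.select(ens, s) for s in np.atleast_1d(contact.donors)]
            )
            accs = contact.acceptors
            if isinstance(accs, qs.SelectionSpec):
                accs = [accs]
            acc = np.concatenate([qs.select(ens, s) for s in accs])
            # 1e-12-level differences are summation-order noise, far below
            # anything that could flip a 3.5 Å classification
            np.testing.assert_allclose(
                series.values, brute_force_min_distances(ens, don, acc),
                rtol=0, atol=1e-9,
            )


class TestArg248:
    def test_constant_geometry_series(self, template):
        s4, s5 = qs.arg248_distances(template.ensemble, template.mapping, "Q1", FULL)
        np.testing.assert_allclose(s4.values, 2.9, atol=1e-9)
        np.testing.assert_allclose(s5.values, 2.9, atol=1e-9)

    def test_ejected_residue_zero_occupancy(self, template):
        truth = qs.PlantedTruth(
            contacts=[
                qs.ContactPlant("Q1", "arg248_p4", 0.0),
                qs.ContactPlant("Q1", "arg248_p5", 0.0),
            ],
            n_frames=50, bend_deg=0.0, corr_pair=None,
        )
        ens, _ = qs.generate(template, truth, seed=23)
        s4, s5 = qs.arg248_distances(ens, template.mapping, "Q1", FULL)
        assert qs.occupancy(s4) == 0.0
        assert qs.occupancy(s5) == 0.0
        assert (s4.values > 3.5).all()


class TestCooccupancy:
    def test_perfect_and_anti_correlation(self):
        frames = np.arange(50)
        a = qs.DistanceSeries("a", frames, np.linspace(2, 6, 50))
        b = qs.DistanceSeries("b", frames, a.values.copy())
        r, _ = qs.cooccupancy_correlation(a, b)
        assert r == pytest.approx(1.0)
        c = qs.DistanceSeries("c", frames, -a.values + 8.0)
        r, _ = qs.cooccupancy_correlation(a, c)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_reports_nan(self):
        frames = np.arange(5)
        a = qs.DistanceSeries("a", frames, np.full(5, 4.0))
        b = qs.DistanceSeries("b", frames, np.linspace(2, 6, 5))
        r, frac = qs.cooccupancy_correlation(a, b)
        assert np.isnan(r)
        assert frac == pytest.approx(np.mean(b.values > 3.5))

    def test_coupled_disruption_fraction(self, template):
        """Jointly broken Lys120/Arg280 frames occur at the planted joint rate."""
        from quartersite.interface_contacts import _lys_contact

        ens, record = qs.coupled_disruption_scenario(
            template, p_joint=0.4, p_solo=0.0, n_frames=2000, seed=29
        )
        contact, _, _ = _lys_contact(ens, template.mapping, "Q1", 2, False, 3.5)
        s_lys = qs.distance_series(ens, contact, FULL)
        s_arg = qs.distance_series(
            ens, saltbridge_contacts(ens, template.mapping, "Q1")["A"], FULL
        )
        r, co = qs.cooccupancy_correlation(s_lys, s_arg)
        planted = np.mean(
            ~record.states["Q1:lys120:p2"] & ~record.states["Q1:A"]
        )
        assert co == pytest.approx(planted, abs=1e-9)
        assert co == pytest.approx(0.4, abs=0.03)
        assert r > 0.8  # joint breaking couples the two distances

    def test_independent_disruption_near_chance(self, template):
        from quartersite.interface_contacts import _lys_contact

        ens, _ = qs.coupled_disruption_scenario(
            template, p_joint=0.0, p_solo=0.5, n_frames=2000, seed=31
        )
        contact, _, _ = _lys_contact(ens, template.mapping, "Q1", 2, False, 3.5)
        s_lys = qs.distance_series(ens, contact, FULL)
        s_arg = qs.distance_series(
            ens, saltbridge_contacts(ens, template.mapping, "Q1")["A"], FULL
        )
        _, co = qs.cooccupancy_correlation(s_lys, s_arg)
        assert co == pytest.approx(0.25, abs=0.03)


class TestLeakage:
    def test_state_classification_mismatch_below_one_permille(self, template):
        """Measured bonded/unbonded states match the drawn states (< 0.1 %)."""
        truth = qs.default_truth(2000)
        ens, record = qs.generate(template, truth, seed=1)
        mismatches = 0
        total = 0
        for quarter in ("Q1", "Q2"):
            contacts = saltbridge_contacts(ens, template.mapping, quarter)
            for kind in "ABCD":
                series = qs.distance_series(ens, contacts[kind], FULL)
                measured = series.values <= 3.5
                drawn = record.states[f"{quarter}:{kind}"]
                mismatches += int((measured != drawn).sum())
                total += len(drawn)
            for kind, series in zip(
                ("arg248_p4", "arg248_p5"),
                qs.arg248_distances(ens, template.mapping, quarter, FULL),
            ):
                measured = series.values <= 3.5
                drawn = record.states[f"{quarter}:{kind}"]
                mismatches += int((measured != drawn).sum())
                total += len(drawn)
        assert total == 2 * 6 * 2000
        assert mismatches / total < 0.001
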