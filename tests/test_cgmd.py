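"""Periodic geometry, contacts, nonbonded energies, free-energy landscapes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gomech import cgmd, synth
from gomech.cgmd import BeadFrame, Topology
from gomech.errors import AmbiguityError, InvalidParameterError


def brute_min_image(a, b, box):
    """27-image oracle for the minimum-image distance."""
    best = np.inf
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                shift = box * np.array([sx, sy, sz], dtype=float)
                best = min(best, float(np.linalg.norm(np.asarray(b) + shift - a)))
    return best


def random_system(rng, n_a=20, n_b=20, box=5.0, charged=True):
    n = n_a + n_b
    pos = rng.uniform(0, box, (n, 3))
    top = Topology(
        types=np.array(["A"] * n_a + ["B"] * n_b, dtype=object),
        charges=rng.uniform(-1, 1, n) if charged else np.zeros(n),
        groups=np.array(["actinA"] * n_a + ["actinB"] * n_b, dtype=object),
        lj_params={
            ("A", "A"): (0.47, 3.5),
            ("A", "B"): (0.47, 2.8),
            ("B", "B"): (0.43, 3.1),
        },
    )
    return BeadFrame(positions=pos, box=box), top


class TestGOSheet:
    @pytest.mark.parametrize(
        "fraction, expected_sp1", [(0.48, 4800), (0.0, 0), (1.0, 10000)]
    )
    def test_oxidation_fraction_is_exact(self, fraction, expected_sp1):
        sheet = cgmd.build_go_sheet(50, 100, oxidation_fraction=fraction, seed=0)
        assert sheet.n_beads == 10000
        assert sheet.n_sp1 == expected_sp1

    def test_bond_graph_is_connected(self):
        import networkx as nx

        sheet = cgmd.build_go_sheet(6, 8, seed=1)
        g = nx.Graph(sheet.bonds.tolist())
        g.add_nodes_from(range(sheet.n_beads))
        assert nx.is_connected(g)

    def test_nearest_neighbor_spacing_is_the_lattice_constant(self):
        sheet = cgmd.build_go_sheet(5, 5, lattice_spacing=0.24, seed=0)
        d = np.linalg.norm(
            sheet.positions[sheet.bonds[:, 0]] - sheet.positions[sheet.bonds[:, 1]],
            axis=1,
        )
        assert np.allclose(d, 0.24, atol=1e-9)

    def test_seeded_oxidation_is_reproducible(self):
        a = cgmd.build_go_sheet(10, 10, seed=5)
        b = cgmd.build_go_sheet(10, 10, seed=5)
        assert np.array_equal(a.types, b.types)


class TestMinImage:
    def test_wrapped_neighbors_are_close(self):
        assert cgmd.min_image_distance((1, 0, 0), (24, 0, 0), 25.0) == pytest.approx(
            2.0
        )

    def test_zero_for_identical_points(self):
        assert cgmd.min_image_distance((3, 4, 5), (3, 4, 5), 25.0) == 0.0

    def test_matches_27_image_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            a, b = rng.uniform(0, 5.0, (2, 3))
            assert cgmd.min_image_distance(a, b, 5.0) == pytest.approx(
                brute_min_image(a, b, 5.0), rel=1e-10
            )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(-10, 30, (2, 3))
        box = 7.3
        d_ab = cgmd.min_image_distance(a, b, box)
        d_ba = cgmd.min_image_distance(b, a, box)
        assert d_ab == pytest.approx(d_ba, rel=1e-12)
        assert 0 <= d_ab <= box * np.sqrt(3) / 2 + 1e-9


class TestGroupCOM:
    def test_single_bead_group_is_its_position(self):
        frame = BeadFrame(positions=[[1.0, 2.0, 3.0]], box=25.0)
        top = Topology(
            types=np.array(["A"], dtype=object),
            charges=np.zeros(1),
            groups=np.array(["actinA"], dtype=object),
        )
        assert np.allclose(cgmd.group_com(frame, top, "actinA"), [1.0, 2.0, 3.0])

    def test_cluster_straddling_boundary_has_com_inside_cluster(self):
        pos = np.array([[24.8, 1, 1], [0.2, 1, 1]])  # wraps across x = 0
        frame = BeadFrame(positions=pos, box=25.0)
        top = Topology(
            types=np.array(["A", "A"], dtype=object),
            charges=np.zeros(2),
            groups=np.array(["actinA", "actinA"], dtype=object),
        )
        com = cgmd.group_com(frame, top, "actinA")
        assert com[0] == pytest.approx(0.0, abs=1e-9) or com[0] == pytest.approx(
            25.0, abs=1e-9
        )

    def test_group_spanning_half_box_is_ambiguous(self):
        pos = np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]])
        frame = BeadFrame(positions=pos, box=25.0)
        top = Topology(
            types=np.array(["A"] * 3, dtype=object),
            charges=np.zeros(3),
            groups=np.array(["actinA"] * 3, dtype=object),
        )
        with pytest.raises(AmbiguityError):
            cgmd.group_com(frame, top, "actinA")

    def test_dimer_fixture_at_printed_separation(self):
        traj = synth.gen_dimer_frames([3.5], jitter_sd=0.0, seed=0)
        d = cgmd.com_distance(traj.frames[0], traj.topology, "actinA", "actinB")
        assert d == pytest.approx(3.5, abs=1e-9)

    def test_jittered_series_mean_within_sampling_error(self):
        sep, n, jit = 4.0, 100, 0.05
        traj = synth.gen_dimer_frames([sep] * n, jitter_sd=jit, seed=3)
        _, dists = cgmd.com_distance_series(
            traj.frames, traj.topology, "actinA", "actinB"
        )
        se = dists.std(ddof=1) / np.sqrt(n)
        assert abs(dists.mean() - sep) < 3.0 * se + 1e-6

    def test_identical_groups_give_zero_distance(self):
        frame = BeadFrame(positions=[[1, 1, 1], [2, 2, 2]], box=25.0)
        top = Topology(
            types=np.array(["A", "A"], dtype=object),
            charges=np.zeros(2),
            groups=np.array(["g", "g"], dtype=object),
        )
        assert cgmd.com_distance(frame, top, "g", "g") == 0.0


class TestContacts:
    def test_single_close_pair_detected(self):
        frame = BeadFrame(positions=[[1, 1, 1], [1.5, 1, 1]], box=25.0)
        top = Topology(
            types=np.array(["A", "B"], dtype=object),
            charges=np.zeros(2),
            groups=np.array(["actinA", "actinB"], dtype=object),
        )
        contacts = cgmd.reference_contacts(frame, top, "actinA", "actinB", cutoff=0.6)
        assert len(contacts) == 1

    def test_distant_groups_have_no_contacts(self):
        frame = BeadFrame(positions=[[1, 1, 1], [6, 1, 1]], box=25.0)
        top = Topology(
            types=np.array(["A", "B"], dtype=object),
            charges=np.zeros(2),
            groups=np.array(["actinA", "actinB"], dtype=object),
        )
        with pytest.warns(UserWarning, match="no native contacts"):
            contacts = cgmd.reference_contacts(
                frame, top, "actinA", "actinB", cutoff=0.6
            )
        assert len(contacts) == 0

    def test_reference_matches_pair_loop_oracle(self, rng):
        traj = synth.gen_dimer_frames(
            [2.0], beads_per_cluster=50, cluster_radius=1.5, jitter_sd=0.0, seed=8
        )
        frame = traj.frames[0]
        contacts = cgmd.reference_contacts(
            frame, traj.topology, "actinA", "actinB", cutoff=0.8
        )
        expected = set()
        for i in range(50):
            for j in range(50, 100):
                if brute_min_image(frame.positions[i], frame.positions[j], frame.box) < 0.8:
                    expected.add((i, j))
        assert set(map(tuple, contacts.pairs)) == expected

    def test_reference_frame_retains_all_contacts(self):
        traj = synth.gen_dimer_frames([2.5], cluster_radius=1.5, seed=2)
        frame = traj.frames[0]
        contacts = cgmd.reference_contacts(
            frame, traj.topology, "actinA", "actinB", cutoff=0.9
        )
        assert cgmd.count_contacts(frame, contacts) == len(contacts)

    def test_translated_group_loses_all_contacts(self):
        traj = synth.gen_dimer_frames([2.0], cluster_radius=1.5, seed=2)
        frame = traj.frames[0]
        contacts = cgmd.reference_contacts(
            frame, traj.topology, "actinA", "actinB", cutoff=0.9
        )
        assert len(contacts) > 0
        moved = frame.positions.copy()
        moved[50:] += np.array([10.0, 0.0, 0.0])
        assert cgmd.count_contacts(BeadFrame(moved, box=frame.box), contacts) == 0

    def test_count_matches_brute_force_on_jittered_frame(self):
        traj = synth.gen_dimer_frames(
            [2.0, 2.2], cluster_radius=1.5, jitter_sd=0.1, seed=4
        )
        ref = traj.frames[0]
        contacts = cgmd.reference_contacts(
            ref, traj.topology, "actinA", "actinB", cutoff=0.9
        )
        frame = traj.frames[1]
        expected = sum(
            1
            for i, j in contacts.pairs
            if brute_min_image(frame.positions[i], frame.positions[j], frame.box) < 0.9
        )
        assert cgmd.count_contacts(frame, contacts) == expected

    def test_out_of_range_indices_rejected(self):
        traj = synth.gen_dimer_frames([2.0], seed=0)
        contacts = cgmd.reference_contacts(
            traj.frames[0], traj.topology, "actinA", "actinB", cutoff=0.9
        )
        small = BeadFrame(positions=np.zeros((3, 3)), box=25.0)
        if len(contacts):
            with pytest.raises(InvalidParameterError):
                cgmd.count_contacts(small, contacts)


class TestEnergies:
    def test_lj_minimum_is_minus_epsilon(self):
        sigma, eps = 0.47, 3.5
        frame = BeadFrame(
            positions=[[1, 1, 1], [1 + 2 ** (1 / 6) * sigma, 1, 1]], box=25.0
        )
        top = Topology(
            types=np.array(["A", "A"], dtype=object),
            charges=np.zeros(2),
            groups=np.array(["actinA", "actinB"], dtype=object),
            lj_params={("A", "A"): (sigma, eps)},
        )
        e = cgmd.lj_energy(frame, top, ("actinA", "actinB"), mode="plain")
        assert e == pytest.approx(-eps, rel=1e-12)

    def test_pairs_beyond_cutoff_contribute_nothing(self):
        frame = BeadFrame(positions=[[1, 1, 1], [2.5, 1, 1]], box=25.0)
        top = Topology(
            types=np.array(["A", "A"], dtype=object),
            charges=np.array([1.0, 1.0]),
            groups=np.array(["actinA", "actinB"], dtype=object),
            lj_params={("A", "A"): (0.47, 3.5)},
        )
        for mode in ("plain", "plain_shift", "force_switch"):
            assert cgmd.lj_energy(frame, top, ("actinA", "actinB"), mode=mode) == 0.0
        assert cgmd.coulomb_energy(frame, top, ("actinA", "actinB")) == 0.0

    @pytest.mark.parametrize("mode", ["plain", "plain_shift", "force_switch"])
    def test_lj_matches_double_loop_oracle(self, mode, rng):
        frame, top = random_system(rng)
        result = cgmd.lj_energy(frame, top, ("actinA", "actinB"), mode=mode)
        expected = 0.0
        r_cut, r_switch = 1.2, 0.9
        for i in range(20):
            for j in range(20, 40):
                r = brute_min_image(frame.positions[i], frame.positions[j], frame.box)
                if r >= r_cut:
                    continue
                sigma, eps = top.lj(top.types[i], top.types[j])
                sr6 = (sigma / r) ** 6
                if mode == "force_switch":
                    for c, p in ((4 * eps * sigma**12, 12), (-4 * eps * sigma**6, 6)):
                        d = r_cut - r_switch
                        A = -p * c * ((p + 4) * r_cut - (p + 1) * r_switch) / (
                            r_cut ** (p + 2) * d**2
                        )
                        B = p * c * ((p + 3) * r_cut - (p + 1) * r_switch) / (
                            r_cut ** (p + 2) * d**3
                        )
                        shift = c / r_cut**p - A / 3 * d**3 - B / 4 * d**4
                        v = c / r**p - shift
                        if r > r_switch:
                            v -= A / 3 * (r - r_switch) ** 3 + B / 4 * (r - r_switch) ** 4
                        expected += v
                else:
                    v = 4 * eps * (sr6**2 - sr6)
                    if mode == "plain_shift":
                        sc6 = (sigma / r_cut) ** 6
                        v -= 4 * eps * (sc6**2 - sc6)
                    expected += v
        assert result == pytest.approx(expected, rel=1e-10)

    def test_force_switch_potential_and_force_vanish_at_cutoff(self):
        from gomech.cgmd import _force_switch_energy

        r_cut, r_switch = 1.2, 0.9
        for c, p in ((4 * 3.5 * 0.47**12, 12), (-4 * 3.5 * 0.47**6, 6)):
            r = np.array([r_cut - 1e-9])
            assert abs(_force_switch_energy(r, c, p, r_switch, r_cut)[0]) < 1e-10
            eps_ = 1e-6
            v1 = _force_switch_energy(np.array([r_cut - 2 * eps_]), c, p, r_switch, r_cut)[0]
            v2 = _force_switch_energy(np.array([r_cut - eps_]), c, p, r_switch, r_cut)[0]
            assert abs((v1 - v2) / eps_) < 1e-6  # force ~ 0 at the cutoff

    def test_coulomb_unit_charges_at_one_nanometer(self):
        frame = BeadFrame(positions=[[1, 1, 1], [2, 1, 1]], box=25.0)
        top = Topology(
            types=np.array(["A", "A"], dtype=object),
            charges=np.array([1.0, 1.0]),
            groups=np.array(["actinA", "actinB"], dtype=object),
        )
        e = cgmd.coulomb_energy(frame, top, ("actinA", "actinB"), mode="plain")
        assert e == pytest.approx(138.935 / 15.0, rel=1e-12)

    def test_neutral_frame_has_zero_coulomb_energy(self, rng):
        frame, top = random_system(rng, charged=False)
        assert cgmd.coulomb_energy(frame, top, ("actinA", "actinB")) == 0.0

    def test_reaction_field_matches_double_loop_oracle(self, rng):
        frame, top = random_system(rng)
        result = cgmd.coulomb_energy(frame, top, ("actinA", "actinB"))
        expected = 0.0
        r_cut, eps_r = 1.2, 15.0
        for i in range(20):
            for j in range(20, 40):
                r = brute_min_image(frame.positions[i], frame.positions[j], frame.box)
                if r >= r_cut:
                    continue
                qq = top.charges[i] * top.charges[j]
                expected += (
                    138.935 * qq / eps_r
                    * (1 / r + r**2 / (2 * r_cut**3) - 3 / (2 * r_cut))
                )
        assert result == pytest.approx(expected, rel=1e-10)

    def test_translation_invariance_of_all_observables(self, rng):
        frame, top = random_system(rng)
        shift = np.array([1.7, -3.2, 11.0])
        moved = BeadFrame(positions=frame.positions + shift, box=frame.box)
        for mode in ("plain_shift", "force_switch"):
            assert cgmd.lj_energy(moved, top, ("actinA", "actinB"), mode=mode) == (
                pytest.approx(
                    cgmd.lj_energy(frame, top, ("actinA", "actinB"), mode=mode),
                    rel=1e-10,
                )
            )
        assert cgmd.coulomb_energy(moved, top, ("actinA", "actinB")) == pytest.approx(
            cgmd.coulomb_energy(frame, top, ("actinA", "actinB")), rel=1e-10
        )
        contacts = cgmd.reference_contacts(frame, top, "actinA", "actinB", cutoff=1.0)
        assert cgmd.count_contacts(moved, contacts) == cgmd.count_contacts(
            frame, contacts
        )
        # COM distance on compact clusters (a dilute gas has no unique COM)
        traj = synth.gen_dimer_frames([3.0], cluster_radius=1.0, seed=1)
        dimer = traj.frames[0]
        moved_dimer = BeadFrame(positions=dimer.positions + shift, box=dimer.box)
        assert cgmd.com_distance(
            moved_dimer, traj.topology, "actinA", "actinB"
        ) == pytest.approx(
            cgmd.com_distance(dimer, traj.topology, "actinA", "actinB"), rel=1e-9
        )


class TestFreeEnergy:
    def test_occupied_minimum_is_exactly_zero(self):
        cv = synth.gen_cv_samples((0, 0), np.eye(2), 5000, seed=0)
        landscape = cgmd.free_energy_2d(cv.x, cv.y, 20, 20)
        assert np.nanmin(landscape.F) == 0.0
        assert np.all(landscape.F[~np.isnan(landscape.F)] >= 0.0)

    def test_gaussian_minimum_bin_contains_the_center(self):
        cv = synth.gen_cv_samples(
            (3.22, 3.23), np.diag([0.01, 0.01]), 100000, seed=1
        )
        landscape = cgmd.free_energy_2d(
            cv.x, cv.y, np.arange(2.71, 3.76, 0.02), np.arange(2.72, 3.77, 0.02)
        )
        x, y, _ = landscape.global_minimum()
        assert abs(x - 3.22) <= 0.02
        assert abs(y - 3.23) <= 0.02

    def test_uniform_samples_have_small_free_energy_spread(self):
        rng = np.random.default_rng(0)
        n, nbins = 200000, 10
        x = rng.uniform(0, 1, n)
        y = rng.uniform(0, 1, n)
        landscape = cgmd.free_energy_2d(x, y, nbins, nbins)
        n_per_bin = n / nbins**2
        spread = np.nanmax(landscape.F) - np.nanmin(landscape.F)
        assert spread < 3.0 * np.sqrt(1.0 / n_per_bin) * landscape.kT * 2

    def test_quadratic_form_recovered_for_gaussian_samples(self):
        sigma = 0.1
        cv = synth.gen_cv_samples((0, 0), np.diag([sigma**2, sigma**2]), 200000, seed=2)
        edges = np.arange(-0.4, 0.41, 0.04)
        landscape = cgmd.free_energy_2d(cv.x, cv.y, edges, edges)
        xc, yc = np.meshgrid(landscape.x_centers, landscape.y_centers, indexing="ij")
        expected = 0.5 * landscape.kT * (xc**2 + yc**2) / sigma**2
        well = landscape.counts >= 100
        resid = landscape.F[well] - expected[well]
        resid -= resid.mean()  # both surfaces are defined up to a constant
        assert np.sqrt(np.mean(resid**2)) < 0.2 * landscape.kT

    def test_degenerate_landscape_warns(self):
        x = np.zeros(200)
        with pytest.warns(UserWarning, match="degenerate"):
            cgmd.free_energy_2d(x, x, 5, 5)


class TestFindMinima:
    def test_single_gaussian_yields_one_minimum_at_center(self):
        cv = synth.gen_cv_samples((0, 0), np.diag([0.04, 0.04]), 100000, seed=3)
        edges = np.arange(-1.1, 1.11, 0.2)
        landscape = cgmd.free_energy_2d(cv.x, cv.y, edges, edges)
        minima = cgmd.find_minima(landscape, depth_threshold=1.0, min_count=10)
        assert len(minima) == 1
        assert abs(minima[0][0]) <= 0.2 and abs(minima[0][1]) <= 0.2

    def test_two_gaussian_mixture_yields_two_minima_at_reported_bins(self):
        half = 50000
        a = synth.gen_cv_samples((750, 1300), np.diag([400.0, 400.0]), half, seed=4)
        b = synth.gen_cv_samples((850, 1400), np.diag([400.0, 400.0]), half, seed=5)
        x = np.concatenate([a.x, b.x])
        y = np.concatenate([a.y, b.y])
        landscape = cgmd.free_energy_2d(
            x, y, np.arange(640, 970, 20.0), np.arange(1190, 1520, 20.0)
        )
        minima = cgmd.find_minima(landscape, depth_threshold=1.0, min_count=10)
        assert len(minima) == 2
        centers = sorted((m[0], m[1]) for m in minima)
        assert abs(centers[0][0] - 750) <= 20 and abs(centers[0][1] - 1300) <= 20
        assert abs(centers[1][0] - 850) <= 20 and abs(centers[1][1] - 1400) <= 20

    def test_flat_landscape_has_no_minima(self):
        x = np.tile(np.arange(5, dtype=float) + 0.5, 100)
        y = np.repeat(np.arange(5, dtype=float) + 0.5, 100)
        landscape = cgmd.free_energy_2d(x, y, np.arange(6.0), np.arange(6.0))
        assert cgmd.find_minima(landscape) == []
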