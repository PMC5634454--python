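"""Synthetic partitioned surface: exactness of the per-atom accounting,
location and quality of the reference minimum, label noise and L(Ω)."""

import numpy as np
import pytest

import krigforce as kf
from krigforce.pes import DEFAULT_PARAMS, PESParameters, water_geometry, zeroed

CONN = [(0, 1), (0, 2)]


def _random_water(rng):
    return water_geometry(
        rng.uniform(0.8, 1.15),
        rng.uniform(0.8, 1.15),
        rng.uniform(np.radians(86), np.radians(128)),
    )


def test_partition_identity_exact_on_random_geometries():
    """Σ_A [E_intra + ½(V_cl + V_x)] equals the molecular total exactly."""
    rng = np.random.default_rng(0)
    for _ in range(1000):
        geom = _random_water(rng)
        dec = kf.evaluate_components(geom, connectivity=CONN)
        total = np.sum(
            dec.e_intra + 0.5 * (dec.v_cl + dec.v_x)
        )
        assert abs(total - dec.molecular_total) <= 1e-10
        np.testing.assert_allclose(
            dec.e_iqa, dec.e_intra + 0.5 * (dec.v_cl + dec.v_x), atol=0
        )


def test_components_rigid_motion_invariant():
    rng = np.random.default_rng(1)
    for _ in range(25):
        geom = _random_water(rng)
        t = rng.uniform(0, np.pi)
        c, s = np.cos(t), np.sin(t)
        q = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        moved = geom.with_coordinates(geom.coordinates @ q.T + rng.uniform(-3, 3, 3))
        d1 = kf.evaluate_components(geom, connectivity=CONN)
        d2 = kf.evaluate_components(moved, connectivity=CONN)
        for name in ("E_intra", "V_cl", "V_x"):
            np.testing.assert_allclose(
                d1.component(name), d2.component(name), atol=1e-10
            )


def test_symmetric_water_has_identical_hydrogen_components():
    geom = water_geometry(0.97, 0.97, 1.85)
    dec = kf.evaluate_components(geom, connectivity=CONN)
    for name in ("E_intra", "V_cl", "V_x"):
        comp = dec.component(name)
        assert comp[1] == pytest.approx(comp[2], abs=1e-12)


def test_zero_charges_kill_coulomb():
    params = PESParameters(charges={"O": 0.0, "H": 0.0})
    dec = kf.evaluate_components(
        water_geometry(0.95, 1.0, 1.8), params, connectivity=CONN
    )
    np.testing.assert_array_equal(dec.v_cl, 0.0)


def test_coincident_atoms_rejected():
    geom = kf.MolecularGeometry(
        ("O", "H", "H"), [[0, 0, 0], [0, 0, 1e-8], [0, 1, 0]]
    )
    with pytest.raises(ValueError, match="coincident"):
        kf.evaluate_components(geom, connectivity=CONN)


class TestReferenceMinimum:
    def test_gradient_vanishes_at_fixture(self, ref_min):
        geom, _ = ref_min
        h = 1e-6
        grad = np.zeros(9)
        for k in range(9):
            cp, cm = geom.coordinates.copy(), geom.coordinates.copy()
            cp.flat[k] += h
            cm.flat[k] -= h
            grad[k] = (
                kf.total_energy(geom.with_coordinates(cp), connectivity=CONN)
                - kf.total_energy(geom.with_coordinates(cm), connectivity=CONN)
            ) / (2 * h)
        assert np.linalg.norm(grad) <= 1e-6

    def test_minimum_geometry_in_target_window(self, ref_min):
        geom, _ = ref_min
        assert 0.90 <= geom.distance(0, 1) <= 1.00
        assert 0.90 <= geom.distance(0, 2) <= 1.00
        assert 100.0 <= np.degrees(geom.angle(1, 0, 2)) <= 110.0

    def test_stretch_raises_energy(self, ref_min):
        geom, e_min = ref_min
        stretched = water_geometry(
            geom.distance(0, 1) * 1.05,
            geom.distance(0, 2) * 1.05,
            geom.angle(1, 0, 2),
        )
        assert e_min < kf.total_energy(stretched, connectivity=CONN)

    def test_energy_reproducible(self, ref_min):
        geom2, e2 = kf.reference_minimum()
        assert abs(e2 - ref_min[1]) <= 1e-8

    def test_boundary_minimum_rejected(self):
        bad = PESParameters(morse_r0=2.0)  # pushes the minimizer off the box
        with pytest.raises(ValueError, match="boundary"):
            kf.reference_minimum(bad)


class TestComponentPreferences:
    """Each energy term, alone, drifts the geometry the way the full
    decomposition's chemistry says it should."""

    def test_coulomb_only_energy_decreases_with_angle(self, ref_min):
        geom, _ = ref_min
        params = zeroed(DEFAULT_PARAMS, {"V_cl"})
        r1, r2 = geom.distance(0, 1), geom.distance(0, 2)
        t0 = geom.angle(1, 0, 2)
        h = 1e-5
        dv = (
            kf.total_energy(water_geometry(r1, r2, t0 + h), params, CONN)
            - kf.total_energy(water_geometry(r1, r2, t0 - h), params, CONN)
        ) / (2 * h)
        assert dv < 0  # like-charged hydrogens: opening the angle relaxes V_cl

    def test_exchange_only_prefers_shorter_bonds(self, ref_min):
        geom, _ = ref_min
        params = zeroed(DEFAULT_PARAMS, {"V_x"})
        r_star = geom.distance(0, 1)
        rs = np.linspace(0.78, 1.14, 50)
        energies = [
            kf.total_energy(water_geometry(r, r, geom.angle(1, 0, 2)), params, CONN)
            for r in rs
        ]
        assert rs[int(np.argmin(energies))] < r_star


def test_total_energy_smooth_along_random_lines(ref_min):
    """No cusps: second differences of line scans stay bounded."""
    geom, _ = ref_min
    rng = np.random.default_rng(9)
    for _ in range(5):
        direction = rng.normal(size=(3, 3))
        direction -= direction.mean(axis=0)
        direction /= np.linalg.norm(direction)
        ts = np.linspace(-0.08, 0.08, 81)
        es = np.array(
            [
                kf.total_energy(
                    geom.with_coordinates(geom.coordinates + t * direction),
                    connectivity=CONN,
                )
                for t in ts
            ]
        )
        second = np.diff(es, 2) / (ts[1] - ts[0]) ** 2
        assert np.all(np.abs(np.diff(second)) < 50.0)  # curvature varies smoothly


class TestLabelNoise:
    def test_zero_sigma_is_identity(self, ref_min):
        geom, _ = ref_min
        dec = kf.evaluate_components(geom, connectivity=CONN)
        ex = kf.add_label_noise(dec, geom, 0.0, 1)
        np.testing.assert_array_equal(ex.noisy.e_intra, dec.e_intra)
        np.testing.assert_array_equal(ex.noisy.v_cl, dec.v_cl)
        np.testing.assert_array_equal(ex.noisy.v_x, dec.v_x)

    def test_sample_sd_matches_sigma(self, ref_min):
        geom, _ = ref_min
        dec = kf.evaluate_components(geom, connectivity=CONN)
        rng = np.random.default_rng(12)
        draws = np.array(
            [
                kf.add_label_noise(dec, geom, 0.1, rng).noisy.e_intra
                - dec.e_intra
                for _ in range(3500)
            ]
        ).ravel()  # 10,500 perturbations
        assert np.std(draws) == pytest.approx(0.1, rel=0.05)

    def test_same_seed_reproduces_labels(self, ref_min):
        geom, _ = ref_min
        dec = kf.evaluate_components(geom, connectivity=CONN)
        a = kf.add_label_noise(dec, geom, 0.2, 42)
        b = kf.add_label_noise(dec, geom, 0.2, 42)
        np.testing.assert_array_equal(a.noisy.e_intra, b.noisy.e_intra)
        np.testing.assert_array_equal(a.lomega, b.lomega)

    def test_negative_sigma_rejected(self, ref_min):
        geom, _ = ref_min
        dec = kf.evaluate_components(geom, connectivity=CONN)
        with pytest.raises(ValueError):
            kf.add_label_noise(dec, geom, -0.1, 0)

    def test_lomega_tail_spans_both_scrub_thresholds(self, ref_min):
        """The loose (0.001 a.u.) and tight (0.00005 a.u.) thresholds must
        each catch a different, non-empty slice of the L(Ω) distribution."""
        geom, _ = ref_min
        dec = kf.evaluate_components(geom, connectivity=CONN)
        rng = np.random.default_rng(77)
        lom = np.array(
            [kf.add_label_noise(dec, geom, 0.0, rng).lomega for _ in range(4000)]
        ).ravel()
        frac_loose = np.mean(lom > 1e-3)
        frac_tight = np.mean(lom > 5e-5)
        assert 0.005 < frac_loose < 0.05
        assert frac_tight > frac_loose + 0.005
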