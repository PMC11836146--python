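"""Green–Lagrange strain, fiber projection, and tract-strain measures."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from helmstrain import tractstrain as ts
from helmstrain.errors import DataError, ParameterError


def uniaxial(stretch, axis=0):
    F = np.eye(3)
    F[axis, axis] = stretch
    return F


def random_rotation(seed):
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


def random_deformation(rng, scale=0.3):
    return np.eye(3) + scale * rng.uniform(-1, 1, (3, 3))


def random_unit(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


class TestGreenLagrange:
    def test_identity_gives_zero(self):
        np.testing.assert_allclose(ts.green_lagrange(np.eye(3)), 0.0)

    def test_uniaxial_stretch(self):
        E = ts.green_lagrange(uniaxial(1.2))
        assert E[0, 0] == pytest.approx(0.22)
        assert np.abs(E).sum() == pytest.approx(0.22)

    def test_simple_shear(self):
        F = np.eye(3)
        F[0, 1] = 0.5
        E = ts.green_lagrange(F)
        assert E[0, 1] == pytest.approx(0.25)
        assert E[1, 1] == pytest.approx(0.125)
        assert E[0, 0] == pytest.approx(0.0)

    def test_rigid_rotation_strain_free(self):
        E = ts.green_lagrange(random_rotation(3))
        np.testing.assert_allclose(E, 0.0, atol=1e-14)


class TestMPS:
    def test_uniaxial_peak(self):
        series = np.stack([np.eye(3), uniaxial(1.2)])
        _, peak = ts.mps_history(ts.green_lagrange(series))
        assert peak == pytest.approx(0.22)

    def test_simple_shear_closed_form(self):
        F = np.eye(3)
        F[0, 1] = 0.5
        peak = ts.principal_strain(ts.green_lagrange(F))
        assert peak == pytest.approx((0.125 + np.sqrt(0.265625)) / 2, rel=1e-12)

    def test_matches_cubic_root_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            A = rng.normal(0, 0.3, (3, 3))
            E = 0.5 * (A + A.T)
            # characteristic polynomial det(E - x I) = 0
            coeffs = np.poly(E)
            roots = np.roots(coeffs)
            assert ts.principal_strain(E) == pytest.approx(
                np.max(roots.real), rel=1e-9, abs=1e-12)


class TestFiberDirection:
    def test_identity_keeps_reference(self):
        a0 = np.array([0.6, 0.8, 0.0])
        np.testing.assert_allclose(
            ts.realtime_fiber_direction(np.eye(3), a0), a0)

    def test_uniaxial_image(self):
        a0 = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        got = ts.realtime_fiber_direction(uniaxial(1.2), a0)
        expected = np.array([1.2, 1.0, 0.0]) / np.sqrt(2.44)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_rigid_rotation_rotates_fiber(self):
        R = random_rotation(5)
        a0 = random_unit(np.random.default_rng(6))
        np.testing.assert_allclose(
            ts.realtime_fiber_direction(R, a0), R @ a0, atol=1e-14)


def histories_for(F, a0, **kw):
    """Single-element, single-time tract strains as plain floats."""
    out = ts.tract_strain_histories(F[None, None], np.asarray(a0)[None], **kw)
    return {k: float(v[0, 0]) for k, v in out.items()}


class TestTractStrains:
    def test_fiber_along_stretch_axis(self):
        h = histories_for(uniaxial(1.2), [1.0, 0.0, 0.0])
        assert h["ton"] == pytest.approx(0.22, rel=1e-12)
        assert h["tpn"] == pytest.approx(0.0, abs=1e-14)
        assert h["tos"] == pytest.approx(0.0, abs=1e-14)
        assert h["tps"] == pytest.approx(0.0, abs=1e-14)

    def test_fiber_perpendicular_to_stretch(self):
        h = histories_for(uniaxial(1.2), [0.0, 1.0, 0.0])
        assert h["ton"] == pytest.approx(0.0, abs=1e-14)
        assert h["tpn"] == pytest.approx(0.22, rel=1e-12)
        assert h["tos"] == pytest.approx(0.0, abs=1e-14)
        assert h["tps"] == pytest.approx(0.11, rel=1e-12)

    def test_oblique_fiber_uses_realtime_direction(self):
        a0 = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        h = histories_for(uniaxial(1.2), a0)
        # deformed direction: a^T E a = 0.22 * 1.44 / 2.44
        assert h["ton"] == pytest.approx(0.22 * 1.44 / 2.44, rel=1e-12)
        # reference-direction convention gives the discriminating 0.11
        h_ref = histories_for(uniaxial(1.2), a0, reference_fiber=True)
        assert h_ref["ton"] == pytest.approx(0.11, rel=1e-12)

    def test_rigid_motion_all_zero(self):
        R = random_rotation(9)
        a0 = random_unit(np.random.default_rng(10))
        h = histories_for(R, a0)
        assert all(abs(v) <= 1e-12 for v in h.values())

    def test_engineering_shear_doubles(self):
        rng = np.random.default_rng(12)
        F = random_deformation(rng)
        a0 = random_unit(rng)
        h1 = histories_for(F, a0)
        h2 = histories_for(F, a0, engineering_shear=True)
        assert h2["tos"] == pytest.approx(2 * h1["tos"], rel=1e-12)
        assert h2["tps"] == pytest.approx(2 * h1["tps"], rel=1e-12)

    def test_non_unit_fiber_rejected(self):
        with pytest.raises(DataError):
            histories_for(np.eye(3), [1.0, 1.0, 0.0])

    def test_perpendicular_sampling_oracle(self):
        """tpn/tps equal brute-force extremes over sampled perpendicular
        directions."""
        rng = np.random.default_rng(33)
        thetas = np.linspace(0, 2 * np.pi, 10_000, endpoint=False)
        for _ in range(20):
            F = random_deformation(rng)
            a0 = random_unit(rng)
            E = ts.green_lagrange(F)
            ahat = ts.realtime_fiber_direction(F, a0)
            b1, b2 = ts._perpendicular_basis(ahat)
            u = (np.cos(thetas)[:, None] * b1 + np.sin(thetas)[:, None] * b2)
            v = (-np.sin(thetas)[:, None] * b1 + np.cos(thetas)[:, None] * b2)
            normal = np.einsum("ki,ij,kj->k", u, E, u)
            shear = np.einsum("ki,ij,kj->k", u, E, v)
            h = histories_for(F, a0)
            assert h["tpn"] == pytest.approx(normal.max(), abs=1e-3)
            assert h["tps"] == pytest.approx(np.abs(shear).max(), abs=1e-3)

    def test_invariance_under_basis_rerandomization(self):
        """Outputs computed with a random perpendicular basis match the
        deterministic one to machine precision."""
        rng = np.random.default_rng(40)
        for _ in range(10):
            F = random_deformation(rng)
            a0 = random_unit(rng)
            E = ts.green_lagrange(F)
            e1 = ts.realtime_fiber_direction(F, a0)
            # random in-plane basis
            phi = rng.uniform(0, 2 * np.pi)
            b1, b2 = ts._perpendicular_basis(e1)
            e2 = np.cos(phi) * b1 + np.sin(phi) * b2
            e3 = -np.sin(phi) * b1 + np.cos(phi) * b2
            e22, e33 = e2 @ E @ e2, e3 @ E @ e3
            e23 = e2 @ E @ e3
            mean, rad = 0.5 * (e22 + e33), np.hypot(0.5 * (e22 - e33), e23)
            h = histories_for(F, a0)
            assert abs(h["tpn"] - (mean + rad)) <= 1e-12
            assert abs(h["tps"] - rad) <= 1e-12
            tos = np.hypot(e1 @ E @ e2, e1 @ E @ e3)
            assert abs(h["tos"] - tos) <= 1e-12

    def test_invariance_under_rigid_rotation(self):
        """Rotating reference and spatial frames together leaves all four
        measures unchanged."""
        rng = np.random.default_rng(50)
        for k in range(10):
            F = random_deformation(rng)
            a0 = random_unit(rng)
            R = random_rotation(100 + k)
            h = histories_for(F, a0)
            h_rot = histories_for(R @ F @ R.T, R @ a0)
            for key in h:
                assert abs(h[key] - h_rot[key]) <= 1e-12


class TestAccumulate:
    def test_monotone_growth_peaks_at_end(self):
        series = np.linspace(0, 0.3, 20)[None, :]
        peaks = ts.accumulate_peaks({"tpn": series})
        assert peaks["tpn"][0] == pytest.approx(0.3)

    def test_load_unload_keeps_mid_pulse_peak(self):
        t = np.linspace(0, 1, 50)
        pulse = 0.25 * np.sin(np.pi * t)[None, :]
        peaks = ts.accumulate_peaks({"ton": pulse})
        assert peaks["ton"][0] == pytest.approx(0.25, rel=1e-3)

    def test_mton_clamped_at_zero(self):
        compressive = np.full((1, 10), -0.1)
        peaks = ts.accumulate_peaks({"ton": compressive})
        assert peaks["ton"][0] == 0.0

    def test_random_series_matches_sort_oracle(self):
        rng = np.random.default_rng(8)
        series = rng.normal(0, 0.1, (5, 40))
        peaks = ts.accumulate_peaks({"tps": series})
        np.testing.assert_allclose(peaks["tps"],
                                   np.sort(series, axis=1)[:, -1])


class TestPercentile:
    def test_definition_oracle_1_to_100(self):
        assert ts.percentile_summary(np.arange(1.0, 101.0), 95) == \
            pytest.approx(95.05)

    def test_constant_field(self):
        assert ts.percentile_summary(np.full(40, 3.3), 95) == pytest.approx(3.3)

    def test_q100_is_max(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 1, 57)
        assert ts.percentile_summary(v, 100) == pytest.approx(v.max())

    def test_empty_mask_rejected(self):
        with pytest.raises(DataError):
            ts.percentile_summary(np.arange(5.0), 95,
                                  mask=np.zeros(5, dtype=bool))


@pytest.fixture(scope="module")
def small_peak_table():
    rng = np.random.default_rng(14)
    n_elem, n_t = 60, 5
    F = np.tile(np.eye(3), (n_elem, n_t, 1, 1))
    amp = rng.uniform(0, 0.2, n_elem)
    D = rng.normal(0, 1, (n_elem, 3, 3))
    D = 0.5 * (D + np.swapaxes(D, 1, 2))
    D /= np.abs(np.linalg.eigvalsh(D)).max(axis=1)[:, None, None]
    ramp = np.linspace(0, 1, n_t)
    F += amp[:, None, None, None] * ramp[None, :, None, None] * D[:, None]
    regions = np.array(["brain"] * 30 + ["white_matter"] * 15
                       + ["corpus_callosum"] * 10 + ["cerebellum_wm"] * 5)
    fibers = rng.standard_normal((30, 3))
    fibers /= np.linalg.norm(fibers, axis=1, keepdims=True)
    return ts.compute_peak_table(F, regions, fibers)


class TestPeakTable:
    def test_region_restrict_counts(self, small_peak_table):
        cc = ts.region_restrict(small_peak_table, "corpus_callosum")
        assert len(cc) == 10

    def test_region_partition(self, small_peak_table):
        counts = [len(ts.region_restrict(small_peak_table, r))
                  for r in ts.REGIONS]
        assert sum(counts) == len(small_peak_table)

    def test_unknown_region_lists_labels(self, small_peak_table):
        with pytest.raises(ParameterError, match="corpus_callosum"):
            ts.region_restrict(small_peak_table, "hippocampus")

    def test_full_region_keeps_summaries(self, small_peak_table):
        wm = small_peak_table[small_peak_table["region"].isin(ts.WM_REGIONS)]
        full = ts.summarize_peaks(small_peak_table)
        assert full["MTON"] == pytest.approx(
            ts.percentile_summary(wm["MTON"].to_numpy(), 95))

    def test_tract_columns_nan_outside_wm(self, small_peak_table):
        brain = small_peak_table[small_peak_table["region"] == "brain"]
        assert brain["MTON"].isna().all()
        assert np.isfinite(brain["MPS"]).all()

    def test_inverted_element_flagged_invalid(self):
        F = np.tile(np.eye(3), (3, 4, 1, 1))
        F[1, 2] = np.diag([-1.0, 1.0, 1.0])  # det < 0 at one time
        table = ts.compute_peak_table(F, ["brain"] * 3, None)
        assert table["valid"].tolist() == [True, False, True]
        assert ts.invalid_element_count(table) == 1

    def test_container_round_trip(self, tmp_path):
        rng = np.random.default_rng(18)
        F = np.tile(np.eye(3), (8, 3, 1, 1))
        F[:, 1:] += rng.normal(0, 0.05, (8, 2, 3, 3))
        regions = ["brain"] * 5 + ["white_matter"] * 3
        fibers = rng.standard_normal((3, 3))
        fibers /= np.linalg.norm(fibers, axis=1, keepdims=True)
        p = tmp_path / "impact.h5"
        ts.write_strain_container(p, np.linspace(0, 30, 3), F, regions, fibers,
                                  attrs={"helmet_id": "HelmetA"})
        back = ts.read_strain_container(p)
        np.testing.assert_array_equal(back["F"], F)
        assert back["regions"] == regions
        np.testing.assert_array_equal(back["fibers"], fibers)
        assert back["attrs"]["helmet_id"] == "HelmetA"


class TestEnsembleInvariants:
    def test_mton_bounded_by_mps(self, strain_results):
        """Along-fiber normal strain never exceeds the principal strain."""
        for key, table in strain_results["tables"].items():
            wm = table[table["region"].isin(ts.WM_REGIONS)]
            assert (wm["MTON"] <= wm["MPS"] + 1e-12).all(), key
            assert (wm["MTPN"] <= wm["MPS"] + 1e-12).all(), key

    def test_summaries_positive_and_ordered(self, strain_results):
        df = strain_results["summaries"]
        assert (df > 0).all().all()
        # tract summaries never exceed the whole-brain MPS summary scale
        assert (df["MTON"] <= df["MPS"]).all()
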