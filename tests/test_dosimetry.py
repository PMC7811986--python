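"""Dose quantities: body current, impedance, heart percentile, line integrals,
heart-current factors, and the qualitative anatomy effects."""

import dataclasses

import numpy as np
import pytest

import ccdosim as cd
from ccdosim.contact import BodyModelMode
from ccdosim.dosimetry import (
    DoseReport, body_current, e99_heart, hcf, heart_field_magnitudes,
    percentile99, sam_field, total_impedance,
)
from ccdosim.phantom import HEART_WALL, MUSCLE, VoxelPhantom
from ccdosim.solver import ContactScenario, FieldSolution

from conftest import BLOCK_PATH, constant_materials, solve_block


def synthetic_solution(e_field, labels, spacing=2.0, heart_axes=None):
    """Wrap a prescribed complex E grid as a FieldSolution."""
    phantom = VoxelPhantom(
        labels=labels, spacing=np.array([spacing] * 3, float),
        origin=np.zeros(3), tissue_map={MUSCLE: "muscle", HEART_WALL: "heart_muscle"},
        electrode_sites={}, electrode_normals={},
        heart_axes=heart_axes if heart_axes is not None else np.zeros((3, 2, 3)))
    scen = ContactScenario(path=BLOCK_PATH, frequency=50.0, touch_voltage=1.0,
                           mode=BodyModelMode.INTERN)
    return FieldSolution(
        potential=np.zeros(labels.shape, complex), frequency=50.0, residual=0.0,
        scenario=scen, phantom=phantom,
        sigma_star=np.where(labels != 0, 0.1 + 0.0j, 0.0),
        e_field=np.asarray(e_field, complex))


class TestBodyCurrent:
    def test_homogeneous_bar_closed_form(self, bar_solution):
        # I = sigma * A * U / L
        sol, _, _ = bar_solution
        cur = body_current(sol, n_planes=4)
        A = (5 * 2e-3) ** 2
        L = 10 * 2e-3
        assert abs(cur.value) == pytest.approx(0.5 * A * 1.0 / L, rel=1e-3)
        assert cur.spread < 1e-10

    def test_two_layer_bar_series_resistance(self):
        mats = constant_materials(m1=1.0, m2=0.25)
        labels = np.ones((13, 4, 4), np.uint8)
        labels[6:] = 2
        sol, _ = solve_block(labels, 2.0, mats, {1: "m1", 2: "m2"})
        cur = body_current(sol, n_planes=3)
        s, A = 2e-3, (8e-3) ** 2
        r_series = s / A * (5.5 / 1.0 + 6.5 / 0.25)
        assert abs(cur.value) == pytest.approx(1.0 / r_series, rel=1e-6)
        assert cur.spread < 1e-10

    def test_plane_missing_body_rejected(self, bar_solution):
        sol, _, _ = bar_solution
        with pytest.raises(ValueError, match="outside the grid"):
            body_current(sol, plane_indices=[99])

    def test_explicit_plane_selection_matches_auto(self, bar_solution):
        sol, _, _ = bar_solution
        auto = body_current(sol, n_planes=2)
        manual = body_current(sol, plane_indices=[3, 7])
        assert abs(auto.value) == pytest.approx(abs(manual.value), rel=1e-9)


class TestImpedance:
    def test_ohms_law(self):
        assert total_impedance(1.0, 1e-3 + 0j) == pytest.approx(1000.0)

    def test_zero_current_rejected(self):
        with pytest.raises(ValueError):
            total_impedance(1.0, 0.0)

    def test_skin_layer_raises_magnitude(self, tiny_phantom, dose_cached):
        # Total-BM strictly exceeds Intern-BM at ELF: the slice adds in series
        zt = abs(dose_cached(tiny_phantom, "LH-BF", frequency=50.0,
                             voltage=25.0, mode=BodyModelMode.TOTAL).z_total)
        zi = abs(dose_cached(tiny_phantom, "LH-BF", frequency=50.0,
                             voltage=25.0, mode=BodyModelMode.INTERN).z_total)
        assert zt > zi

    def test_total_bm_impedance_falls_with_frequency(self, tiny_phantom,
                                                     dose_cached):
        mags = [abs(dose_cached(tiny_phantom, "LH-BF", frequency=f,
                                voltage=25.0, mode=BodyModelMode.TOTAL).z_total)
                for f in (50.0, 1e4, 1e5)]
        assert mags[0] > mags[1] > mags[2]


class TestHeartPercentile:
    def test_uniform_field_returns_field_magnitude(self):
        labels = np.full((6, 6, 6), MUSCLE, np.uint8)
        labels[2:5, 2:5, 2:5] = HEART_WALL
        E = np.zeros(labels.shape + (3,))
        E[..., 0] = 3.0
        sol = synthetic_solution(E, labels)
        assert e99_heart(sol) == pytest.approx(3.0)

    def test_order_statistic_interpolation(self):
        # 100 magnitudes 1..100 -> 99th percentile 99.01
        assert percentile99(np.arange(1, 101)) == pytest.approx(99.01)

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(3)
        v = rng.random(500)
        assert percentile99(5.0 * v) == pytest.approx(5.0 * percentile99(v))

    def test_matches_brute_force_on_random_fields(self):
        # oracle: sort, then linearly interpolate between the two order
        # statistics bracketing rank 0.99*(n-1)
        rng = np.random.default_rng(42)
        for n in (5, 37, 100, 1000):
            v = rng.lognormal(size=n)
            srt = np.sort(v)
            pos = 0.99 * (n - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            expected = srt[lo] if lo == n - 1 else \
                srt[lo] + frac * (srt[lo + 1] - srt[lo])
            assert percentile99(v) == pytest.approx(expected, rel=1e-12)

    def test_no_myocardium_rejected(self):
        labels = np.full((4, 4, 4), MUSCLE, np.uint8)
        sol = synthetic_solution(np.zeros(labels.shape + (3,)), labels)
        with pytest.raises(ValueError, match="myocardium"):
            e99_heart(sol)

    def test_phasor_magnitude_combines_components(self):
        labels = np.full((4, 4, 4), HEART_WALL, np.uint8)
        E = np.zeros(labels.shape + (3,), complex)
        E[..., 0] = 3.0
        E[..., 1] = 4.0j  # quadrature component still contributes |.|
        sol = synthetic_solution(E, labels)
        assert e99_heart(sol) == pytest.approx(5.0)


def axes_block(n=20, spacing=2.0):
    labels = np.full((n, n, n), MUSCLE, np.uint8)
    c = n * spacing / 2
    r = n * spacing / 4
    axes = np.array([
        [[c - r, c, c], [c + r, c, c]],
        [[c, c - r, c], [c, c + r, c]],
        [[c, c, c - r], [c, c, c + r]],
    ]) - spacing / 2  # world of voxel centers starts at origin
    return labels, axes


class TestSamField:
    def test_uniform_field_aligned_with_one_axis(self):
        labels, axes = axes_block()
        E = np.zeros(labels.shape + (3,))
        E[..., 0] = 7.0
        sol = synthetic_solution(E, labels, heart_axes=axes)
        assert sam_field(sol) == pytest.approx(7.0, rel=1e-9)

    def test_oblique_uniform_field_recovered_by_orthogonal_decomposition(self):
        labels, axes = axes_block()
        E = np.zeros(labels.shape + (3,))
        E[..., :] = 2.0 / np.sqrt(3.0)  # equal angles to all axes, |E| = 2
        sol = synthetic_solution(E, labels, heart_axes=axes)
        assert sam_field(sol) == pytest.approx(2.0, rel=1e-9)

    def test_line_integral_equals_potential_difference(self, bar_solution):
        # gradient theorem: V_i along an axis inside the bar equals the
        # endpoint potential difference of the solved field
        sol, _, _ = bar_solution
        p = sol.phantom
        axes = np.array([
            [[4.0, 4.0, 4.0], [16.0, 4.0, 4.0]],
            [[10.0, 2.0, 4.0], [10.0, 6.0, 4.0]],
            [[10.0, 4.0, 2.0], [10.0, 4.0, 6.0]],
        ])
        p2 = dataclasses.replace(p, heart_axes=axes)
        sol2 = dataclasses.replace(sol, phantom=p2)
        e_sam, comps = sam_field(sol2, return_components=True)
        # phi varies only along x: axis 0 spans 12 mm of a 20 mm, 1 V bar
        expected = (12.0 / 20.0) * 1.0 / 12e-3
        assert comps[0] == pytest.approx(expected, rel=1e-3)
        assert comps[1] == pytest.approx(0.0, abs=1e-6 * expected)
        assert comps[2] == pytest.approx(0.0, abs=1e-6 * expected)

    def test_axis_leaving_the_body_rejected(self):
        labels, axes = axes_block()
        labels[:2] = 0
        E = np.zeros(labels.shape + (3,))
        sol = synthetic_solution(E, labels, heart_axes=axes)
        bad = axes.copy()
        bad[0, 0, 0] = -50.0
        sol = dataclasses.replace(
            sol, phantom=dataclasses.replace(sol.phantom, heart_axes=bad))
        with pytest.raises(ValueError, match="exits"):
            sam_field(sol)


def make_report(path, freq, e99, i_body, e_sam=None):
    return DoseReport(path_label=path, frequency=freq, touch_voltage=220.0,
                      mode="INTERN", i_body=i_body,
                      z_total=220.0 / i_body, e99_heart=e99,
                      e_sam=e_sam if e_sam is not None else e99,
                      plane_spread=0.0, residual=0.0)


class TestHCF:
    def test_reference_row_exactly_one(self):
        doses = [make_report("LH-BF", f, e99=3.7, i_body=0.2 + 0.1j)
                 for f in (0.0, 50.0, 1e3)]
        doses += [make_report("RH-RF", f, e99=1.85, i_body=0.1 + 0.05j)
                  for f in (0.0, 50.0, 1e3)]
        table = hcf(doses, "F99")
        assert (table.frame.loc["LH-BF"] == 1.0).all()

    def test_duplicated_reference_path_gives_unity(self):
        doses = [make_report("LH-BF", 50.0, 2.0, 0.1),
                 make_report("XX-YY", 50.0, 2.0, 0.1)]
        table = hcf(doses, "F99")
        assert table.frame.loc["XX-YY", 50.0] == 1.0

    def test_direct_substitution(self):
        # E(p)=2, I(p)=4, E(ref)=1, I(ref)=1 -> F = 0.5
        doses = [make_report("LH-BF", 50.0, 1.0, 1.0),
                 make_report("AT-LH", 50.0, 2.0, 4.0)]
        assert hcf(doses, "F99").frame.loc["AT-LH", 50.0] == pytest.approx(0.5)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            hcf([make_report("RH-RF", 50.0, 1.0, 1.0)], "F99")

    def test_fsam_statistic_uses_line_integral_field(self):
        doses = [make_report("LH-BF", 50.0, 1.0, 1.0, e_sam=2.0),
                 make_report("AT-LH", 50.0, 1.0, 1.0, e_sam=6.0)]
        assert hcf(doses, "FSAM").frame.loc["AT-LH", 50.0] == pytest.approx(3.0)

    def test_touch_voltage_invariance(self, tiny_phantom, dose_cached):
        # solver linearity: identical factor tables at 25 V and 220 V drive
        tables = {}
        for u in (25.0, 220.0):
            doses = [dose_cached(tiny_phantom, lbl, frequency=0.0, voltage=u,
                                 mode=BodyModelMode.INTERN, tolerance=1e-12)
                     for lbl in ("LH-BF", "LH-RH")]
            tables[u] = hcf(doses, "F99").frame
        diff = (tables[25.0] - tables[220.0]).abs() / tables[220.0]
        assert diff.max().max() < 1e-9


class TestAnatomyEffects:
    def test_vessel_channeling_raises_heart_field(self, default_phantom,
                                                  default_phantom_no_vessels,
                                                  dose_cached):
        # current channeled through the blood vessels into the heart lumen
        # elevates the myocardial field at the same touch voltage
        on = dose_cached(default_phantom, "LH-BF", frequency=50.0)
        off = dose_cached(default_phantom_no_vessels, "LH-BF", frequency=50.0)
        assert on.e99_heart > off.e99_heart

    def test_transversal_path_field_more_inhomogeneous_near_electrode(
            self, default_phantom, solve_cached):
        # anterior-thorax contact close to the heart skews the myocardial
        # field distribution compared with the hand-to-hand path
        ratios = {}
        for lbl in ("AT-LH", "LH-RH"):
            sol = solve_cached(default_phantom, lbl, frequency=50.0)
            m = heart_field_magnitudes(sol)
            ratios[lbl] = (np.percentile(m, 75) - np.percentile(m, 25)) / \
                np.median(m)
        assert ratios["AT-LH"] > ratios["LH-RH"]
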