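"""Morphologies, transmembrane currents, and the volume-conductor forward model."""

import numpy as np
import pandas as pd
import pytest

from menpsim.neuro_fields import (
    AXON,
    DENDRITE,
    SOMA,
    FieldGrid,
    MagnetizationField,
    Morphology,
    SWCError,
    SegmentCurrents,
    _line_source_kernel,
    ap_current_source,
    biphasic_waveform,
    classify_sites,
    efield_from_potential,
    extracellular_potential,
    peak_window_summary,
    read_swc,
    synth_morphology,
    write_swc,
)

THREE_POINT_SWC = """\
# soma - axon - dendrite fixture
1 1 0 0 0 10 -1
2 2 0 -100 0 0.5 1
3 3 0 120 0 1.0 1
"""


def soma_only(radius=10.0):
    return Morphology(
        ids=np.array([1]), types=np.array([SOMA]), xyz=np.zeros((1, 3)),
        radius=np.array([radius]), parent=np.array([-1]),
    )


class TestSWCIO:
    def test_three_point_fixture_parses(self, tmp_path):
        p = tmp_path / "cell.swc"
        p.write_text(THREE_POINT_SWC)
        m = read_swc(str(p))
        assert m.n_segments == 3
        assert set(m.types.tolist()) == {SOMA, AXON, DENDRITE}

    def test_round_trip_identity(self, tmp_path):
        m = synth_morphology("branched", {"depth": 2}, seed=7)
        p = tmp_path / "out.swc"
        write_swc(m, str(p))
        m2 = read_swc(str(p))
        assert np.array_equal(m.ids, m2.ids)
        assert np.array_equal(m.types, m2.types)
        assert np.array_equal(m.xyz, m2.xyz)
        assert np.array_equal(m.radius, m2.radius)
        assert np.array_equal(m.parent, m2.parent)

    def test_orphan_parent_named_in_error(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 10 -1\n2 2 0 1 0 1 99\n")
        with pytest.raises(SWCError, match="99"):
            read_swc(str(p))

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 10 -1\n2 2 0 1 0\n")
        with pytest.raises(SWCError, match=":2"):
            read_swc(str(p))

    def test_cycle_detected(self):
        with pytest.raises(SWCError, match="cycle"):
            Morphology(
                ids=np.array([1, 2, 3]), types=np.array([1, 2, 2]),
                xyz=np.zeros((3, 3)), radius=np.ones(3),
                parent=np.array([-1, 3, 2]),
            )

    def test_multiple_roots_rejected(self):
        with pytest.raises(SWCError, match="root"):
            Morphology(
                ids=np.array([1, 2]), types=np.array([1, 1]),
                xyz=np.zeros((2, 3)), radius=np.ones(2),
                parent=np.array([-1, -1]),
            )


class TestSynthMorphology:
    def test_ball_and_stick_minimal(self):
        m = synth_morphology("ball_and_stick", {"n_dend": 1})
        assert m.n_segments == 3
        assert set(m.types.tolist()) == {SOMA, AXON, DENDRITE}

    def test_seed_reproducibility(self):
        a = synth_morphology("branched", {"depth": 3}, seed=5)
        b = synth_morphology("branched", {"depth": 3}, seed=5)
        assert np.array_equal(a.xyz, b.xyz)
        c = synth_morphology("branched", {"depth": 3}, seed=6)
        assert not np.array_equal(a.xyz, c.xyz)

    def test_branched_binary_tree_count(self):
        """A depth-3 full binary dendritic tree has 2^4 - 2 = 14 compartments."""
        m = synth_morphology("branched", {"depth": 3, "n_axon": 4}, seed=0)
        n_dend = int(np.sum(m.types == DENDRITE))
        assert n_dend == 2 ** (3 + 1) - 2
        assert m.n_segments == 1 + 4 + n_dend

    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError, match="template"):
            synth_morphology("torus")


class TestAPCurrentSource:
    t = np.arange(0.0, 10.0, 0.01)

    def test_zero_amplitude_gives_zero_currents(self):
        m = synth_morphology("ball_and_stick")
        out = ap_current_source(m, self.t, amplitude_nA=0.0)
        assert np.all(out.currents == 0)

    def test_net_current_zero_at_every_sample(self):
        m = synth_morphology("branched", {"depth": 3}, seed=1)
        out = ap_current_source(m, self.t, amplitude_nA=2.0)
        net = np.abs(out.currents.sum(axis=0))
        assert net.max() < 1e-9 * np.abs(out.currents).max()

    def test_unbalanced_template_rejected(self):
        m = synth_morphology("ball_and_stick")
        with pytest.raises(ValueError, match="zero"):
            ap_current_source(
                m, self.t, waveform=lambda tt: np.exp(-((tt - 1) ** 2))
            )

    def test_distal_axon_peak_lags_by_transit_time(self):
        """Propagation delay equals path distance over conduction speed.

        The distal axon tip carries a pure delayed template, so its peak
        time is onset + distance/speed + the template's own peak offset
        (3 sigma for the derivative-of-Gaussian shape).
        """
        width = 0.25
        onset = 1.0
        speed = 250.0
        m = synth_morphology(
            "branched", {"depth": 1, "n_axon": 5, "axon_len": 500.0}, seed=0
        )
        out = ap_current_source(
            m, self.t, onset_ms=onset, conduction_speed_um_per_ms=speed,
            width_ms=width,
        )
        dist = m.path_distance()
        rows = np.flatnonzero(m.types == AXON)
        tip = rows[int(np.argmax(dist[rows]))]
        tip_peak = self.t[np.argmax(out.currents[tip])]
        expected = onset + dist[tip] / speed + 3.0 * width
        assert tip_peak == pytest.approx(expected, abs=0.02)

    def test_balance_check_raises_on_violation(self):
        bad = SegmentCurrents(time_ms=self.t, currents=np.ones((2, len(self.t))))
        with pytest.raises(ValueError, match="net transmembrane"):
            bad.check_balance()


class TestExtracellularPotential:
    def test_point_source_closed_form(self):
        """A soma sphere alone is an exact I/(4 pi sigma r) monopole."""
        m = soma_only(radius=5.0)
        I = SegmentCurrents(
            time_ms=np.array([0.0]), currents=np.array([[2.0]])
        )
        sigma = 0.3
        for r in (10.0, 50.0, 400.0):
            phi = extracellular_potential(m, I, np.array([[r, 0, 0]]), sigma)
            assert phi[0, 0] == pytest.approx(2.0 / (4 * np.pi * sigma * r), rel=1e-12)

    def test_superposition_and_scaling(self):
        m = synth_morphology("branched", {"depth": 2}, seed=3)
        t = np.arange(0.0, 5.0, 0.5)
        c1 = ap_current_source(m, t, amplitude_nA=1.0)
        c2 = ap_current_source(m, t, amplitude_nA=3.0)
        sites = np.array([[40.0, 10.0, 5.0], [-20.0, 60.0, 0.0]])
        p1 = extracellular_potential(m, c1, sites)
        p2 = extracellular_potential(m, c2, sites)
        assert np.allclose(p2, 3.0 * p1, rtol=1e-12)

    def test_far_field_line_matches_point_source(self):
        """At 100 segment lengths the line kernel is a monopole to < 0.01%."""
        L = 10.0
        p0, p1 = np.zeros(3), np.array([0.0, 0.0, L])
        sites = np.array([[100 * L, 0.0, L / 2], [60 * L, 60 * L, -30 * L]])
        g_line = _line_source_kernel(p0, p1, 0.5, sites, 0.3)
        mid = (p0 + p1) / 2
        d = np.linalg.norm(sites - mid, axis=1)
        g_point = 1.0 / (4 * np.pi * 0.3 * d)
        assert np.all(np.abs(g_line / g_point - 1.0) < 1e-4)

    def test_inverse_distance_decay_slope(self):
        m = soma_only()
        I = SegmentCurrents(time_ms=np.array([0.0]), currents=np.array([[1.0]]))
        r = np.logspace(1.5, 3.0, 12)
        sites = np.column_stack([r, np.zeros_like(r), np.zeros_like(r)])
        phi = extracellular_potential(m, I, sites)[:, 0]
        slope = np.polyfit(np.log(r), np.log(phi), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.01)

    def test_site_clamped_to_surface(self):
        m = soma_only(radius=8.0)
        I = SegmentCurrents(time_ms=np.array([0.0]), currents=np.array([[1.0]]))
        inside = extracellular_potential(m, I, np.array([[1.0, 0, 0]]))
        surface = extracellular_potential(m, I, np.array([[8.0, 0, 0]]))
        assert inside[0, 0] == surface[0, 0]

    def test_invalid_conductivity(self):
        m = soma_only()
        I = SegmentCurrents(time_ms=np.array([0.0]), currents=np.array([[1.0]]))
        with pytest.raises(ValueError):
            extracellular_potential(m, I, np.array([[10.0, 0, 0]]), sigma_ext=0.0)


class TestEfieldFromPotential:
    def make_grid(self, spacing=10.0, n=(5, 5, 5)):
        grid = FieldGrid.from_dims(
            (spacing * (n[0] - 1), spacing * (n[1] - 1), spacing * (n[2] - 1)),
            spacing, np.array([0.0]),
        )
        return grid

    def test_constant_potential_zero_field(self):
        grid = self.make_grid()
        grid.phi = np.full((grid.n_sites, 1), 3.7)
        efield_from_potential(grid)
        assert np.allclose(grid.E, 0.0)

    def test_linear_ramp_exact(self):
        """phi = a*x (mV, um) gives E = (-1000a, 0, 0) V/m exactly."""
        grid = self.make_grid()
        a = 0.25
        grid.phi = (a * grid.sites[:, 0])[:, None]
        efield_from_potential(grid)
        assert np.allclose(grid.E[:, 0, 0], -1000.0 * a, rtol=1e-12)
        assert np.allclose(grid.E[:, 0, 1:], 0.0, atol=1e-12)

    def test_second_order_convergence_on_point_source(self):
        """Central-difference error shrinks ~4x when the lattice is halved."""
        src = np.array([-35.0, -35.0, -35.0])

        def interior_error(spacing):
            n = int(80 / spacing) + 1
            grid = FieldGrid.from_dims((80.0,) * 3, spacing, np.array([0.0]))
            r = np.linalg.norm(grid.sites - src, axis=1)
            grid.phi = (1.0 / (4 * np.pi * 0.3 * r))[:, None]
            efield_from_potential(grid)
            rel = grid.sites - src
            E_true = 1000.0 * rel / (4 * np.pi * 0.3 * r**3)[:, None]
            err = np.linalg.norm(grid.E[:, 0, :] - E_true, axis=1)
            interior = np.all(
                (grid.sites > grid.origin + spacing - 1e-9)
                & (grid.sites < grid.origin + 80.0 - spacing + 1e-9),
                axis=1,
            )
            return np.max(err[interior] / np.linalg.norm(E_true[interior], axis=1))

        e1, e2 = interior_error(10.0), interior_error(5.0)
        assert 2.5 < e1 / e2 < 6.0

    def test_too_few_planes_rejected(self):
        grid = FieldGrid.from_dims((10.0, 40.0, 40.0), 10.0, np.array([0.0]))
        grid.phi = np.zeros((grid.n_sites, 1))
        with pytest.raises(ValueError, match="planes"):
            efield_from_potential(grid)

    def test_site_count_closed_form(self):
        grid = FieldGrid.from_dims((200.0, 700.0, 200.0), 5.0, np.array([0.0]))
        assert grid.shape == (41, 141, 41)
        assert grid.n_sites == 237021


class TestClassifySites:
    def fixture_morph(self):
        # Soma at origin (r=5), axon to (0,-100,0), dendrite to (0,120,0).
        return Morphology(
            ids=np.array([1, 2, 3]), types=np.array([SOMA, AXON, DENDRITE]),
            xyz=np.array([[0, 0, 0], [0, -100, 0], [0, 120, 0]], float),
            radius=np.array([5.0, 0.5, 1.0]), parent=np.array([-1, 1, 1]),
        )

    def test_near_soma_is_somatic(self):
        labels = classify_sites(self.fixture_morph(), np.array([[5.0, 0.0, 0.0]]))
        assert labels[0] == "somatic"

    def test_beyond_all_zones_is_none(self):
        labels = classify_sites(self.fixture_morph(), np.array([[200.0, 0.0, 0.0]]))
        assert labels[0] == "none"

    def test_soma_precedence_on_ties(self):
        # Equidistant (10 um) from the soma center and the axon line.
        m = self.fixture_morph()
        labels = classify_sites(m, np.array([[10.0, -50.0, 0.0], [0.0, 0.0, 10.0]]))
        assert labels[0] == "axonal"
        assert labels[1] == "somatic"
        tie_site = np.array([[10.0, 0.0, 0.0]])  # 10 from soma, 10 from axon end
        assert classify_sites(m, tie_site)[0] == "somatic"

    def test_independent_of_node_ordering(self):
        m = self.fixture_morph()
        # Same tree, children listed in the opposite order.
        m2 = Morphology(
            ids=np.array([1, 2, 3]), types=np.array([SOMA, DENDRITE, AXON]),
            xyz=np.array([[0, 0, 0], [0, 120, 0], [0, -100, 0]], float),
            radius=np.array([5.0, 1.0, 0.5]), parent=np.array([-1, 1, 1]),
        )
        rng = np.random.default_rng(0)
        sites = rng.uniform(-150, 150, size=(100, 3))
        assert np.array_equal(classify_sites(m, sites), classify_sites(m2, sites))

    def test_zone_radius_must_be_positive(self):
        with pytest.raises(ValueError):
            classify_sites(self.fixture_morph(), np.zeros((1, 3)), zone_radius_um=0.0)


class TestPeakWindowSummary:
    def make_field(self, values, times=None):
        n_sites = len(values)
        grid = FieldGrid.from_dims((10.0, 10.0, 0.0), 10.0, times if times is not None else np.arange(5.0))
        # Use a custom flat grid: override shape bookkeeping via a 1-D stack.
        grid = FieldGrid(
            origin=np.zeros(3), spacing=10.0, shape=(n_sites, 1, 1),
            times_ms=times if times is not None else np.arange(5.0),
        )
        dm = np.tile(np.asarray(values, float)[:, None], (1, len(grid.times_ms)))
        return MagnetizationField(grid=grid, dm=dm)

    def test_uniform_field_mean_and_zero_iqr(self):
        field = self.make_field([0.5] * 8)
        cats = np.array(["somatic"] * 8)
        out = peak_window_summary(field, cats, window_ms=(0, 4))
        row = out["summary"].loc["somatic"]
        assert row["mean"] == pytest.approx(0.5)
        assert row["q3"] - row["q1"] == 0.0

    def test_peak_time_is_argmax_of_integrated_magnitude(self):
        grid = FieldGrid(
            origin=np.zeros(3), spacing=5.0, shape=(4, 1, 1),
            times_ms=np.arange(10.0),
        )
        dm = np.ones((4, 10))
        dm[:, 6] = 5.0  # global peak at t = 6 ms
        out = peak_window_summary(
            MagnetizationField(grid=grid, dm=dm), np.array(["axonal"] * 4),
            window_ms=(0, 9),
        )
        assert out["peak_time_ms"] == 6.0

    def test_two_category_constants_recovered(self):
        field = self.make_field([1.0, 1.0, -3.0, -3.0, -3.0])
        cats = np.array(["somatic", "somatic", "dendritic", "dendritic", "dendritic"])
        out = peak_window_summary(field, cats, window_ms=(0, 4))
        assert out["summary"].loc["somatic", "mean"] == pytest.approx(1.0)
        assert out["summary"].loc["dendritic", "mean"] == pytest.approx(3.0)
        assert out["summary"].loc["somatic", "n"] == 2
        assert any("axonal" in note for note in out["notes"])

    def test_window_not_covered_rejected(self):
        field = self.make_field([1.0])
        with pytest.raises(ValueError, match="window"):
            peak_window_summary(field, np.array(["somatic"]), window_ms=(100, 120))


class TestBiphasicWaveform:
    def test_charge_balanced_over_support(self):
        t = np.linspace(0.0, 20.0, 100001)
        w = biphasic_waveform(t, width_ms=0.5)
        assert abs(np.trapezoid(w, t)) < 1e-3 * np.abs(w).max()

    def test_unit_positive_peak(self):
        t = np.linspace(0.0, 5.0, 50001)
        assert biphasic_waveform(t, 0.25).max() == pytest.approx(1.0, abs=1e-6)
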