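import numpy as np
import pytest

from woundchip import fields as F
from woundchip import geometry as G

SIGMA = G.PBS_CONDUCTIVITY
AREA_M2 = 0.9e-3 * 0.08e-3  # default channel cross-section


def uniform_channel_field(current_uA: float) -> float:
    """Closed-form |E| (mV/mm) of a uniform conductor: E = I / (sigma A)."""
    return current_uA * 1e-6 / (SIGMA * AREA_M2)


class TestSolveField:
    def test_uniform_channel_matches_closed_form(self, straight_solution):
        prof = F.wound_profiles(straight_solution)
        assert prof.center_E == pytest.approx(uniform_channel_field(25.0), rel=0.01)

    def test_zero_current_gives_zero_field(self, straight_chip):
        _, cmap, cfg = straight_chip
        sol = F.solve_field(cmap, cfg, current_uA=0.0)
        assert np.nanmax(sol.E_mag) == pytest.approx(0.0, abs=1e-12)

    def test_field_is_linear_in_current(self, straight_chip, straight_solution):
        _, cmap, cfg = straight_chip
        sol2 = F.solve_field(cmap, cfg, current_uA=50.0)
        ref = np.nan_to_num(straight_solution.E_mag)
        assert np.allclose(np.nan_to_num(sol2.E_mag), 2.0 * ref, atol=1e-9)

    def test_current_conservation_through_cuts(self, straight_solution):
        for x_cut in (-3.0, 0.0, 2.5):
            flux = F.cut_current_uA(straight_solution, x_cut)
            assert flux == pytest.approx(25.0, rel=1e-6)

    def test_resistance_is_positive(self, straight_solution):
        assert straight_solution.resistance_kohm > 0

    def test_mirror_symmetric_field(self):
        # symmetric conductor + symmetric electrodes: |E| symmetric about the
        # horizontal midline.  Built by hand so the grid itself is exactly
        # symmetric (rasterized bounds carry float-level asymmetries).
        ny, nx = 21, 80
        g = np.zeros((ny, nx))
        g[3:18, :] = 1.54 * 0.08e-3
        left = np.zeros((ny, nx), bool)
        right = np.zeros((ny, nx), bool)
        left[3:18, :3] = True
        right[3:18, -3:] = True
        wound = np.zeros((ny, nx), bool)
        wound[9:12, 38:42] = True
        cmap = G.ConductivityMap(
            grid_spacing=0.1,
            x=(np.arange(nx) + 0.5) * 0.1,
            y=(np.arange(ny) + 0.5) * 0.1,
            sheet_conductance=g,
            electrode_masks=[left, right],
            wound_mask=wound,
            network=None,
        )
        cfg = G.ElectrodeConfig(
            (
                G.Electrode(0, G.ElectrodeRole.ANODE, 25.0),
                G.Electrode(1, G.ElectrodeRole.CATHODE, 25.0),
            ),
            G.Scheme.UNI_DIRECTIONAL,
        )
        sol = F.solve_field(cmap, cfg)
        E = np.nan_to_num(sol.E_mag)
        asym = np.abs(E - E[::-1, :]).max() / E.max()
        assert asym < 1e-6

    def test_grid_halving_changes_center_field_below_one_percent(self):
        net = G.build_layout("straight")
        cfg = G.default_electrodes(net, "uni_directional", 25.0)
        e = []
        for h in (0.1, 0.05):
            sol = F.solve_field(G.rasterize(net, h), cfg)
            e.append(F.wound_profiles(sol).center_E)
        assert abs(e[1] - e[0]) / e[0] < 0.01

    def test_disconnected_electrodes_raise(self):
        segs = (
            G.Segment((-5.0, 0.0), (-1.0, 0.0), 0.9),
            G.Segment((1.0, 0.0), (5.0, 0.0), 0.9),
        )
        net = G.ChannelNetwork(
            layout_kind=G.LayoutKind.STRAIGHT,
            segments=segs,
            reservoirs=(G.Reservoir((-6.0, 0.0), 1.0), G.Reservoir((6.0, 0.0), 1.0)),
            wound_zone=G.WoundZone(-4.0, -0.45, -3.0, 0.45),
        )
        cfg = G.default_electrodes(net, "uni_directional", 25.0)
        with pytest.raises(F.ConnectivityError):
            F.solve_field(G.rasterize(net, 0.1), cfg)

    def test_energy_consistency_with_resistance(self, straight_solution):
        # integrated areal power = I^2 R within 1%
        sol = straight_solution
        a_cell = (sol.map.grid_spacing * 1e-3) ** 2
        p_grid = float(sol.power_density().sum() * a_cell)
        p_ohm = (25e-6) ** 2 * sol.resistance_kohm * 1e3
        assert p_grid == pytest.approx(p_ohm, rel=0.01)


class TestWoundProfiles:
    def test_uniform_channel_profiles_are_flat(self, straight_solution):
        prof = F.wound_profiles(straight_solution)
        # across-profile within the mid-channel region (x in [-2, 2] mm)
        sel = np.abs(prof.across_position_mm) < 2.0
        vals = prof.across_E[sel]
        assert np.nanstd(vals) / np.nanmean(vals) < 0.01

    def test_center_value_consistent_between_profiles(self, straight_solution):
        prof = F.wound_profiles(straight_solution)
        ic = np.argmin(np.abs(prof.along_position_mm - 0.0))
        jc = np.argmin(np.abs(prof.across_position_mm - 0.0))
        assert prof.along_E[ic] == pytest.approx(prof.center_E)
        assert prof.across_E[jc] == pytest.approx(prof.center_E)


class TestCalibrateCurrent:
    def test_uniform_channel_closed_form(self, straight_chip):
        # I = sigma * E * A for a 0.9 x 0.08 mm channel
        _, cmap, cfg = straight_chip
        target = 200.0  # mV/mm
        expected_uA = SIGMA * target * AREA_M2 * 1e6
        got = F.calibrate_current(cmap, cfg, target)
        assert got == pytest.approx(expected_uA, rel=0.005)

    def test_scaling_is_exactly_linear(self, straight_chip):
        _, cmap, cfg = straight_chip
        i100 = F.calibrate_current(cmap, cfg, 100.0, verify=False)
        i200 = F.calibrate_current(cmap, cfg, 200.0, verify=False)
        assert i100 == pytest.approx(i200 / 2.0, rel=1e-12)

    def test_zero_target_rejected(self, straight_chip):
        _, cmap, cfg = straight_chip
        with pytest.raises(F.CalibrationError):
            F.calibrate_current(cmap, cfg, 0.0)

    def test_peace_sign_calibrated_current_hits_target(self):
        net = G.build_layout("peace_sign")
        cmap = G.rasterize(net, 0.1)
        cfg = G.default_electrodes(net, "uni_directional")
        current = F.calibrate_current(cmap, cfg, 200.0)
        sol = F.solve_field(cmap, cfg, current_uA=current)
        assert F.wound_profiles(sol).center_E == pytest.approx(200.0, rel=0.005)


class TestDeadZone:
    def test_uniform_straight_channel_ratio_is_one(self, straight_solution):
        assert F.dead_zone_metric(straight_solution) == pytest.approx(1.0, abs=0.02)

    def test_t_junction_converging_has_dead_zone(self):
        net = G.build_layout("t_junction")
        cmap = G.rasterize(net, 0.1)
        cfg = G.default_electrodes(net, "pseudo_converging", 20.0)
        ratio = F.dead_zone_metric(F.solve_field(cmap, cfg, state=0))
        assert ratio < 1.0

    def test_peace_sign_mitigates_the_dead_zone(self):
        ratios = {}
        for kind in ("t_junction", "peace_sign"):
            net = G.build_layout(kind)
            cmap = G.rasterize(net, 0.1)
            cfg = G.default_electrodes(net, "pseudo_converging", 20.0)
            ratios[kind] = F.dead_zone_metric(F.solve_field(cmap, cfg, state=0))
        assert ratios["peace_sign"] > ratios["t_junction"]
        assert abs(ratios["peace_sign"] - 1) < abs(ratios["t_junction"] - 1)


@pytest.fixture(scope="module")
def relay():
    net = G.build_layout("peace_sign")
    cmap = G.rasterize(net, 0.1)
    cfg = G.default_electrodes(net, "pseudo_converging", 20.0)
    return cmap, cfg


class TestRelaySequence:

    def test_twelve_hours_thirty_minutes_gives_24_intervals(self, relay):
        cmap, cfg = relay
        seq = F.relay_sequence(cmap, cfg, 12.0)
        assert len(seq) == 24
        labels = [sol.state for _, sol in seq]
        assert labels.count("anode0") == 12
        assert labels.count("anode1") == 12

    def test_field_direction_flips_between_intervals(self, relay):
        cmap, cfg = relay
        seq = F.relay_sequence(cmap, cfg, 1.0)
        ic = int(np.argmin(np.abs(cmap.y - 0.0)))
        jc = int(np.argmin(np.abs(cmap.x - 0.0)))
        ex = [sol.Ex[ic, jc] for _, sol in seq]
        assert ex[0] * ex[1] < 0

    def test_zero_duration_gives_empty_sequence(self, relay):
        cmap, cfg = relay
        assert F.relay_sequence(cmap, cfg, 0.0) == []

    def test_uni_scheme_rejected(self, straight_chip):
        _, cmap, cfg = straight_chip
        with pytest.raises(G.GeometryError):
            F.relay_sequence(cmap, cfg, 1.0)
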