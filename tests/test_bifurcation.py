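"""P-bifurcation analysis: mode counting, scans, burst-shift formulas."""

import numpy as np
import pytest

from burstbif.bifurcation import (
    count_maxima,
    scan_phase_diagram,
    shift_derivative,
    track_extrema_vs_r,
)
from burstbif.model_core import SchloglParams

FIG6 = dict(k1=3e6, k2=77518.0, k3=601.0, k4=1.0)
FIG4B = dict(k1=5.33e6, k3=800.0)  # sweeps k̃2
CUSP_K3 = 720.0


class TestCountMaxima:
    def test_fig6_fpe_labels(self):
        assert count_maxima(SchloglParams(**FIG6, r=1), "fpe").label == "monostable"
        lab = count_maxima(SchloglParams(**FIG6, r=25), "fpe")
        assert lab.label == "bistable" and lab.n_maxima == 2

    @pytest.mark.parametrize("r", [1, 25, 40])
    def test_fig6_deterministic_monostable_for_every_r(self, r):
        lab = count_maxima(SchloglParams(**FIG6, r=r), "deterministic")
        assert lab.label == "monostable" and lab.n_maxima == 1

    def test_cme_source_agrees_with_fpe(self):
        p = SchloglParams(**FIG6, r=25)
        assert count_maxima(p, "cme", x_max=1500).n_maxima == 2


class TestTrackExtremaVsR:
    def test_fig6_noise_induced_transition(self):
        track = track_extrema_vs_r(SchloglParams(**FIG6), range(1, 26))
        assert len(track.transitions) == 1
        r_star = track.transitions[0]
        assert 1 < r_star <= 25
        tab = track.table.set_index("r")
        assert tab.loc[1, "n_maxima"] == 1
        assert tab.loc[25, "n_maxima"] == 2

    def test_newly_born_pair_is_close(self):
        """At the transition the created max/min pair carries the saddle-node
        signature: it is much closer together than to the pre-existing mode."""
        track = track_extrema_vs_r(SchloglParams(**FIG6), range(1, 26))
        r_star = track.transitions[0]
        row = track.table.set_index("r").loc[r_star]
        new_max, old_max = row["maxima"]
        (born_min,) = row["minima"]
        assert abs(born_min - new_max) < 0.2 * abs(old_max - new_max)

    def test_deterministic_roots_attached_and_r_independent(self):
        track = track_extrema_vs_r(SchloglParams(**FIG6), range(1, 6))
        assert len(track.deterministic_roots) == 1
        assert track.deterministic_roots[0] == pytest.approx(440.475, abs=1e-2)

    def test_reentrant_bistability_in_burst_size(self):
        """The same rates pass monostable -> bistable -> monostable as the
        burst size grows: noise induces and then destroys the bifurcation."""
        track = track_extrema_vs_r(SchloglParams(**FIG6), [1, 10, 25, 50, 100])
        n = dict(zip(track.table["r"], track.table["n_maxima"]))
        assert n[1] == 1 and n[10] == 2 and n[25] == 2 and n[50] == 1 and n[100] == 1


class TestShiftDerivative:
    def test_k1_shift_closed_form(self):
        p = SchloglParams.from_reduced(9e6, 1.5e5, 720.0)
        rep = shift_derivative(p, "k1", x=100.0, r=1)
        assert rep.analytic == pytest.approx(72_000.0, rel=1e-14)

    def test_k3_shift_closed_form(self):
        p = SchloglParams.from_reduced(9e6, 1.5e5, 720.0, r=25)
        rep = shift_derivative(p, "k3", x=100.0)
        assert rep.analytic == pytest.approx(720.0 / 75.0, rel=1e-14)

    def test_k3_shift_pole_at_x_equal_r(self):
        p = SchloglParams.from_reduced(9e6, 1.5e5, 720.0, r=25)
        with pytest.raises(ZeroDivisionError):
            shift_derivative(p, "k3", x=25.0)

    def test_general_formula_reproduces_special_cases(self):
        """The implicit-function-theorem value equals k̃3 x (for k̃1) and
        k̃3/(x-r) (for k̃3) on a random grid, to machine precision."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            k3 = rng.uniform(1.0, 1000.0)
            x = rng.uniform(1.0, 500.0)
            r = int(rng.integers(1, 60))
            if abs(x - r) < 1.0:
                continue
            p = SchloglParams.from_reduced(1e6, 1e5, k3, r=r)
            np.testing.assert_allclose(
                shift_derivative(p, "k1", x=x).analytic, k3 * x, rtol=1e-12)
            np.testing.assert_allclose(
                shift_derivative(p, "k3", x=x).analytic, k3 / (x - r), rtol=1e-12)

    def test_k2_shift_tends_to_minus_k3(self):
        """dk̃2/dr = -2k̃3 x/(2x+1) -> -k̃3 for x >> 1: the boundary curves
        are equidistant along k̃2."""
        p = SchloglParams.from_reduced(5.33e6, 1.6e5, 800.0)
        vals = [shift_derivative(p, "k2", x=x).analytic for x in (10, 100, 1000)]
        errs = [abs(v + 800.0) / 800.0 for v in vals]
        assert errs[2] < 1e-3
        assert errs[0] > errs[1] > errs[2]

    @pytest.mark.parametrize("which", ["k1", "k2", "k3"])
    def test_finite_difference_tracking_agrees(self, which):
        """Re-solving the extremum condition at r and r+1 reproduces the
        derivative to < 1% for x >> 1."""
        p = SchloglParams.from_reduced(9e6, 1.5e5, 720.0, r=5)
        rep = shift_derivative(p, which, x=300.0)
        assert rep.rel_error < 0.01


class TestScanPhaseDiagram:
    def test_deterministic_cusp_geometry(self):
        """Two saddle-node branches along k̃1 merge and vanish as k̃2 rises
        past the cusp at k̃2 = k̃3²/3, k̃1 = k̃3³/27."""
        k3 = CUSP_K3
        k2_cusp = k3**2 / 3  # 172800
        k1_cusp = k3**3 / 27  # 13824000
        k2_vals = np.array([0.80, 0.90, 0.97, 1.03]) * k2_cusp
        k1_vals = np.linspace(2e6, 1.4e7, 121)  # step below the narrowest window
        d = scan_phase_diagram(
            [("k1", k1_vals), ("k2", k2_vals)], {"k3": k3}, r_list=(1,),
            source="deterministic",
        )
        crossings = {}
        for a2, c in d.boundaries[1]:
            crossings.setdefault(a2, []).append(c)
        widths = []
        for k2v in k2_vals[:3]:
            cs = sorted(crossings[float(k2v)])
            assert len(cs) == 2  # below the cusp: a bistable window
            widths.append(cs[1] - cs[0])
        assert float(k2_vals[3]) not in crossings  # beyond the cusp: none
        assert widths[0] > widths[1] > widths[2]  # window closes at the cusp

    def test_equidistant_boundaries_along_k2(self):
        """Upper bistability boundary along k̃2 moves by ~ -k̃3 per unit r."""
        d = scan_phase_diagram(
            [("k2", np.linspace(1.2e5, 2.4e5, 41))], FIG4B,
            r_list=(1, 11, 21, 31, 41), source="fpe",
        )
        upper = [max(c for _, c in d.boundaries[r]) for r in d.r_list]
        spacings = np.diff(upper)  # per Δr = 10
        np.testing.assert_allclose(spacings, -10 * FIG4B["k3"], rtol=0.01)

    def test_burst_destroys_bistable_window_along_k1(self):
        """The k̃1-window shrinks with r (the two branches shift at different
        rates k̃3·x) and has vanished by r = 11."""
        d = scan_phase_diagram(
            [("k1", np.linspace(1.0e7, 1.6e7, 31))], {"k2": 1.65e5, "k3": CUSP_K3},
            r_list=(1, 11), source="fpe",
        )
        assert len(d.boundaries[1]) == 2
        assert len(d.boundaries[11]) == 0

    def test_boundary_resolution_stable(self):
        """Halving the grid step moves bisected boundaries by < one coarse cell."""
        fixed = FIG4B
        coarse = scan_phase_diagram(
            [("k2", np.linspace(1.2e5, 2.0e5, 17))], fixed, r_list=(1,), source="fpe")
        fine = scan_phase_diagram(
            [("k2", np.linspace(1.2e5, 2.0e5, 33))], fixed, r_list=(1,), source="fpe")
        cell = (2.0e5 - 1.2e5) / 16
        c_coarse = sorted(c for _, c in coarse.boundaries[1])
        c_fine = sorted(c for _, c in fine.boundaries[1])
        assert len(c_coarse) == len(c_fine)
        for a, b in zip(c_coarse, c_fine):
            assert abs(a - b) < cell

    def test_frame_export_is_tidy(self):
        d = scan_phase_diagram(
            [("k2", np.linspace(1.4e5, 1.8e5, 5))], FIG4B, r_list=(1, 21))
        df = d.to_frame()
        assert set(df.columns) == {"k2", "r", "n_maxima", "label"}
        assert len(df) == 10
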