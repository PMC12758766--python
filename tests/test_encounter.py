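"""Calm/turbulent encounter kernels: published values, limits and invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sagitta as sg
from conftest import STRATUM_MEANS

speeds = st.floats(0.01, 1.0)
turb = st.floats(0.0, 0.5)
densities = st.floats(0.0, 1e4)


class TestGsRate:
    @pytest.mark.parametrize(
        "stratum", list(STRATUM_MEANS), ids=lambda s: f"{s[0]}-{s[1]}"
    )
    def test_reproduces_published_surface_rates(self, ambush_params, stratum):
        """With R=3 mm, x=150 mm/s, y=0, the kernel recovers every published
        calm-water surface rate from its copepod density within 1% (table
        values are rounded means)."""
        row = STRATUM_MEANS[stratum]
        assert sg.gs_rate(ambush_params, row["cop"]) == pytest.approx(row["gs"], rel=0.01)

    def test_zero_density_gives_zero(self, ambush_params):
        assert sg.gs_rate(ambush_params, 0.0) == 0.0

    def test_equal_speeds_match_continuity_limit(self):
        """At x = y the bracketed expression is smooth; the value agrees with
        evaluation just off the diagonal and with the closed form 4x/3."""
        p_eq = sg.EncounterParams(radius=0.003, prey_speed=0.150, predator_speed=0.150)
        p_off = sg.EncounterParams(radius=0.003, prey_speed=0.150, predator_speed=0.1499999)
        r_eq = sg.gs_rate(p_eq, 100.0)
        assert r_eq == pytest.approx(sg.gs_rate(p_off, 100.0), rel=1e-6)
        closed = sg.DAY_SECONDS * np.pi * 0.003**2 * 100.0 * (4 * 0.150 / 3)
        assert r_eq == pytest.approx(closed, rel=1e-12)

    def test_both_speeds_zero_is_a_domain_error(self):
        p = sg.EncounterParams(radius=0.003, prey_speed=0.0, predator_speed=0.0)
        with pytest.raises(ValueError, match="both"):
            sg.gs_rate(p, 10.0)

    def test_negative_inputs_rejected(self, ambush_params):
        with pytest.raises(ValueError):
            sg.gs_rate(ambush_params, -1.0)
        with pytest.raises(ValueError):
            sg.EncounterParams(radius=-0.003)

    @given(x=speeds, y=speeds, n=densities)
    def test_symmetric_in_speeds(self, x, y, n):
        pa = sg.EncounterParams(radius=0.003, prey_speed=x, predator_speed=y)
        pb = sg.EncounterParams(radius=0.003, prey_speed=y, predator_speed=x)
        assert sg.gs_rate(pa, n) == pytest.approx(sg.gs_rate(pb, n), rel=1e-12)

    @given(x=speeds, y=speeds, n=st.floats(0.1, 1e4))
    def test_exactly_linear_in_density(self, x, y, n):
        p = sg.EncounterParams(radius=0.003, prey_speed=x, predator_speed=y)
        assert sg.gs_rate(p, 2 * n) == pytest.approx(2 * sg.gs_rate(p, n), rel=1e-12)


class TestRoRate:
    def test_zero_turbulence_recovers_calm_kernel(self, ambush_params):
        n = np.array([10.0, 205.2, 0.0])
        assert sg.ro_rate(ambush_params, n, 0.0) == pytest.approx(sg.gs_rate(ambush_params, n))

    @given(x=speeds, w=st.floats(1e-4, 0.5), n=st.floats(0.1, 1e4))
    def test_ambush_closed_form(self, x, w, n):
        """For y=0 the substituted kernel equals
        86400*pi*R^2*N*(3x^2+4w^2)/(3*sqrt(x^2+w^2))."""
        p = sg.EncounterParams(radius=0.003, prey_speed=x, predator_speed=0.0)
        closed = sg.DAY_SECONDS * np.pi * 0.003**2 * n * (3 * x**2 + 4 * w**2) / (
            3 * np.hypot(x, w)
        )
        assert sg.ro_rate(p, n, w) == pytest.approx(closed, rel=1e-10)

    @given(x=speeds, y=speeds, w=turb, n=st.floats(0.1, 1e4))
    def test_dominates_calm_rate(self, x, y, w, n):
        p = sg.EncounterParams(radius=0.003, prey_speed=x, predator_speed=y)
        assert sg.ro_rate(p, n, w) >= sg.gs_rate(p, n) * (1 - 1e-12)

    def test_calibrated_summer_turbulence_reproduces_published_ratio(self, ambush_params):
        """The rms turbulent velocity backed out of the published summer
        neritic turbulent/calm ratio (115.1/75.4) yields the published
        turbulent rate from the published density."""
        w = sg.calibrate_surface_w(115.1 / 75.4, 0.150)
        assert w == pytest.approx(0.1322, abs=2e-4)
        assert sg.ro_rate(ambush_params, 205.2, w) == pytest.approx(115.1, rel=0.01)

    def test_asymptotically_linear_in_w(self, ambush_params):
        """For w >> x the ambush rate grows like (4/3)*pi*R^2*N*w per second."""
        r10 = sg.ro_rate(ambush_params, 100.0, 10.0)
        r20 = sg.ro_rate(ambush_params, 100.0, 20.0)
        assert r20 / r10 == pytest.approx(2.0, rel=1e-3)
        # limit of the closed form: (3x^2+4w^2)/(3 sqrt(x^2+w^2)) -> 4w/3
        assert r20 == pytest.approx(sg.DAY_SECONDS * np.pi * 0.003**2 * 100 * 4 * 20 / 3, rel=1e-3)

    def test_negative_w_rejected(self, ambush_params):
        with pytest.raises(ValueError):
            sg.ro_rate(ambush_params, 10.0, -0.1)


class TestEnhancementAndCalibration:
    def test_no_turbulence_no_enhancement(self):
        assert sg.enhancement_factor(0.150, 0.0) == pytest.approx(1.0, abs=1e-14)

    def test_known_values(self):
        assert sg.enhancement_factor(0.150, 0.150) == pytest.approx(1.650, abs=5e-4)
        assert sg.enhancement_factor(0.150, 0.1322) == pytest.approx(115.1 / 75.4, abs=1e-3)

    def test_matches_rate_ratio(self, ambush_params):
        w = 0.09
        ratio = sg.ro_rate(ambush_params, 73.0, w) / sg.gs_rate(ambush_params, 73.0)
        assert sg.enhancement_factor(0.150, w) == pytest.approx(ratio, rel=1e-12)

    def test_zero_prey_speed_is_domain_error(self):
        with pytest.raises(ValueError):
            sg.enhancement_factor(0.0, 0.1)

    def test_calibration_trivial_and_published_ratios(self):
        assert sg.calibrate_surface_w(1.0, 0.150) == 0.0
        assert sg.calibrate_surface_w(100.3 / 55.7, 0.150) == pytest.approx(0.171, abs=2e-3)
        with pytest.raises(ValueError):
            sg.calibrate_surface_w(0.9, 0.150)

    @given(f=st.floats(1.0, 3.0), x=speeds)
    def test_calibration_roundtrip(self, f, x):
        w = sg.calibrate_surface_w(f, x)
        assert sg.enhancement_factor(x, w) == pytest.approx(f, abs=1e-10)

    @given(x=speeds, w1=turb, w2=turb)
    def test_strictly_increasing_in_w(self, x, w1, w2):
        lo, hi = sorted((w1, w2))
        if hi > lo + 1e-6:  # resolvable gap at float precision
            assert sg.enhancement_factor(x, hi) > sg.enhancement_factor(x, lo)


class TestProfiles:
    def test_constant_mode(self):
        spec = sg.TurbulenceSpec(w0=0.1, profile_mode="constant")
        assert np.all(sg.turbulence_profile(spec, [0, 10, 500]) == 0.1)

    def test_exponential_surface_and_decay(self):
        spec = sg.TurbulenceSpec(w0=0.132, decay_depth=12.0, profile_mode="exponential")
        assert sg.turbulence_profile(spec, 0.0) == pytest.approx(0.132)
        # 10%-of-surface horizon at z = decay_depth * ln 10 ~ 27.6 m
        assert sg.turbulence_profile(spec, 27.6) == pytest.approx(0.132 * np.exp(-2.3), rel=1e-10)

    def test_linear_cutoff_reaches_zero(self):
        spec = sg.TurbulenceSpec(w0=0.1, decay_depth=40.0, profile_mode="linear_cutoff")
        w = sg.turbulence_profile(spec, [0, 20, 40, 60])
        assert w == pytest.approx([0.1, 0.05, 0.0, 0.0])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="profile_mode"):
            sg.TurbulenceSpec(w0=0.1, profile_mode="quadratic")

    def test_profile_collapses_to_calm_without_turbulence(self, ambush_params):
        spec = sg.TurbulenceSpec(w0=0.0)
        prof = sg.encounter_profile(ambush_params, 205.2, spec, np.arange(0, 51, 5.0))
        assert prof.c_ro == pytest.approx(prof.c_gs)

    def test_calibrated_summer_profile_shape(self, ambush_params):
        """Surface turbulent/calm ratio ~1.53 with the summer calibration,
        decaying to 1 at depth; turbulent rate is monotone non-increasing and
        never below the depth-constant calm rate."""
        w0 = sg.calibrate_surface_w(115.1 / 75.4, 0.150)
        spec = sg.TurbulenceSpec(w0=w0, decay_depth=12.0)
        prof = sg.encounter_profile(ambush_params, 205.2, spec, np.arange(0, 201, 2.0))
        assert np.ptp(prof.c_gs) == 0.0
        assert prof.c_ro[0] / prof.c_gs[0] == pytest.approx(1.527, abs=2e-3)
        assert prof.c_ro[-1] / prof.c_gs[-1] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(prof.c_ro) <= 1e-12 * prof.c_ro[0])
        assert np.all(prof.c_ro >= prof.c_gs - 1e-9)
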