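"""CD deconvolution, unfolding onset, and single-wavelength Tm."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cryostab.cd_deconv import (
    BasisSet,
    CDSpectrum,
    deconvolve_fractions,
    fraction_trajectory,
    onset_temperature,
    reference_basis,
    tm_at_wavelength,
)
from cryostab.melt import NoTransitionError, _fit_two_state_arrays
from cryostab.synthetic import synth_cd_series, two_state_schedule

TEMPS = np.arange(20.0, 91.0, 2.0)


class TestDeconvolve:
    def test_pure_component_recovery(self, basis):
        for i, name in enumerate(basis.names):
            spec = CDSpectrum(basis.wavelength, basis.spectra[i], 20.0)
            f, res = deconvolve_fractions(spec, basis)
            expected = np.zeros(4)
            expected[i] = 1.0
            np.testing.assert_allclose(f, expected, atol=1e-9)
            assert res < 1e-9

    def test_noiseless_mixture_recovery(self, basis):
        mix = np.array([0.5, 0.3, 0.15, 0.05])
        spec = CDSpectrum(basis.wavelength, mix @ basis.spectra, 25.0)
        f, res = deconvolve_fractions(spec, basis)
        np.testing.assert_allclose(f, mix, atol=1e-6)
        assert res < 1e-9

    def test_noisy_mixture_mean_error(self, basis):
        """Mean absolute fraction error stays below 0.05 at 2% noise (30-seed
        slice; the 100-seed version runs in the acceptance suite)."""
        mix = np.array([0.5, 0.3, 0.15, 0.05])
        scale = 0.02 * float(np.max(np.abs(basis.spectra)))
        errs = []
        for s in range(30):
            noise = np.random.default_rng(s).normal(0, scale, basis.wavelength.shape)
            spec = CDSpectrum(basis.wavelength, mix @ basis.spectra + noise, 25.0)
            f, _ = deconvolve_fractions(spec, basis)
            errs.append(np.mean(np.abs(f - mix)))
        assert np.mean(errs) < 0.05

    @given(st.integers(0, 10_000))
    def test_fractions_always_on_simplex(self, seed):
        """Any input spectrum yields non-negative fractions summing to one."""
        basis = reference_basis()
        rng = np.random.default_rng(seed)
        spec = CDSpectrum(basis.wavelength, rng.normal(0, 5, basis.wavelength.shape), 20.0)
        f, _ = deconvolve_fractions(spec, basis)
        assert np.all(f >= 0)
        assert f.sum() == pytest.approx(1.0, abs=1e-6)

    def test_scaling_caveat(self, basis):
        """Scaling spectrum and basis together preserves fractions; scaling the
        spectrum alone does not (sum-to-one pins the scale)."""
        mix = np.array([0.25, 0.25, 0.25, 0.25])
        y = mix @ basis.spectra
        f1, _ = deconvolve_fractions(CDSpectrum(basis.wavelength, 3 * y, 20.0),
                                     BasisSet(basis.names, basis.wavelength, 3 * basis.spectra))
        np.testing.assert_allclose(f1, mix, atol=1e-6)
        f2, res2 = deconvolve_fractions(CDSpectrum(basis.wavelength, 3 * y, 20.0), basis)
        assert res2 > 1e-3  # scaled spectrum no longer fits in the simplex span

    def test_rank_deficient_basis_rejected(self, basis):
        spectra = basis.spectra.copy()
        spectra[3] = spectra[0] + spectra[1]
        with pytest.raises(ValueError):
            BasisSet(basis.names, basis.wavelength, spectra)

    def test_grid_resampling(self, basis):
        """A spectrum on a coarser grid is matched by linear resampling."""
        wl = np.arange(195.0, 245.5, 1.0)
        mix = np.array([0.6, 0.2, 0.1, 0.1])
        dense = mix @ basis.spectra
        coarse = np.interp(wl, basis.wavelength, dense)
        f, _ = deconvolve_fractions(CDSpectrum(wl, coarse, 20.0), basis)
        np.testing.assert_allclose(f, mix, atol=1e-3)


class TestTrajectory:
    def test_constant_series(self, basis):
        sch = np.tile([0.4, 0.3, 0.2, 0.1], (len(TEMPS), 1))
        series = synth_cd_series(sch, temperatures=TEMPS, noise_frac=0.0)
        traj = fraction_trajectory(series, basis)
        np.testing.assert_allclose(traj.fractions, sch, atol=1e-8)

    def test_monotone_helix_handoff(self, basis):
        """A linear helix->other handoff between 46 and 70 degC shows as a
        monotone helix decrease over that interval."""
        sch = two_state_schedule(TEMPS, tm=58.0, dH=250.0)
        series = synth_cd_series(sch, temperatures=TEMPS, noise_frac=0.0)
        traj = fraction_trajectory(series, basis)
        helix = traj.fractions[:, 0]
        window = (TEMPS >= 46) & (TEMPS <= 70)
        assert np.all(np.diff(helix[window]) < 1e-9)

    def test_schedule_inversion(self, basis):
        sch = two_state_schedule(TEMPS, tm=50.0, dH=300.0)
        series = synth_cd_series(sch, temperatures=TEMPS, noise_frac=0.0)
        traj = fraction_trajectory(series, basis)
        np.testing.assert_allclose(traj.fractions, sch, atol=1e-6)


class TestOnset:
    def _stable_then_diverge(self, onset_t, noise=0.01, seed=2):
        """Stable composition below onset_t, then a linear folded->unfolded
        handoff completing 24 degC later."""
        folded = np.array([0.62, 0.20, 0.08, 0.10])
        unfolded = np.array([0.04, 0.10, 0.14, 0.72])
        lam = np.clip((TEMPS - (onset_t - 2.0)) / 24.0, 0.0, 1.0)
        sch = (1 - lam)[:, None] * folded + lam[:, None] * unfolded
        return synth_cd_series(sch, temperatures=TEMPS, noise_frac=noise, seed=seed)

    def test_constant_series_returns_none(self):
        sch = np.tile([0.5, 0.2, 0.2, 0.1], (len(TEMPS), 1))
        series = synth_cd_series(sch, temperatures=TEMPS, noise_frac=0.01, seed=1)
        assert onset_temperature(series) is None

    def test_divergence_at_46_recovered(self):
        series = self._stable_then_diverge(46.0)
        assert onset_temperature(series) == pytest.approx(46.0, abs=2.0)

    def test_z_monotonicity(self):
        """Raising z can only raise or remove the onset, never lower it."""
        series = self._stable_then_diverge(46.0)
        onsets = [onset_temperature(series, z=z) for z in (2.0, 3.0, 6.0, 50.0)]
        seen = [o for o in onsets if o is not None]
        assert seen == sorted(seen)
        for a, b in zip(onsets, onsets[1:]):
            if a is None:
                assert b is None

    def test_false_positive_rate_on_noise(self):
        """<=5% spurious onsets on pure-noise constant series at z=3."""
        sch = np.tile([0.25, 0.25, 0.25, 0.25], (len(TEMPS), 1))
        fp = sum(
            onset_temperature(
                synth_cd_series(sch, temperatures=TEMPS, noise_frac=0.01, seed=7000 + s)
            )
            is not None
            for s in range(40)
        )
        assert fp / 40 <= 0.05


class TestTmAtWavelength:
    def test_sigmoid_recovery_at_210(self):
        sch = two_state_schedule(TEMPS, tm=47.8, dH=300.0)
        series = synth_cd_series(sch, temperatures=TEMPS, noise_frac=0.005, seed=3)
        tm, fit = tm_at_wavelength(series, 210.0)
        assert tm == pytest.approx(47.8, abs=0.5)

    def test_flat_trace_raises(self, basis):
        sch = np.tile([0.5, 0.2, 0.2, 0.1], (len(TEMPS), 1))
        series = synth_cd_series(sch, temperatures=TEMPS, noise_frac=0.002, seed=4)
        with pytest.raises(NoTransitionError):
            tm_at_wavelength(series, 210.0)

    def test_agrees_with_helix_fraction_midpoint(self, basis):
        """Tm from the helix-fraction trajectory matches the 210 nm trace."""
        sch = two_state_schedule(TEMPS, tm=52.0, dH=300.0)
        series = synth_cd_series(sch, temperatures=TEMPS, noise_frac=0.005, seed=5)
        tm_210, _ = tm_at_wavelength(series, 210.0)
        traj = fraction_trajectory(series, basis)
        helix_fit = _fit_two_state_arrays(traj.temperatures, traj.fractions[:, 0])
        assert tm_210 == pytest.approx(helix_fit.tm, abs=2.0)
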