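"""Woody alignment, template projection and template derivation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nnrf.preprocess import baseline_correct
from nnrf.synthetic import CohortConfig, simulate_epochset, template_amplitude
from nnrf.template import (
    Template,
    WoodyConfig,
    derive_template,
    magnitudes,
    project,
    read_template,
    woody_align,
    write_template,
)

RATE = 500.0


def _epoch_with_template(shift_ms: float, magnitude: float = 1.0,
                         noise: np.ndarray | None = None) -> np.ndarray:
    t = -1000.0 + np.arange(int(2 * RATE)) * 1000.0 / RATE
    x = magnitude * template_amplitude(t - shift_ms)
    if noise is not None:
        x = x + noise
    return x


def brute_force_woody(epoch, template, max_jitter_ms, rate, tmin_ms):
    """Independent exhaustive double loop: shifts x closed-form regression."""
    length = template.samples.size
    i0 = int(round((template.window_ms[0] - tmin_ms) * rate / 1000.0))
    jmax = int(round(max_jitter_ms * rate / 1000.0))
    best = None
    for s in sorted(range(-jmax, jmax + 1), key=lambda s: (abs(s), s)):
        seg = epoch[i0 + s: i0 + s + length]
        sc, tc = seg - seg.mean(), template.samples - template.samples.mean()
        denom = np.sqrt((sc**2).sum() * (tc**2).sum())
        r = (sc * tc).sum() / denom if denom > 0 else -np.inf
        if best is None or r > best[0]:
            mag = float(seg @ template.samples / (template.samples @ template.samples))
            best = (r, s, mag)
    return best[1] * 1000.0 / rate, best[2]


class TestWoodyAlign:
    def test_self_alignment_returns_zero_shift(self, template):
        shift, seg = woody_align(
            _epoch_with_template(0.0), template, rate=RATE, tmin_ms=-1000.0
        )
        assert shift == 0.0
        assert np.allclose(seg, template.samples)

    @pytest.mark.parametrize("true_shift", [-80.0, -22.0, 50.0, 98.0])
    def test_recovers_injected_delay(self, template, true_shift):
        shift, _ = woody_align(
            _epoch_with_template(true_shift), template, rate=RATE, tmin_ms=-1000.0
        )
        assert shift == true_shift

    def test_shift_beyond_bound_clips_to_search_boundary(self, template):
        shift, _ = woody_align(
            _epoch_with_template(150.0), template, rate=RATE, tmin_ms=-1000.0
        )
        assert shift == 100.0

    def test_tie_break_prefers_zero_shift(self, template):
        # all-zero epoch: every shift scores identically
        zero = np.zeros(int(2 * RATE))
        cfg = WoodyConfig(criterion="covariance")
        shift, _ = woody_align(zero, template, cfg, rate=RATE, tmin_ms=-1000.0)
        assert shift == 0.0

    def test_epoch_too_short_for_search_raises(self, template):
        with pytest.raises(ValueError, match="too short"):
            woody_align(np.zeros(100), template, rate=RATE, tmin_ms=400.0)

    def test_matches_brute_force_oracle_on_noisy_epochs(self, template, rng):
        for _ in range(20):
            epoch = _epoch_with_template(
                float(rng.integers(-50, 51)) * 2.0,
                magnitude=float(rng.normal(1.0, 0.5)),
                noise=rng.standard_normal(int(2 * RATE)) * 10.0,
            )
            shift, seg = woody_align(epoch, template, rate=RATE, tmin_ms=-1000.0)
            mag = project(seg, template)
            o_shift, o_mag = brute_force_woody(epoch, template, 100.0, RATE, -1000.0)
            assert shift == o_shift
            assert mag == pytest.approx(o_mag, abs=1e-12)


class TestAlignmentResolution:
    """Latency resolution of the correlation search on this smooth waveform."""

    @staticmethod
    def _recovery_errors(snr: float, rate: float = 1000.0) -> np.ndarray:
        from nnrf.template import Template as _T
        from nnrf.synthetic import make_template_waveform

        template = _T.from_waveform(make_template_waveform(rate))
        noise_rms = float(np.sqrt(np.mean(template.samples**2))) / snr
        rng = np.random.default_rng(7)
        n = int(2 * rate)
        t = -1000.0 + np.arange(n) * 1000.0 / rate
        errs = []
        for true_shift in range(-100, 101, 4):
            epoch = template_amplitude(t - true_shift)
            epoch += rng.standard_normal(n) * noise_rms
            shift, _ = woody_align(epoch, template, rate=rate, tmin_ms=-1000.0)
            errs.append(abs(shift - true_shift))
        return np.asarray(errs)

    def test_exact_recovery_in_the_high_snr_regime(self):
        assert np.all(self._recovery_errors(snr=100.0) == 0.0)

    def test_moderate_snr_recovery_within_waveform_resolution(self):
        # the ~30 Hz band limit flattens the correlation peak; at SNR 5
        # latency error stays within a few ms but is not sample-exact
        errs = self._recovery_errors(snr=5.0)
        assert errs.max() <= 8.0
        assert errs.mean() <= 3.0

    def test_projection_without_search_is_unbiased_for_weak_responses(self):
        """Disabling the latency search removes the selection bias."""
        cfg = CohortConfig(
            n_participants=150, rate=RATE, seed=8, noise_rms=10.0,
            sites={"A": 1.3}, control_mean=0.42, control_sd=0.33,
            latency_jitter_bound=0.0,
        )
        epochs, _ = simulate_epochset(cfg)
        clean = baseline_correct(epochs.crop(-500.0, 1000.0))
        from nnrf.template import Template as _T
        from nnrf.synthetic import make_template_waveform

        tpl = _T.from_waveform(make_template_waveform(RATE))
        mags = magnitudes(clean, tpl, WoodyConfig(max_jitter_ms=0.0))
        ctrl = mags.loc[mags["stimulus"] == "control_lance", "magnitude"]
        se = ctrl.std(ddof=1) / np.sqrt(len(ctrl))
        assert abs(ctrl.mean() - 0.42) < 3 * se


class TestProjection:
    def test_self_projection_is_unity(self, template):
        assert project(template.samples, template) == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(k=st.floats(-10, 10))
    def test_projection_is_linear_in_the_segment(self, template, k):
        assert project(k * template.samples, template) == pytest.approx(k, abs=1e-9)

    def test_orthogonal_segment_projects_to_zero(self, template, rng):
        v = rng.standard_normal(template.samples.size)
        t = template.samples
        v -= (v @ t) / (t @ t) * t
        assert project(v, template) == pytest.approx(0.0, abs=1e-12)
        # adding an orthogonal component never changes the magnitude
        assert project(2.5 * t + 40.0 * v, template) == pytest.approx(2.5)

    def test_zero_energy_template_rejected(self, template):
        empty = Template(np.zeros_like(template.samples), RATE)
        with pytest.raises(ValueError, match="zero-energy"):
            project(template.samples, empty)


class TestDeriveTemplate:
    def _reference_epochs(self, n=20, noise_rms=0.0, seed=3):
        cfg = CohortConfig(
            n_participants=n, rate=RATE, noise_rms=noise_rms, seed=seed,
            sites={"A": 1.0}, magnitude_sd=0.3, include_control=False,
            latency_jitter_bound=0.0,
        )
        epochs, _ = simulate_epochset(cfg)
        return baseline_correct(epochs.crop(-500.0, 1000.0))

    def test_recovers_true_shape_from_scaled_noiseless_epochs(self, template):
        derived = derive_template(self._reference_epochs())
        r = np.corrcoef(derived.samples, template.samples)[0, 1]
        assert r > 0.999

    def test_mean_reference_projection_is_exactly_one(self):
        epochs = self._reference_epochs(noise_rms=5.0)
        derived = derive_template(epochs)
        mags = magnitudes(epochs, derived)
        assert abs(mags["magnitude"].mean() - 1.0) < 1e-9
        assert derived.norm_constant != 1.0

    def test_requires_at_least_ten_reference_epochs(self):
        with pytest.raises(ValueError, match="10"):
            derive_template(self._reference_epochs(n=5))


class TestMagnitudes:
    def test_noise_free_cohort_recovers_truth_exactly(self, clean_cohort, template):
        _, epochs, table = clean_cohort
        mags = magnitudes(epochs, template)
        merged = mags.merge(
            table.rename(columns={"participant_id": "participant"}),
            on=["participant", "stimulus"],
        )
        assert np.allclose(merged["magnitude"], merged["magnitude_truth"], atol=1e-9)
        assert np.allclose(merged["shift_ms"], merged["shift_truth_ms"], atol=1e-9)

    def test_rejected_epochs_absent_from_output(self, clean_cohort, template):
        _, epochs, _ = clean_cohort
        flagged = epochs.select(np.ones(epochs.n_epochs, bool))
        flagged.rejected[:] = True
        flagged.rejected[0] = False
        out = magnitudes(flagged, template)
        assert len(out) == 1
        all_rejected = epochs.select(np.ones(epochs.n_epochs, bool))
        all_rejected.rejected[:] = True
        assert magnitudes(all_rejected, template).empty


class TestTemplateIO:
    def test_round_trip_preserves_template(self, template, tmp_path):
        path = tmp_path / "template.tsv"
        t2 = Template(
            template.samples * 1.7, RATE, norm_constant=1.7, converged=False
        )
        write_template(t2, path)
        back = read_template(path)
        assert np.allclose(back.samples, t2.samples, atol=1e-7)
        assert back.norm_constant == pytest.approx(1.7)
        assert back.rate == RATE and back.converged is False
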