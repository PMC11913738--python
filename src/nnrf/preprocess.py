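"""Resampling, FIR filtering, epoching, baseline correction and rejection.

The processing chain mirrors standard neonatal evoked-potential practice:
continuous Cz EEG is resampled to the working rate (2000 Hz by default),
band-pass filtered with Hamming-windowed sinc FIR filters (high-pass −6 dB
cut-off 0.5 Hz with 1 Hz transition bandwidth, low-pass −6 dB cut-off
33.75 Hz with 7.5 Hz transition bandwidth, optional 50 Hz notch), epoched
around stimulus annotations, baseline-corrected to the pre-stimulus mean,
and screened with amplitude-based rejection rules (±150 µV anywhere in the
assessment window; >100 µV peak-to-peak in the pre-stimulus baseline).

Filters are linear-phase designs applied with group-delay compensation, so
output is zero-phase with respect to the input.  Rejection comparisons are
strict (a sample at exactly ±150 µV is retained).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .epochs import EpochSet

__all__ = [
    "FilterSpec",
    "RejectionCriteria",
    "resample",
    "design_fir",
    "fir_filter",
    "cut_epochs",
    "baseline_correct",
    "reject_epochs",
    "rejection_report",
]

# Hamming-window design rule: order ~ 3.3 / (transition width / rate)
_HAMMING_TBW_FACTOR = 3.3


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass (+ optional notch) FIR specification; cutoffs at −6 dB."""

    highpass_hz: float = 0.5
    highpass_tbw_hz: float = 1.0
    lowpass_hz: float = 33.75
    lowpass_tbw_hz: float = 7.5
    notch_hz: float | None = None
    notch_halfwidth_hz: float = 2.5
    notch_tbw_hz: float = 2.0

    def __post_init__(self):
        if not 0.0 < self.highpass_hz < self.lowpass_hz:
            raise ValueError("need 0 < highpass cutoff < lowpass cutoff")
        if self.highpass_tbw_hz <= 0 or self.lowpass_tbw_hz <= 0:
            raise ValueError("transition bandwidths must be positive")


@dataclass(frozen=True)
class RejectionCriteria:
    """Amplitude rejection rules, strict-inequality comparisons."""

    amplitude_uv: float = 150.0
    baseline_range_uv: float = 100.0
    window_ms: tuple[float, float] = (-500.0, 1000.0)

    def __post_init__(self):
        if self.amplitude_uv <= 0 or self.baseline_range_uv <= 0:
            raise ValueError("rejection bounds must be positive")


def resample(x: np.ndarray, from_rate: float, to_rate: float) -> np.ndarray:
    """Polyphase rational-ratio resampling with anti-alias filtering.

    Output length is ``ceil(len(x) * to_rate / from_rate)``; identity when
    the rates are equal.
    """
    if from_rate <= 0 or to_rate <= 0:
        raise ValueError("rates must be positive")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    if from_rate == to_rate:
        return x.copy()
    ratio = Fraction(to_rate / from_rate).limit_denominator(10000)
    return sps.resample_poly(x, ratio.numerator, ratio.denominator)


def _numtaps(tbw_hz: float, rate: float) -> int:
    """Odd tap count from the Hamming transition-bandwidth rule."""
    order = int(np.ceil(_HAMMING_TBW_FACTOR / (tbw_hz / rate)))
    order += order % 2  # even order -> odd, type-I symmetric taps
    return order + 1


def design_fir(spec: FilterSpec, rate: float) -> list[np.ndarray]:
    """Windowed-sinc taps: one band-pass stage (+ one notch stage if set)."""
    if spec.lowpass_hz >= rate / 2:
        raise ValueError("lowpass cutoff must be below Nyquist")
    n_bp = _numtaps(min(spec.highpass_tbw_hz, spec.lowpass_tbw_hz), rate)
    stages = [
        sps.firwin(
            n_bp,
            [spec.highpass_hz, spec.lowpass_hz],
            pass_zero=False,
            window="hamming",
            fs=rate,
        )
    ]
    if spec.notch_hz is not None:
        n_notch = _numtaps(spec.notch_tbw_hz, rate)
        stages.append(
            sps.firwin(
                n_notch,
                [
                    spec.notch_hz - spec.notch_halfwidth_hz,
                    spec.notch_hz + spec.notch_halfwidth_hz,
                ],
                pass_zero=True,
                window="hamming",
                fs=rate,
            )
        )
    return stages


def fir_filter(x: np.ndarray, spec: FilterSpec, rate: float) -> np.ndarray:
    """Apply the FIR stages zero-phase (group-delay compensated single pass)."""
    x = np.asarray(x, dtype=float)
    for taps in design_fir(spec, rate):
        if x.size < taps.size:
            raise ValueError(
                f"signal length {x.size} shorter than filter length {taps.size}"
            )
        # odd symmetric taps: 'same' convolution realigns the group delay
        x = sps.fftconvolve(x, taps, mode="same")
    return x


def cut_epochs(
    x: np.ndarray,
    annotations_ms: np.ndarray,
    window_ms: tuple[float, float],
    rate: float,
    info: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut stimulus-locked epochs from a continuous record.

    The window ``(pre_ms, post_ms)`` is half-open ``[-pre, +post)``: a
    (500, 1000) ms window at 2000 Hz yields exactly 3000 samples with sample
    1000 at t = 0.  Annotations too close to the record edge raise a
    ``ValueError`` naming the annotation.
    """
    x = np.asarray(x, dtype=float)
    pre_ms, post_ms = window_ms
    n_pre = int(round(pre_ms * rate / 1000.0))
    n_post = int(round(post_ms * rate / 1000.0))
    segs = []
    for t_ann in np.atleast_1d(annotations_ms):
        i0 = int(round(t_ann * rate / 1000.0))
        lo, hi = i0 - n_pre, i0 + n_post
        if lo < 0 or hi > x.size:
            raise ValueError(
                f"annotation at {t_ann} ms does not leave room for the "
                f"[-{pre_ms}, +{post_ms}) ms window"
            )
        segs.append(x[lo:hi])
    data = np.asarray(segs)
    if info is None:
        info = pd.DataFrame(
            {
                "participant": [f"epoch{i}" for i in range(data.shape[0])],
                "stimulus": ["unknown"] * data.shape[0],
            }
        )
    return EpochSet(data, rate, -pre_ms, info)


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each epoch's pre-stimulus (t < 0) mean."""
    pre = epochs.times_ms < 0.0
    if not pre.any():
        raise ValueError("epochs contain no pre-stimulus samples")
    data = epochs.data - epochs.data[:, pre].mean(axis=1, keepdims=True)
    return EpochSet(
        data,
        epochs.rate,
        epochs.tmin_ms,
        epochs.info.copy(),
        epochs.rejected.copy(),
        epochs.reject_reason.copy(),
    )


def reject_epochs(
    epochs: EpochSet, criteria: RejectionCriteria = RejectionCriteria()
) -> EpochSet:
    """Flag epochs breaching the amplitude rules (flags only, nothing dropped).

    Reason "amplitude": any |sample| strictly greater than the bound within
    the assessment window.  Reason "baseline_range": pre-stimulus max−min
    strictly greater than the bound.  Amplitude takes precedence when both
    apply.  Re-application is idempotent; pre-existing "manual" flags are
    preserved.
    """
    t = epochs.times_ms
    in_win = (t >= criteria.window_ms[0]) & (t < criteria.window_ms[1])
    pre = t < 0.0
    amp = np.abs(epochs.data[:, in_win]).max(axis=1) > criteria.amplitude_uv
    base = (
        epochs.data[:, pre].max(axis=1) - epochs.data[:, pre].min(axis=1)
    ) > criteria.baseline_range_uv
    reason = np.array(["none"] * epochs.n_epochs, dtype=object)
    reason[base] = "baseline_range"
    reason[amp] = "amplitude"
    manual = epochs.reject_reason == "manual"
    reason[manual] = "manual"
    rejected = amp | base | manual
    return EpochSet(
        epochs.data.copy(), epochs.rate, epochs.tmin_ms, epochs.info.copy(),
        rejected, reason,
    )


def rejection_report(epochs: EpochSet) -> pd.DataFrame:
    """Per-epoch rejection table (participant, stimulus, reason)."""
    return pd.DataFrame(
        {
            "participant": epochs.info["participant"],
            "stimulus": epochs.info["stimulus"],
            "rejected": epochs.rejected,
            "reason": epochs.reject_reason,
        }
    )
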