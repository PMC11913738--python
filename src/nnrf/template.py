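"""n-NRF template projection with Woody latency alignment.

The noxious neurodynamic response function (n-NRF) is a fixed template
waveform.  Each single trial is first Woody-aligned to the template — an
exhaustive search over integer-sample latency shifts within ±100 ms that
maximises the Pearson correlation between the template and the epoch segment
in the 400–700 ms post-stimulus fit window — and the template is then
projected onto the aligned segment by least squares without intercept.  The
resulting scaling factor is the per-trial response magnitude.

The template is normalised so that the mean magnitude over a reference set
of noxious trials equals exactly 1.0, which puts magnitudes from new data on
a common, interpretable scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .synthetic import TemplateWaveform

__all__ = [
    "Template",
    "WoodyConfig",
    "woody_align",
    "project",
    "derive_template",
    "magnitudes",
    "write_template",
    "read_template",
]

FIT_WINDOW_MS = (400.0, 700.0)  # half-open [400, 700)


@dataclass(frozen=True)
class WoodyConfig:
    """Alignment search: ±``max_jitter_ms`` in steps of ``step_samples``.

    ``criterion`` is "correlation" (scale-invariant, default) or
    "covariance".
    """

    max_jitter_ms: float = 100.0
    step_samples: int = 1
    criterion: str = "correlation"

    def __post_init__(self):
        if self.max_jitter_ms < 0:
            raise ValueError("max jitter must be >= 0")
        if self.step_samples < 1:
            raise ValueError("step must be >= 1 sample")
        if self.criterion not in ("correlation", "covariance"):
            raise ValueError("criterion must be 'correlation' or 'covariance'")


@dataclass(frozen=True)
class Template:
    """The n-NRF restricted to its fit window.

    ``samples`` live on the half-open fit window at ``rate``;
    ``norm_constant`` is the factor the raw waveform was multiplied by so
    that the mean reference projection equals 1.0 (1.0 when supplied
    unnormalised).  ``converged`` records the iterative derivation status.
    """

    samples: np.ndarray
    rate: float
    window_ms: tuple[float, float] = FIT_WINDOW_MS
    norm_constant: float = 1.0
    converged: bool = True

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("template amplitudes must be finite")
        expected = int(round((self.window_ms[1] - self.window_ms[0]) * self.rate / 1000.0))
        if self.samples.size != expected:
            raise ValueError(
                f"template has {self.samples.size} samples, fit window needs {expected}"
            )

    @classmethod
    def from_waveform(
        cls,
        waveform: TemplateWaveform,
        window_ms: tuple[float, float] = FIT_WINDOW_MS,
    ) -> "Template":
        """Restrict a full waveform to the fit window."""
        i0 = int(round((window_ms[0] - waveform.t0_ms) * waveform.rate / 1000.0))
        i1 = int(round((window_ms[1] - waveform.t0_ms) * waveform.rate / 1000.0))
        if i0 < 0 or i1 > waveform.samples.size:
            raise ValueError("waveform does not cover the fit window")
        return cls(waveform.samples[i0:i1].copy(), waveform.rate, window_ms)


def _fit_segments(epoch: np.ndarray, i0: int, length: int, shifts: np.ndarray) -> np.ndarray:
    return np.stack([epoch[i0 + s : i0 + s + length] for s in shifts])


def woody_align(
    epoch: np.ndarray,
    template: Template,
    cfg: WoodyConfig = WoodyConfig(),
    *,
    rate: float,
    tmin_ms: float,
) -> tuple[float, np.ndarray]:
    """Best latency shift (ms) and the re-registered fit-window segment.

    Exhaustive search over integer-sample shifts within ±max jitter.  Ties in
    the criterion are broken towards the smallest |shift|, then the negative
    one.  The epoch must cover [fit start − jitter, fit end + jitter].
    """
    if rate != template.rate:
        raise ValueError("epoch and template rates differ")
    epoch = np.asarray(epoch, dtype=float)
    length = template.samples.size
    i0 = int(round((template.window_ms[0] - tmin_ms) * rate / 1000.0))
    jmax = int(round(cfg.max_jitter_ms * rate / 1000.0))
    if i0 - jmax < 0 or i0 + jmax + length > epoch.size:
        raise ValueError("epoch too short for the alignment search range")
    # search order encodes the tie-break: 0, -1, +1, -2, +2, ...
    order = sorted(
        range(-jmax, jmax + 1, cfg.step_samples), key=lambda s: (abs(s), s)
    )
    shifts = np.asarray(order)
    segs = _fit_segments(epoch, i0, length, shifts)
    t = template.samples
    if cfg.criterion == "correlation":
        tc = t - t.mean()
        sc = segs - segs.mean(axis=1, keepdims=True)
        denom = np.sqrt((tc**2).sum()) * np.sqrt((sc**2).sum(axis=1))
        with np.errstate(invalid="ignore"):
            score = np.where(denom > 0, sc @ tc / denom, -np.inf)
    else:
        score = segs @ t
    best = int(np.argmax(score))  # argmax returns the first max -> tie-break
    shift_samples = int(shifts[best])
    return shift_samples * 1000.0 / rate, segs[best].copy()


def project(segment: np.ndarray, template: Template) -> float:
    """Least-squares scaling factor ⟨segment, template⟩ / ⟨template, template⟩."""
    t = template.samples
    energy = float(t @ t)
    if energy == 0.0:
        raise ValueError("zero-energy template")
    return float(np.asarray(segment, dtype=float) @ t / energy)


def derive_template(
    epochs: EpochSet,
    cfg: WoodyConfig = WoodyConfig(),
    window_ms: tuple[float, float] = FIT_WINDOW_MS,
    tol: float = 1e-8,
    max_iter: int = 20,
) -> Template:
    """Derive a normalised template from reference (noxious) epochs.

    Iterative Woody procedure: start from the plain average over the fit
    window, then repeatedly re-align every un-rejected epoch to the current
    template and re-average the aligned segments, until the template change
    falls below ``tol`` (relative to its RMS) or ``max_iter`` iterations.
    The result is rescaled so the mean projection magnitude over the
    reference epochs equals exactly 1.0.  Requires >= 10 un-rejected epochs.
    """
    use = epochs.select(epochs.kept)
    if use.n_epochs < 10:
        raise ValueError(
            f"need at least 10 un-rejected reference epochs, got {use.n_epochs}"
        )
    i0 = use.sample_index(window_ms[0])
    i1 = use.sample_index(window_ms[1])
    current = use.data[:, i0:i1].mean(axis=0)
    converged = False
    for _ in range(max_iter):
        tpl = Template(current, use.rate, window_ms)
        aligned = np.stack(
            [
                woody_align(x, tpl, cfg, rate=use.rate, tmin_ms=use.tmin_ms)[1]
                for x in use.data
            ]
        )
        new = aligned.mean(axis=0)
        scale = np.sqrt(np.mean(new**2))
        if scale > 0 and np.max(np.abs(new - current)) < tol * scale:
            current = new
            converged = True
            break
        current = new
    tpl = Template(current, use.rate, window_ms)
    aligned = np.stack(
        [
            woody_align(x, tpl, cfg, rate=use.rate, tmin_ms=use.tmin_ms)[1]
            for x in use.data
        ]
    )
    mean_proj = float(np.mean([project(seg, tpl) for seg in aligned]))
    if mean_proj <= 0:
        raise ValueError("mean reference projection is not positive")
    return Template(
        current * mean_proj,
        use.rate,
        window_ms,
        norm_constant=mean_proj,
        converged=converged,
    )


def magnitudes(
    epochs: EpochSet, template: Template, cfg: WoodyConfig = WoodyConfig()
) -> pd.DataFrame:
    """Per-trial Woody shift and projection magnitude for un-rejected epochs.

    Returns one row per surviving epoch with the epoch's labels joined in;
    rejected epochs are absent from the output.
    """
    rows = []
    carry = [c for c in ("participant", "site", "stimulus") if c in epochs.info]
    for i in range(epochs.n_epochs):
        if epochs.rejected[i]:
            continue
        shift, seg = woody_align(
            epochs.data[i], template, cfg, rate=epochs.rate, tmin_ms=epochs.tmin_ms
        )
        row = {c: epochs.info[c].iloc[i] for c in carry}
        row["shift_ms"] = shift
        row["magnitude"] = project(seg, template)
        rows.append(row)
    return pd.DataFrame(rows, columns=carry + ["shift_ms", "magnitude"])


def write_template(template: Template, path) -> None:
    """Two-column text file (time_ms, amplitude) with a metadata header."""
    t0, t1 = template.window_ms
    times = t0 + np.arange(template.samples.size) * 1000.0 / template.rate
    header = (
        f"# rate_hz={template.rate}\n"
        f"# fit_window_ms={t0},{t1}\n"
        f"# norm_constant={template.norm_constant!r}\n"
        f"# converged={template.converged}\n"
        "time_ms\tamplitude\n"
    )
    body = "".join(
        f"{tt:.6f}\t{aa:.9g}\n" for tt, aa in zip(times, template.samples)
    )
    Path(path).write_text(header + body)


def read_template(path) -> Template:
    meta = {}
    lines = Path(path).read_text().splitlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
        elif line and not line.startswith("time_ms"):
            data_lines.append(line)
    amp = np.array([float(l.split("\t")[1]) for l in data_lines])
    w0, w1 = (float(x) for x in meta["fit_window_ms"].split(","))
    return Template(
        amp,
        float(meta["rate_hz"]),
        (w0, w1),
        norm_constant=float(meta["norm_constant"]),
        converged=meta.get("converged", "True") == "True",
    )
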