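"""Stimulus-locked EEG epoch container.

An :class:`EpochSet` holds a stack of single-channel (Cz) epochs on a shared,
uniformly sampled time axis expressed in milliseconds relative to the stimulus,
together with per-epoch labels (participant, site, stimulus type) and rejection
flags.  Amplitudes are in microvolts throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REJECT_REASONS = ("none", "amplitude", "baseline_range", "manual")


@dataclass
class EpochSet:
    """A set of equal-length epochs on a shared time axis.

    Parameters
    ----------
    data
        Array of shape ``(n_epochs, n_samples)``, amplitudes in µV.
    rate
        Sampling rate in samples/second.
    tmin_ms
        Time of the first sample relative to the stimulus, in ms.
    info
        One row per epoch.  Expected columns include ``participant`` and
        ``stimulus``; anything else (site, ages, truth columns) is carried
        along untouched.
    rejected
        Boolean flag per epoch; rejected epochs are excluded from all
        downstream statistics.
    reject_reason
        One of :data:`REJECT_REASONS` per epoch.
    """

    data: np.ndarray
    rate: float
    tmin_ms: float
    info: pd.DataFrame
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    reject_reason: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_epochs, n_samples)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        n = self.data.shape[0]
        if len(self.info) != n:
            raise ValueError("info must have one row per epoch")
        self.info = self.info.reset_index(drop=True)
        if self.rejected is None:
            self.rejected = np.zeros(n, dtype=bool)
        else:
            self.rejected = np.asarray(self.rejected, dtype=bool).copy()
        if self.reject_reason is None:
            self.reject_reason = np.array(["none"] * n, dtype=object)
        else:
            self.reject_reason = np.asarray(self.reject_reason, dtype=object).copy()

    # -- basic geometry ------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        """Shared time axis in ms relative to the stimulus."""
        return self.tmin_ms + np.arange(self.n_samples) * 1000.0 / self.rate

    @property
    def kept(self) -> np.ndarray:
        """Boolean mask of un-rejected epochs."""
        return ~self.rejected

    # -- manipulation --------------------------------------------------
    def sample_index(self, t_ms: float) -> int:
        """Index of the sample at time ``t_ms`` (nearest-sample rounding)."""
        return int(round((t_ms - self.tmin_ms) * self.rate / 1000.0))

    def crop(self, tmin_ms: float, tmax_ms: float) -> "EpochSet":
        """Return epochs restricted to the half-open window ``[tmin, tmax)``."""
        i0 = self.sample_index(tmin_ms)
        i1 = self.sample_index(tmax_ms)
        if i0 < 0 or i1 > self.n_samples or i0 >= i1:
            raise ValueError(
                f"crop window [{tmin_ms}, {tmax_ms}) ms outside epoch span "
                f"[{self.tmin_ms}, {self.times_ms[-1] + 1000.0 / self.rate}) ms"
            )
        return EpochSet(
            self.data[:, i0:i1].copy(),
            self.rate,
            self.tmin_ms + i0 * 1000.0 / self.rate,
            self.info.copy(),
            self.rejected.copy(),
            self.reject_reason.copy(),
        )

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Return the subset of epochs where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return EpochSet(
            self.data[mask].copy(),
            self.rate,
            self.tmin_ms,
            self.info.loc[mask].reset_index(drop=True),
            self.rejected[mask].copy(),
            self.reject_reason[mask].copy(),
        )

    # -- I/O: columnar text format ------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (epoch, sample)."""
        t = self.times_ms
        n, m = self.data.shape
        out = pd.DataFrame(
            {
                "epoch": np.repeat(np.arange(n), m),
                "participant_id": np.repeat(
                    self.info["participant"].to_numpy(), m
                ),
                "stimulus": np.repeat(self.info["stimulus"].to_numpy(), m),
                "time_ms": np.tile(t, n),
                "amplitude_uV": self.data.ravel(),
            }
        )
        return out

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, rate: float) -> "EpochSet":
        """Rebuild an EpochSet from the long columnar format."""
        groups = list(frame.groupby("epoch", sort=True))
        rows, data = [], []
        for _, g in groups:
            g = g.sort_values("time_ms")
            data.append(g["amplitude_uV"].to_numpy())
            rows.append(
                {
                    "participant": g["participant_id"].iloc[0],
                    "stimulus": g["stimulus"].iloc[0],
                }
            )
        data = np.asarray(data, dtype=float)
        tmin = float(frame["time_ms"].min())
        return cls(data, rate, tmin, pd.DataFrame(rows))

    @classmethod
    def read_tsv(cls, path, rate: float) -> "EpochSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"), rate)
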