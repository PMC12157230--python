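"""Signal conditioning: from raw multi-rate recordings to a 148 Hz channel grid.

Per-channel pipeline, in order:

1. outlier removal — samples beyond ±3 SD (single pass over unmasked values)
   are added to the missing mask;
2. gap filling — linear interpolation of interior gaps, nearest-value
   extension at the edges;
3. zero-phase band-pass filtering — 4th-order Butterworth applied
   forward-backward; gyroscope 0.25–30 Hz, accelerometer 1–20 Hz (both at
   148 Hz), EMG 20–500 Hz at its native 1259 Hz;
4. feature derivation — IMU: forward-difference jerk, then a 100 ms centred
   moving average; EMG: full-wave rectification, then the same 100 ms
   moving average (the envelope);
5. resampling — everything onto a common 148 Hz grid (polyphase for the
   EMG 1259 → 148 path, identity for IMU channels);
6. truncation of all channels to the common minimum frame count.

Jerk uses the forward difference (x(t+dt) − x(t))/dt with the final frame
replicated, so a recording keeps its length. The angular-jerk channel is
dω/dt by default; ``angular_jerk_order=2`` switches to the second
derivative of angular velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from gaitfatigue.recordings_io import RawRecording, SITES, FS_IMU, FS_EMG

TARGET_FS = 148.0

#: Axis labels for 3-axis blocks, in storage order.
AXES = ("x", "y", "z")


class AllMaskedError(ValueError):
    """Channel has no observed samples to work with."""


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification: zero-phase 4th-order Butterworth."""

    low_hz: float
    high_hz: float
    order: int = 4

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0.0 < self.low_hz < self.high_hz):
            raise ValueError(f"invalid band ({self.low_hz}, {self.high_hz})")
        if self.high_hz >= nyq:
            raise ValueError(
                f"band high edge {self.high_hz} Hz ≥ Nyquist {nyq} Hz at fs={fs}"
            )

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return signal.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass",
            fs=fs, output="sos",
        )


@dataclass
class PreprocessConfig:
    """Tunable knobs of the conditioning pipeline (defaults as used throughout)."""

    gyro_band: FilterSpec = field(default_factory=lambda: FilterSpec(0.25, 30.0))
    accel_band: FilterSpec = field(default_factory=lambda: FilterSpec(1.0, 20.0))
    emg_band: FilterSpec = field(default_factory=lambda: FilterSpec(20.0, 500.0))
    smoothing_window_ms: float = 100.0
    target_fs: float = TARGET_FS
    outlier_k: float = 3.0
    angular_jerk_order: int = 1  # dω/dt as printed; 2 = d²ω/dt²


@dataclass
class ProcessedRecording:
    """All channels of one subject-state on a common 148 Hz grid.

    ``data`` is (frames × channels); ``channel_names`` tags each column as
    ``<site>.<modality>.<axis>`` (jerk) or ``<site>.emg_env``.
    """

    subject_id: str
    state: str
    data: np.ndarray
    channel_names: list[str]
    fs: float = TARGET_FS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channel_names):
            raise ValueError("data must be (frames, channels) matching channel_names")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("processed data must be finite everywhere")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def remove_outliers(x: np.ndarray, mask: np.ndarray | None = None,
                    k: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Mask samples more than ``k`` standard deviations from the mean.

    Mean and SD are computed once over currently unmasked samples; values are
    untouched, only the mask grows. A constant channel (SD = 0) passes
    through unchanged.
    """
    x = np.asarray(x, dtype=float)
    mask = np.zeros_like(x, dtype=bool) if mask is None else mask.copy()
    obs = x[~mask]
    if obs.size == 0:
        raise AllMaskedError("cannot compute outlier statistics on all-masked input")
    if obs.size < 2:
        return x, mask
    mu, sd = obs.mean(), obs.std()
    if sd == 0.0:
        return x, mask
    mask |= np.abs(x - mu) > k * sd
    return x, mask


def interpolate_missing(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fill masked samples: linear interior interpolation, edge extension."""
    x = np.asarray(x, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise AllMaskedError("cannot interpolate a fully masked series")
    if not mask.any():
        return x.copy()
    idx = np.arange(x.size)
    good = ~mask
    # np.interp clamps outside the observed range → nearest-value extension
    return np.interp(idx, idx[good], x[good])


def bandpass(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Zero-phase band-pass (forward-backward Butterworth); length preserved."""
    sos = spec.sos(fs)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def rectify(emg: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(emg, dtype=float))


def smoothing_window_samples(window_ms: float, fs: float) -> int:
    """100 ms → samples; even counts are bumped to odd for a symmetric centre."""
    w = int(round(window_ms / 1000.0 * fs))
    if w % 2 == 0:
        w += 1
    return max(w, 1)


def moving_average(x: np.ndarray, window_ms: float, fs: float) -> np.ndarray:
    """Centred moving mean; the window shrinks at the edges (same length out)."""
    x = np.asarray(x, dtype=float)
    w = smoothing_window_samples(window_ms, fs)
    if w > x.shape[0]:
        raise ValueError(f"smoothing window ({w} samples) longer than series ({x.shape[0]})")
    kernel = np.ones(w)
    if x.ndim == 1:
        num = np.convolve(x, kernel, mode="same")
        den = np.convolve(np.ones(x.shape[0]), kernel, mode="same")
        return num / den
    den = np.convolve(np.ones(x.shape[0]), kernel, mode="same")
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = np.convolve(x[:, j], kernel, mode="same") / den
    return out


def _forward_difference(x: np.ndarray, fs: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 frames to differentiate")
    d = np.diff(x, axis=0) * fs
    return np.concatenate([d, d[-1:]], axis=0)  # replicate last to keep length


def linear_jerk(acc: np.ndarray, fs: float) -> np.ndarray:
    """Linear jerk (m/s³): forward difference of acceleration."""
    return _forward_difference(acc, fs)


def angular_jerk(gyro: np.ndarray, fs: float, order: int = 1) -> np.ndarray:
    """Angular jerk: dω/dt (``order=1``, as used throughout) or d²ω/dt²."""
    if order not in (1, 2):
        raise ValueError("angular_jerk order must be 1 or 2")
    out = _forward_difference(gyro, fs)
    if order == 2:
        out = _forward_difference(out, fs)
    return out


def resample_to_common(x: np.ndarray, fs_in: float, fs_out: float = TARGET_FS) -> np.ndarray:
    """Band-limited polyphase resampling; identity when rates match."""
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_in == fs_out:
        return np.asarray(x, dtype=float).copy()
    # express the ratio with integers (rates here are integral Hz)
    from math import gcd
    a, b = int(round(fs_out)), int(round(fs_in))
    g = gcd(a, b)
    return signal.resample_poly(np.asarray(x, dtype=float), a // g, b // g, axis=0)


def _condition(x: np.ndarray, mask: np.ndarray, band: FilterSpec, fs: float,
               k: float) -> np.ndarray:
    """Steps 1–3 shared by every channel: outliers → interpolation → band-pass."""
    if x.ndim == 1:
        _, m = remove_outliers(x, mask, k=k)
        return bandpass(interpolate_missing(x, m), band, fs)
    cols = []
    for j in range(x.shape[1]):
        _, m = remove_outliers(x[:, j], mask[:, j], k=k)
        cols.append(interpolate_missing(x[:, j], m))
    return bandpass(np.column_stack(cols), band, fs)


def channel_names_for_sites(sites=SITES) -> list[str]:
    names = []
    for site in sites:
        names += [f"{site}.linjerk.{ax}" for ax in AXES]
        names += [f"{site}.angjerk.{ax}" for ax in AXES]
        names.append(f"{site}.emg_env")
    return names


def preprocess_recording(group: dict[str, RawRecording],
                         config: PreprocessConfig | None = None) -> ProcessedRecording:
    """Condition a complete six-site group into one 148 Hz channel matrix.

    Per site the output carries 3 linear-jerk + 3 angular-jerk + 1 EMG
    envelope channel (42 channels total), truncated to the shortest channel
    so every column has the same frame count.
    """
    cfg = config or PreprocessConfig()
    missing = [s for s in SITES if s not in group]
    if missing:
        raise ValueError(f"incomplete site group; missing {missing}")
    ref = group[SITES[0]]
    subject_id, state = ref.subject_id, ref.state
    for s in SITES:
        rec = group[s]
        if (rec.subject_id, rec.state) != (subject_id, state):
            raise ValueError("group mixes subjects or states")
        rec.validate()

    columns: list[np.ndarray] = []
    for site in SITES:
        rec = group[site]
        fs = rec.fs_imu
        acc = _condition(rec.acc, rec.acc_mask, cfg.accel_band, fs, cfg.outlier_k)
        gyr = _condition(rec.gyro, rec.gyro_mask, cfg.gyro_band, fs, cfg.outlier_k)
        lj = moving_average(linear_jerk(acc, fs), cfg.smoothing_window_ms, fs)
        aj = moving_average(
            angular_jerk(gyr, fs, order=cfg.angular_jerk_order),
            cfg.smoothing_window_ms, fs,
        )
        lj = resample_to_common(lj, fs, cfg.target_fs)
        aj = resample_to_common(aj, fs, cfg.target_fs)

        # EMG is filtered and enveloped at its native 1259 Hz, then resampled
        emg = _condition(rec.emg, rec.emg_mask, cfg.emg_band, rec.fs_emg, cfg.outlier_k)
        env = moving_average(rectify(emg), cfg.smoothing_window_ms, rec.fs_emg)
        env = resample_to_common(env, rec.fs_emg, cfg.target_fs)

        columns += [lj[:, j] for j in range(3)]
        columns += [aj[:, j] for j in range(3)]
        columns.append(env)

    n = min(c.shape[0] for c in columns)
    data = np.column_stack([c[:n] for c in columns])
    return ProcessedRecording(
        subject_id=subject_id, state=state, data=data,
        channel_names=channel_names_for_sites(), fs=cfg.target_fs,
    )
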