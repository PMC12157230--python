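"""Seeded synthetic gait cohorts with controllable fatigue effects.

Each subject walks with a latent stride rate (~0.9 strides/s with
inter-subject jitter). Per sensor site the generator emits:

* accelerometer — a periodic stride waveform (fundamental + second
  harmonic) plus sharp Gaussian heel-strike transients (σ ≈ 20 ms) and
  white noise, at 148 Hz;
* gyroscope — phase-locked sinusoids plus attenuated heel-strike
  transients and noise, at 148 Hz;
* EMG — band-limited carrier noise (20–450 Hz at the native 1259 Hz)
  amplitude-modulated by a gait-phase-gated burst envelope over a small
  tonic floor.

Right-side sites run half a cycle out of phase with the left. The fatigued
recording of a subject shares all latent parameters with the non-fatigued
one and differs only through four effect multipliers, chosen so that the
effects survive per-segment z-scoring (which removes any whole-signal
amplitude change):

* ``jerk_gain`` scales the heel-strike transients (not the smooth stride
  waveform), raising transient-to-waveform contrast and hence jerk;
* ``emg_gain`` scales the burst envelope (not the tonic floor), raising
  burst-to-baseline contrast;
* ``asymmetry_gain`` additionally scales left-side EMG bursts, creating
  left–right asymmetry;
* ``cadence_factor`` slows the stride rate.

Setting every multiplier to 1 produces a null cohort in which the label is
independent of the signal. Subject streams are seeded independently, so
regenerating one subject never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

from gaitfatigue.recordings_io import (
    RawRecording, CohortManifest, ManifestEntry, write_manifest, write_recording,
    SITES, STATES, FS_IMU, FS_EMG,
)

_RIGHT_SITES = {"TAR", "GLR", "RFR"}
_LEFT_SITES = {"TAL", "GLL", "RFL"}

#: Gait-phase centre of the EMG burst per muscle (radians into the stride).
_MUSCLE_PHASE = {"TA": 0.3, "GL": 3.6, "RF": 1.2}

#: Relative heel-strike transient weight per accelerometer axis.
_IMPACT_AXIS_WEIGHTS = np.array([1.0, 0.6, 0.4])


@dataclass
class SimulationParams:
    """Cohort-level generator settings (study conditions, not tuning dials)."""

    n_subjects: int = 8
    duration_s: float = 16.0          # ≥ 15 s guarantees 9 windows at 148 Hz
    cadence_hz: float = 0.9           # baseline strides/s
    cadence_sd: float = 0.05          # inter-subject cadence jitter
    accel_base_amp: float = 2.0       # m/s², stride waveform
    heel_impulse_amp: float = 8.0     # m/s², transient peak
    heel_impulse_sigma_s: float = 0.02
    gyro_amp: float = 1.5             # rad/s
    emg_burst_amp: float = 0.8        # mV, burst envelope peak
    emg_tonic_amp: float = 0.1        # mV, tonic floor
    noise_sd_acc: float = 0.15        # m/s²
    noise_sd_gyro: float = 0.08       # rad/s
    jerk_gain: float = 1.3
    emg_gain: float = 1.25
    asymmetry_gain: float = 1.2       # applied to left-side EMG when fatigued
    cadence_factor: float = 0.92      # fatigued stride-rate multiplier
    dropout_frac: float = 0.0         # optional masked-sample fraction
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        for name in ("jerk_gain", "emg_gain", "asymmetry_gain", "cadence_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.duration_s * FS_IMU < 2220:
            raise ValueError(
                "duration too short: need ≥ 2220 frames at 148 Hz "
                "(≥ 15 s) for nine 3 s windows at 50 % overlap"
            )


def _subject_latents(params: SimulationParams, rng: np.random.Generator) -> dict:
    """Per-subject gait parameters shared between the two states."""
    return {
        "cadence_hz": float(np.clip(
            rng.normal(params.cadence_hz, params.cadence_sd), 0.6, 1.3)),
        "phase0": float(rng.uniform(0, 2 * np.pi)),
        # per-site amplitude idiosyncrasies (≈ ±10 %)
        "site_gain": {s: float(rng.normal(1.0, 0.1)) for s in SITES},
        "axis_phases": rng.uniform(0, 2 * np.pi, size=6).tolist(),
        "harmonic": float(rng.uniform(0.2, 0.4)),
    }


def _emg_carrier(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited noise carrier, 20–450 Hz at 1259 Hz."""
    sos = sps.butter(4, [20.0, 450.0], btype="bandpass", fs=FS_EMG, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / max(np.sqrt(np.mean(x ** 2)), 1e-12)


def _inject_dropout(x: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Mask short random runs covering ≈ frac of the samples."""
    mask = np.zeros(x.shape, dtype=bool)
    if frac <= 0:
        return mask
    flat = mask.reshape(-1)
    n_target = int(frac * flat.size)
    run = 5
    while flat.sum() < n_target:
        start = int(rng.integers(0, max(flat.size - run, 1)))
        flat[start:start + run] = True
    return mask


def simulate_recording(latents: dict, state: str, params: SimulationParams,
                       seed_seq: np.random.SeedSequence) -> dict[str, RawRecording]:
    """Generate the six-site recording group of one subject in one state."""
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    params.validate()
    fatigued = state == "fatigued"
    n_imu = int(round(params.duration_s * FS_IMU))
    n_emg = int(round(params.duration_s * FS_EMG))
    t_imu = np.arange(n_imu) / FS_IMU
    t_emg = np.arange(n_emg) / FS_EMG

    cadence = latents["cadence_hz"] * (params.cadence_factor if fatigued else 1.0)
    jerk_g = params.jerk_gain if fatigued else 1.0
    emg_g = params.emg_gain if fatigued else 1.0

    site_rngs = {
        s: np.random.default_rng(child)
        for s, child in zip(SITES, seed_seq.spawn(len(SITES)))
    }

    group: dict[str, RawRecording] = {}
    for site in SITES:
        rng = site_rngs[site]
        side_shift = np.pi if site in _RIGHT_SITES else 0.0
        phase = 2 * np.pi * cadence * t_imu + latents["phase0"] + side_shift
        gain = latents["site_gain"][site]

        # heel-strike times for this side: phase crossings of 2π
        first = (2 * np.pi - (latents["phase0"] + side_shift) % (2 * np.pi)) / (2 * np.pi * cadence)
        strikes = np.arange(first, params.duration_s, 1.0 / cadence)
        sigma = params.heel_impulse_sigma_s
        impulse = np.zeros(n_imu)
        for tk in strikes:
            lo = max(int((tk - 5 * sigma) * FS_IMU), 0)
            hi = min(int((tk + 5 * sigma) * FS_IMU) + 1, n_imu)
            impulse[lo:hi] += np.exp(-((t_imu[lo:hi] - tk) ** 2) / (2 * sigma ** 2))

        ph = latents["axis_phases"]
        harm = latents["harmonic"]
        acc = np.column_stack([
            gain * params.accel_base_amp
            * (np.sin(phase + ph[j]) + harm * np.sin(2 * phase + ph[j] / 2))
            + jerk_g * params.heel_impulse_amp * _IMPACT_AXIS_WEIGHTS[j] * impulse
            for j in range(3)
        ])
        acc += rng.normal(0.0, params.noise_sd_acc, size=acc.shape)

        gyro = np.column_stack([
            gain * params.gyro_amp
            * (np.sin(phase + ph[3 + j]) + harm * np.sin(2 * phase + ph[3 + j] / 2))
            + 0.3 * jerk_g * params.heel_impulse_amp * _IMPACT_AXIS_WEIGHTS[j] * impulse
            for j in range(3)
        ])
        gyro += rng.normal(0.0, params.noise_sd_gyro, size=gyro.shape)

        # EMG: gait-gated burst envelope over a tonic floor, times a
        # band-limited carrier
        muscle = site[:2]
        phase_emg = 2 * np.pi * cadence * t_emg + latents["phase0"] + side_shift
        burst = np.clip(np.cos(phase_emg - _MUSCLE_PHASE[muscle]), 0.0, None) ** 4
        burst_amp = gain * params.emg_burst_amp * emg_g
        if fatigued and site in _LEFT_SITES:
            burst_amp *= params.asymmetry_gain
        envelope = params.emg_tonic_amp + burst_amp * burst
        emg = envelope * _emg_carrier(n_emg, rng)

        acc_mask = _inject_dropout(acc, params.dropout_frac, rng)
        gyro_mask = _inject_dropout(gyro, params.dropout_frac, rng)
        emg_mask = _inject_dropout(emg, params.dropout_frac, rng)
        acc[acc_mask] = np.nan
        gyro[gyro_mask] = np.nan
        emg[emg_mask] = np.nan

        rec = RawRecording(
            subject_id=latents["subject_id"], state=state, site=site,
            acc=acc, gyro=gyro, emg=emg,
            acc_mask=acc_mask, gyro_mask=gyro_mask, emg_mask=emg_mask,
        )
        rec.validate()
        group[site] = rec
    return group


@dataclass
class SimulatedCohort:
    params: SimulationParams
    recordings: dict = field(default_factory=dict)  # (subject, state) → {site: RawRecording}
    manifest: CohortManifest | None = None

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.recordings})


def _subject_id(k: int) -> str:
    return f"S{k + 1:03d}"


def simulate_cohort(params: SimulationParams,
                    outdir: str | Path | None = None) -> SimulatedCohort:
    """Generate a full cohort; optionally persist it as CSV files + manifest.

    Deterministic given ``params.seed``; each subject's streams are seeded
    independently (``SeedSequence([seed, k, ...])``), so one subject's data
    never depends on another's.
    """
    params.validate()
    cohort = SimulatedCohort(params=params)
    entries: list[ManifestEntry] = []

    for k in range(params.n_subjects):
        sid = _subject_id(k)
        latents = _subject_latents(
            params, np.random.default_rng(np.random.SeedSequence([params.seed, k, 0]))
        )
        latents["subject_id"] = sid
        for si, state in enumerate(STATES):
            group = simulate_recording(
                latents, state, params, np.random.SeedSequence([params.seed, k, 1 + si])
            )
            cohort.recordings[(sid, state)] = group
            if outdir is not None:
                for site, rec in group.items():
                    imu_rel = f"{sid}_{state}_{site}_imu.csv"
                    emg_rel = f"{sid}_{state}_{site}_emg.csv"
                    write_recording(rec, Path(outdir) / imu_rel, Path(outdir) / emg_rel)
                    entries.append(ManifestEntry(sid, state, site, imu_rel, emg_rel))

    if outdir is not None:
        cohort.manifest = CohortManifest(entries=entries)
        write_manifest(cohort.manifest, Path(outdir) / "manifest.json")
    return cohort


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.nanmean(np.asarray(x, dtype=float) ** 2)))


def effect_report(cohort: SimulatedCohort) -> dict:
    """Realized fatigue effect sizes, per subject and cohort-averaged.

    Reports fatigued / non-fatigued ratios of raw linear-jerk RMS (forward
    difference of the generated accelerometer signal) and EMG RMS, plus the
    left–right EMG asymmetry index |L − R| / (L + R) per state. Because the
    EMG keeps a tonic floor that the gain does not scale, the realized EMG
    ratio sits slightly below the configured gain.
    """
    per_subject = {}
    for sid in cohort.subjects:
        row = {}
        jerk_rms, emg_rms, asym = {}, {}, {}
        for state in STATES:
            group = cohort.recordings[(sid, state)]
            jv = [
                _rms(np.diff(np.nan_to_num(group[s].acc, nan=0.0), axis=0) * FS_IMU)
                for s in SITES
            ]
            jerk_rms[state] = float(np.mean(jv))
            emg_rms[state] = float(np.mean([_rms(group[s].emg[~group[s].emg_mask])
                                            for s in SITES]))
            pair_idx = []
            for left, right in (("TAL", "TAR"), ("GLL", "GLR"), ("RFL", "RFR")):
                l = _rms(group[left].emg[~group[left].emg_mask])
                r = _rms(group[right].emg[~group[right].emg_mask])
                pair_idx.append(abs(l - r) / (l + r))
            asym[state] = float(np.mean(pair_idx))
        row["jerk_rms_ratio"] = jerk_rms["fatigued"] / jerk_rms["non_fatigued"]
        row["emg_rms_ratio"] = emg_rms["fatigued"] / emg_rms["non_fatigued"]
        row["asymmetry_non_fatigued"] = asym["non_fatigued"]
        row["asymmetry_fatigued"] = asym["fatigued"]
        per_subject[sid] = row

    keys = next(iter(per_subject.values())).keys()
    summary = {k: float(np.mean([v[k] for v in per_subject.values()])) for k in keys}
    return {
        "per_subject": per_subject,
        "mean": summary,
        "configured": {
            "jerk_gain": cohort.params.jerk_gain,
            "emg_gain": cohort.params.emg_gain,
            "asymmetry_gain": cohort.params.asymmetry_gain,
            "cadence_factor": cohort.params.cadence_factor,
        },
    }


def params_to_dict(params: SimulationParams) -> dict:
    return asdict(params)
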