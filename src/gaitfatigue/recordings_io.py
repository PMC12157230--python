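"""Reading and writing multi-rate sensor recordings and cohort manifests.

One walking trial of one subject in one fatigue state produces, per sensor
site, a 6-channel IMU block (3-axis accelerometer in m/s², 3-axis gyroscope
in rad/s, both at 148 Hz) and a single surface-EMG channel (mV, 1259 Hz).
Each (subject, state, site, modality) lives in its own comma-delimited text
file with a header row and a time column in seconds; missing samples are
empty cells and are carried in memory as a boolean mask rather than sentinel
values, so downstream interpolation sees explicit missingness.

A cohort manifest (JSON) enumerates the files; a (subject, state) pair is
usable only when all six sites are present.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Sensor sites: tibialis anterior, gastrocnemius lateralis, rectus femoris,
#: each left (L) and right (R).
SITES = ("TAL", "TAR", "GLL", "GLR", "RFL", "RFR")

#: Binary fatigue states.
STATES = ("non_fatigued", "fatigued")

#: Native sampling rates of the wireless sensors.
FS_IMU = 148.0
FS_EMG = 1259.0

IMU_COLUMNS = ["time", "ax", "ay", "az", "gx", "gy", "gz"]
EMG_COLUMNS = ["time", "emg"]


class FormatError(ValueError):
    """Malformed recording file (wrong header / column count)."""


class RateError(ValueError):
    """Sample rate implied by the file disagrees with the manifest."""


class ManifestError(ValueError):
    """Structurally invalid cohort manifest."""


@dataclass
class RawRecording:
    """One subject × state × site multi-rate sensor block.

    Masks are boolean arrays the same length as their channel, ``True``
    where the sample is missing.
    """

    subject_id: str
    state: str
    site: str
    acc: np.ndarray          # (n, 3) m/s² at 148 Hz
    gyro: np.ndarray         # (n, 3) rad/s at 148 Hz
    emg: np.ndarray          # (m,)  mV at 1259 Hz
    acc_mask: np.ndarray = None
    gyro_mask: np.ndarray = None
    emg_mask: np.ndarray = None
    fs_imu: float = FS_IMU
    fs_emg: float = FS_EMG

    def __post_init__(self):
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float).reshape(-1)
        if self.acc_mask is None:
            self.acc_mask = ~np.isfinite(self.acc)
        if self.gyro_mask is None:
            self.gyro_mask = ~np.isfinite(self.gyro)
        if self.emg_mask is None:
            self.emg_mask = ~np.isfinite(self.emg)
        self.acc_mask = np.asarray(self.acc_mask, dtype=bool)
        self.gyro_mask = np.asarray(self.gyro_mask, dtype=bool)
        self.emg_mask = np.asarray(self.emg_mask, dtype=bool)

    def validate(self) -> None:
        """Enforce the data-model invariants; raise ``ValueError`` on breach."""
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise FormatError("acc must be (n, 3)")
        if self.gyro.shape != self.acc.shape:
            raise ValueError("acc and gyro must have equal sample counts")
        expected_emg = self.acc.shape[0] * self.fs_emg / self.fs_imu
        if abs(self.emg.shape[0] - expected_emg) > 1.0 + 1e-9:
            raise RateError(
                f"EMG length {self.emg.shape[0]} inconsistent with IMU length "
                f"{self.acc.shape[0]} (expected ≈{expected_emg:.1f} ±1)"
            )
        for arr, mask, name in (
            (self.acc, self.acc_mask, "acc"),
            (self.gyro, self.gyro_mask, "gyro"),
            (self.emg, self.emg_mask, "emg"),
        ):
            if mask.shape != arr.shape:
                raise ValueError(f"{name} mask shape mismatch")
            if not np.all(np.isfinite(arr[~mask])):
                raise ValueError(f"non-finite {name} value outside the missing mask")

    @property
    def n_imu(self) -> int:
        return self.acc.shape[0]


@dataclass
class ManifestEntry:
    subject_id: str
    state: str
    site: str
    imu_path: str
    emg_path: str


@dataclass
class CohortManifest:
    """Validated file inventory of a cohort.

    Only (subject, state) pairs with all six sites survive validation;
    incomplete pairs are reported via :func:`warnings.warn` and dropped.
    """

    entries: list[ManifestEntry] = field(default_factory=list)
    fs_imu: float = FS_IMU
    fs_emg: float = FS_EMG

    @property
    def subjects(self) -> list[str]:
        return sorted({e.subject_id for e in self.entries})

    def groups(self) -> dict[tuple[str, str], dict[str, ManifestEntry]]:
        """Map (subject, state) → {site: entry} for complete groups."""
        out: dict[tuple[str, str], dict[str, ManifestEntry]] = {}
        for e in self.entries:
            out.setdefault((e.subject_id, e.state), {})[e.site] = e
        return out

    def n_complete_groups(self) -> int:
        return len(self.groups())


def _validate_entries(raw_entries: list[ManifestEntry]) -> list[ManifestEntry]:
    seen = set()
    for e in raw_entries:
        key = (e.subject_id, e.state, e.site)
        if key in seen:
            raise ManifestError(f"duplicate (subject, state, site) triple {key}")
        if e.state not in STATES:
            raise ManifestError(f"unknown state {e.state!r} in manifest")
        if e.site not in SITES:
            raise ManifestError(f"unknown site {e.site!r} in manifest")
        seen.add(key)
    by_group: dict[tuple[str, str], set[str]] = {}
    for e in raw_entries:
        by_group.setdefault((e.subject_id, e.state), set()).add(e.site)
    complete = {g for g, sites in by_group.items() if sites == set(SITES)}
    for g, sites in sorted(by_group.items()):
        if g not in complete:
            missing = sorted(set(SITES) - sites)
            warnings.warn(
                f"(subject={g[0]}, state={g[1]}) missing sites {missing}; excluded",
                stacklevel=3,
            )
    return [e for e in raw_entries if (e.subject_id, e.state) in complete]


def read_manifest(path: str | Path) -> CohortManifest:
    """Read and validate a JSON cohort manifest.

    Raises :class:`ManifestError` for empty/duplicate/ill-formed manifests;
    incomplete (subject, state) site groups are warned about and excluded.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ManifestError(f"empty manifest file {path}")
    doc = json.loads(text)
    if not isinstance(doc, dict) or "entries" not in doc or not doc["entries"]:
        raise ManifestError("manifest must contain a non-empty 'entries' list")
    raw = [
        ManifestEntry(
            subject_id=str(d["subject_id"]),
            state=str(d["state"]),
            site=str(d["site"]),
            imu_path=str(d["imu_path"]),
            emg_path=str(d["emg_path"]),
        )
        for d in doc["entries"]
    ]
    entries = _validate_entries(raw)
    return CohortManifest(
        entries=entries,
        fs_imu=float(doc.get("fs_imu", FS_IMU)),
        fs_emg=float(doc.get("fs_emg", FS_EMG)),
    )


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "fs_imu": manifest.fs_imu,
        "fs_emg": manifest.fs_emg,
        "entries": [
            {
                "subject_id": e.subject_id,
                "state": e.state,
                "site": e.site,
                "imu_path": e.imu_path,
                "emg_path": e.emg_path,
            }
            for e in manifest.entries
        ],
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


def _read_table(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != columns:
        raise FormatError(
            f"{path}: expected columns {columns}, found {list(df.columns)}"
        )
    return df


def read_recording(entry: ManifestEntry, base_dir: str | Path = ".",
                   fs_imu: float = FS_IMU, fs_emg: float = FS_EMG) -> RawRecording:
    """Read one (subject, state, site) recording from its IMU + EMG CSV pair.

    Empty cells become masked samples (value NaN, mask True). The time
    column's median step is checked against the declared rate (±1 %).
    """
    base = Path(base_dir)
    imu = _read_table(base / entry.imu_path, IMU_COLUMNS)
    emg = _read_table(base / entry.emg_path, EMG_COLUMNS)

    for df, fs, which in ((imu, fs_imu, "IMU"), (emg, fs_emg, "EMG")):
        t = df["time"].to_numpy(dtype=float)
        if len(t) >= 2:
            dt = np.median(np.diff(t))
            if not np.isclose(dt, 1.0 / fs, rtol=0.01):
                raise RateError(
                    f"{which} time step {dt:.6g}s inconsistent with {fs} Hz"
                )

    acc = imu[["ax", "ay", "az"]].to_numpy(dtype=float)
    gyro = imu[["gx", "gy", "gz"]].to_numpy(dtype=float)
    emg_x = emg["emg"].to_numpy(dtype=float)
    rec = RawRecording(
        subject_id=entry.subject_id, state=entry.state, site=entry.site,
        acc=acc, gyro=gyro, emg=emg_x, fs_imu=fs_imu, fs_emg=fs_emg,
    )
    rec.validate()
    return rec


def write_recording(rec: RawRecording, imu_path: str | Path,
                    emg_path: str | Path) -> tuple[Path, Path]:
    """Persist one recording as an IMU CSV + EMG CSV pair.

    Masked samples are written as empty cells; a NaN outside the mask is an
    invariant breach and is refused. Round-tripping is lossless for finite
    values and masks.
    """
    rec.validate()  # refuses NaN outside mask
    imu_path, emg_path = Path(imu_path), Path(emg_path)

    n = rec.n_imu
    t_imu = np.arange(n) / rec.fs_imu
    imu = pd.DataFrame({"time": t_imu})
    for j, col in enumerate(("ax", "ay", "az")):
        v = rec.acc[:, j].copy()
        v[rec.acc_mask[:, j]] = np.nan
        imu[col] = v
    for j, col in enumerate(("gx", "gy", "gz")):
        v = rec.gyro[:, j].copy()
        v[rec.gyro_mask[:, j]] = np.nan
        imu[col] = v

    m = rec.emg.shape[0]
    v = rec.emg.copy()
    v[rec.emg_mask] = np.nan
    emg = pd.DataFrame({"time": np.arange(m) / rec.fs_emg, "emg": v})

    imu_path.parent.mkdir(parents=True, exist_ok=True)
    emg_path.parent.mkdir(parents=True, exist_ok=True)
    # 17 significant digits round-trips float64 exactly
    imu.to_csv(imu_path, index=False, float_format="%.17g")
    emg.to_csv(emg_path, index=False, float_format="%.17g")
    return imu_path, emg_path
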