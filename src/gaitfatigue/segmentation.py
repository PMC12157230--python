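"""Fixed-window segmentation and per-segment normalization.

Processed recordings are cut into 3 s windows (444 frames at 148 Hz) with
50 % overlap (hop 222 frames); each window is z-scored per channel so that
a segment carries only shape information, never a subject's amplitude
offset — a prerequisite for honest subject-independent evaluation. Nine
windows per recording (the first nine) form the standard dataset: a cohort
of 35 subjects × 2 states × 9 windows yields the canonical
630 × 444 × C array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gaitfatigue.preprocess import ProcessedRecording
from gaitfatigue.recordings_io import STATES

#: 3 s at 148 Hz: round(3 × 148) frames.
WINDOW_FRAMES = 444
#: 50 % overlap → hop of half a window.
HOP_FRAMES = 222

#: Binary label encoding: fatigued is the positive class.
LABELS = {"non_fatigued": 0, "fatigued": 1}


@dataclass
class SegmentSet:
    """Model-ready dataset: (segments × frames × channels) plus bookkeeping."""

    data: np.ndarray
    labels: np.ndarray       # 0 = non-fatigued, 1 = fatigued
    subject_ids: np.ndarray  # per-segment subject identifier (str)
    window_ids: np.ndarray   # window index within the (subject, state) recording
    channel_names: list[str]
    window_frames: int = WINDOW_FRAMES
    hop_frames: int = HOP_FRAMES

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        self.window_ids = np.asarray(self.window_ids, dtype=int)
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.subject_ids) == len(self.window_ids) == n):
            raise ValueError("per-segment arrays must align with data")
        if self.data.ndim != 3 or self.data.shape[2] != len(self.channel_names):
            raise ValueError("data must be (segments, frames, channels)")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    @property
    def subjects(self) -> list[str]:
        return sorted(set(self.subject_ids.tolist()))


def window_count(n_frames: int, window: int = WINDOW_FRAMES, hop: int = HOP_FRAMES) -> int:
    """Number of full windows: floor((L − W)/H) + 1 (0 if L < W)."""
    if n_frames < window:
        return 0
    return (n_frames - window) // hop + 1


def segment_windows(rec: ProcessedRecording, window_s: float = 3.0,
                    overlap: float = 0.5, max_windows: int | None = 9) -> list[np.ndarray]:
    """Cut one recording into overlapping fixed windows (tail discarded).

    Windows start at multiples of ``hop = window × (1 − overlap)``; when
    ``max_windows`` is set only the first that many are kept.
    """
    window = int(round(window_s * rec.fs))
    hop = int(round(window * (1.0 - overlap)))
    n = window_count(rec.n_frames, window, hop)
    if n == 0:
        raise ValueError(
            f"recording of {rec.n_frames} frames shorter than one {window}-frame window"
        )
    if max_windows is not None:
        n = min(n, max_windows)
    return [rec.data[i * hop: i * hop + window] for i in range(n)]


def zscore_segment(seg: np.ndarray) -> np.ndarray:
    """Per-channel z-score within the segment; zero-variance channels → 0."""
    seg = np.asarray(seg, dtype=float)
    mu = seg.mean(axis=0, keepdims=True)
    sd = seg.std(axis=0, keepdims=True)
    out = np.zeros_like(seg)
    nz = sd[0] > 0
    out[:, nz] = (seg[:, nz] - mu[:, nz]) / sd[:, nz]
    return out


def assemble_dataset(recordings: list[ProcessedRecording],
                     windows_per_recording: int = 9,
                     drop_short: bool = False) -> SegmentSet:
    """Build the labelled segment array from a cohort of processed recordings.

    Every subject must contribute both states; segments are ordered by
    (subject, state, window index), so reassembly is reproducible. Subjects
    whose recordings are too short abort assembly unless ``drop_short``.
    """
    by_subject: dict[str, dict[str, ProcessedRecording]] = {}
    for rec in recordings:
        slot = by_subject.setdefault(rec.subject_id, {})
        if rec.state in slot:
            raise ValueError(f"duplicate recording for ({rec.subject_id}, {rec.state})")
        slot[rec.state] = rec

    usable: list[str] = []
    problems: list[str] = []
    for subj in sorted(by_subject):
        states = by_subject[subj]
        if set(states) != set(STATES):
            raise ValueError(f"subject {subj} lacks one of the two states")
        short = [
            st for st in STATES
            if window_count(states[st].n_frames) < windows_per_recording
        ]
        if short:
            problems.append(f"{subj} ({', '.join(short)})")
        else:
            usable.append(subj)
    if problems:
        if not drop_short:
            raise ValueError(
                "recordings too short for "
                f"{windows_per_recording} windows: {'; '.join(problems)}"
            )
    if not usable:
        raise ValueError("no usable subjects after length screening")

    channel_names = by_subject[usable[0]][STATES[0]].channel_names
    segs, labels, subjects, win_ids = [], [], [], []
    for subj in usable:
        for state in STATES:
            rec = by_subject[subj][state]
            if rec.channel_names != channel_names:
                raise ValueError("inconsistent channel layout across recordings")
            for w, seg in enumerate(segment_windows(rec, max_windows=windows_per_recording)):
                segs.append(zscore_segment(seg))
                labels.append(LABELS[state])
                subjects.append(subj)
                win_ids.append(w)

    return SegmentSet(
        data=np.stack(segs), labels=np.array(labels),
        subject_ids=np.array(subjects), window_ids=np.array(win_ids),
        channel_names=list(channel_names),
    )
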