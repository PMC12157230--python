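"""The 14 sensor/signal combinations evaluated by the pipeline.

Each combination is an ordered recipe of (site, modality) blocks: an EMG
envelope contributes one channel, a linear- or angular-jerk block three
(x, y, z). EMG blocks are listed before jerk blocks within a combination.
The registry spans single-site EMG (1 feature) through the comprehensive
bilateral setup (20 features).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from gaitfatigue.preprocess import AXES
from gaitfatigue.segmentation import SegmentSet

#: Channels contributed by each modality block.
_BLOCK_WIDTH = {"emg_env": 1, "linjerk": 3, "angjerk": 3}


@dataclass(frozen=True)
class CombinationSpec:
    """One registry row: ordered (site, modality) blocks and their category."""

    id: int
    category: str
    blocks: tuple[tuple[str, str], ...]  # ((site, modality), ...)

    @property
    def n_features(self) -> int:
        return sum(_BLOCK_WIDTH[m] for _, m in self.blocks)

    @property
    def channels(self) -> list[str]:
        """Expanded channel names in selection order."""
        out = []
        for site, mod in self.blocks:
            if mod == "emg_env":
                out.append(f"{site}.emg_env")
            else:
                out += [f"{site}.{mod}.{ax}" for ax in AXES]
        return out

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "category": self.category,
            "blocks": [list(b) for b in self.blocks],
            "n_features": self.n_features,
            "channels": self.channels,
        }


def _c(id_, category, *blocks):
    return CombinationSpec(id=id_, category=category, blocks=tuple(blocks))


_GL_EMG = "bilateral/unilateral GL EMG"
_TA = "TA jerk"
_RF = "RF jerk"
_HYBRID = "single-leg hybrid"
_ALL = "comprehensive"

REGISTRY: dict[int, CombinationSpec] = {
    1: _c(1, _GL_EMG, ("GLL", "emg_env")),
    2: _c(2, _GL_EMG, ("GLR", "emg_env")),
    3: _c(3, _GL_EMG, ("GLL", "emg_env"), ("GLR", "emg_env")),
    4: _c(4, _TA, ("TAL", "linjerk"), ("TAR", "linjerk")),
    5: _c(5, _TA, ("TAL", "angjerk"), ("TAR", "angjerk")),
    6: _c(6, _TA, ("TAL", "linjerk"), ("TAL", "angjerk"),
          ("TAR", "linjerk"), ("TAR", "angjerk")),
    7: _c(7, _RF, ("RFL", "linjerk"), ("RFR", "linjerk")),
    8: _c(8, _RF, ("RFL", "angjerk"), ("RFR", "angjerk")),
    9: _c(9, _RF, ("RFL", "linjerk"), ("RFL", "angjerk"),
          ("RFR", "linjerk"), ("RFR", "angjerk")),
    10: _c(10, _HYBRID, ("GLL", "emg_env"), ("TAL", "linjerk"), ("TAL", "angjerk")),
    11: _c(11, _HYBRID, ("GLL", "emg_env"), ("RFL", "linjerk")),
    12: _c(12, _HYBRID, ("TAL", "linjerk"), ("TAL", "angjerk"), ("RFL", "linjerk")),
    13: _c(13, _HYBRID, ("GLL", "emg_env"), ("TAL", "linjerk"),
           ("TAL", "angjerk"), ("RFL", "linjerk")),
    14: _c(14, _ALL, ("GLL", "emg_env"), ("GLR", "emg_env"),
           ("TAL", "linjerk"), ("TAL", "angjerk"),
           ("TAR", "linjerk"), ("TAR", "angjerk"),
           ("RFL", "linjerk"), ("RFR", "linjerk")),
}


def get_combination(id_: int) -> CombinationSpec:
    """Look up a registry row by id (1–14)."""
    try:
        return REGISTRY[int(id_)]
    except (KeyError, ValueError, TypeError):
        raise KeyError(f"unknown combination id {id_!r}; valid ids are 1–14") from None


def select_channels(segments: SegmentSet, spec: CombinationSpec) -> SegmentSet:
    """Restrict a segment set to the channels of one combination.

    Selection happens after per-segment z-scoring, so the selected values
    equal the corresponding slice of the full set. Labels, subjects and
    segment order are untouched.
    """
    wanted = spec.channels
    missing = [c for c in wanted if c not in segments.channel_names]
    if missing:
        raise KeyError(f"combination {spec.id} needs absent channel(s): {missing}")
    idx = [segments.channel_names.index(c) for c in wanted]
    return SegmentSet(
        data=segments.data[:, :, idx],
        labels=segments.labels.copy(),
        subject_ids=segments.subject_ids.copy(),
        window_ids=segments.window_ids.copy(),
        channel_names=wanted,
        window_frames=segments.window_frames,
        hop_frames=segments.hop_frames,
    )


def registry_json() -> str:
    """The full registry as JSON (for CLI dumping / provenance)."""
    return json.dumps([REGISTRY[i].to_dict() for i in sorted(REGISTRY)], indent=1)
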