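"""Optode montage, symmetric-pair bookkeeping and session event timelines.

The montage is purely a labeling structure: channels are ordered
(emitter, detector) label pairs, each assigned to a hemisphere, with
homotopic (mirror-symmetric) channels recorded as left/right pairs.  No 3-D
head geometry is modeled.  Event schedules tile the block/trial structure of
a motor-imagery BCI session: alternating rest and motor-imagery phases, each
opened by a short preparation interval and a visual cue.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

HEMIS = ("left", "right")

#: phase labels understood by the design-matrix builder
PHASE_LABELS = ("rest", "prep_rest", "prep_task", "mi_left", "mi_right")

# Per-protocol timing, seconds.  Clinical: 2 s preparation + 15 s execution
# inside each 17 s half-trial; healthy: 3 s + 20 s.
PROTOCOLS = {
    "clinical": {"prep": 2.0, "task": 15.0, "fs": 15.6, "default_blocks": 4},
    "healthy": {"prep": 3.0, "task": 20.0, "fs": 3.9, "default_blocks": 3},
}


@dataclass(frozen=True)
class Phase:
    onset: float
    duration: float
    label: str


@dataclass
class EventSchedule:
    """Timed experiment phases for one recording session."""

    phases: list[Phase]
    cue_onsets: list[tuple[float, str]]
    fs: float
    session_id: int = 0
    day_index: int = 1
    protocol: str = "clinical"

    @property
    def duration(self) -> float:
        if not self.phases:
            return 0.0
        last = self.phases[-1]
        return last.onset + last.duration

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.onset, p.duration, p.label) for p in self.phases],
            columns=["onset", "duration", "label"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class Montage:
    """Channel labels, hemisphere assignment and homotopic pairs."""

    name: str
    channels: list[str]
    hemisphere_of_channel: dict[str, str]
    symmetric_pairs: list[tuple[str, str]]
    positions: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for lch, rch in self.symmetric_pairs:
            for ch in (lch, rch):
                if ch not in self.channels:
                    raise ValueError(f"pair member {ch!r} not a montage channel")
                if ch in seen:
                    raise ValueError(f"channel {ch!r} appears in more than one pair")
                seen.add(ch)
            if self.hemisphere_of_channel[lch] != "left" or self.hemisphere_of_channel[rch] != "right":
                raise ValueError(f"pair ({lch}, {rch}) must be (left, right) channels")
        for ch in self.channels:
            if self.hemisphere_of_channel.get(ch) not in HEMIS:
                raise ValueError(f"channel {ch!r} lacks a hemisphere label")

    @property
    def paired_channels(self) -> list[str]:
        out = []
        for lch, rch in self.symmetric_pairs:
            out.extend([lch, rch])
        return out

    def partner(self, channel: str) -> str | None:
        for lch, rch in self.symmetric_pairs:
            if channel == lch:
                return rch
            if channel == rch:
                return lch
        return None


@dataclass
class SubjectMeta:
    subject_id: str
    group: str  # "patient" | "healthy"
    lesion_side: str  # "left" | "right" | "none"
    handedness: str = "right"
    sessions: list[tuple[int, int]] = field(default_factory=list)  # (session_id, day)
    baseline_arat: float | None = None
    outcome_arat: float | None = None

    def __post_init__(self) -> None:
        if (self.lesion_side == "none") != (self.group == "healthy"):
            raise ValueError("lesion_side is 'none' iff group is 'healthy'")
        days = [d for _, d in self.sessions]
        if any(b < a for a, b in zip(days, days[1:])):
            raise ValueError("day_index must be non-decreasing over sessions")

    @property
    def relative_improvement(self) -> float | None:
        """Post-therapy ARAT improvement relative to baseline, percent."""
        if self.baseline_arat in (None, 0) or self.outcome_arat is None:
            return None
        return 100.0 * (self.outcome_arat - self.baseline_arat) / self.baseline_arat

    @property
    def affected_hand(self) -> str | None:
        """Hand contralateral to the lesioned hemisphere."""
        if self.lesion_side == "none":
            return None
        return "right" if self.lesion_side == "left" else "left"


def build_schedule(
    protocol: str,
    n_blocks: int | None = None,
    seed: int = 0,
    fs: float | None = None,
    session_id: int = 0,
    day_index: int = 1,
) -> EventSchedule:
    """Build one session's event timeline.

    Each block holds 4 trials, 2 per hand, in a seed-determined random
    order.  A trial is a rest phase followed by a motor-imagery phase; each
    phase opens with a preparation interval, and a visual cue is emitted at
    the start of every non-preparatory instruction.  Phases tile
    back-to-back with no inter-trial gap, so a clinical trial spans exactly
    (2+15) + (2+15) = 34 s.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    spec = PROTOCOLS[protocol]
    if n_blocks is None:
        n_blocks = spec["default_blocks"]
    if n_blocks <= 0:
        raise ValueError("n_blocks must be positive")
    standard = {"clinical": (4, 6), "healthy": (3,)}[protocol]
    if n_blocks not in standard:
        warnings.warn(f"{n_blocks} blocks is non-standard for the {protocol} protocol")
    fs = spec["fs"] if fs is None else float(fs)
    if fs <= 0:
        raise ValueError("fs must be positive")
    prep, task = spec["prep"], spec["task"]

    rng = np.random.default_rng(seed)
    phases: list[Phase] = []
    cues: list[tuple[float, str]] = []

    def snap(t: float) -> float:
        # onsets rounded to the nearest sample of the recording
        return round(t * fs) / fs

    t = 0.0
    for _ in range(n_blocks):
        hands = ["mi_left", "mi_left", "mi_right", "mi_right"]
        rng.shuffle(hands)
        for mi in hands:
            phases.append(Phase(snap(t), prep, "prep_rest"))
            t += prep
            cues.append((snap(t), "rest"))
            phases.append(Phase(snap(t), task, "rest"))
            t += task
            phases.append(Phase(snap(t), prep, "prep_task"))
            t += prep
            cues.append((snap(t), mi))
            phases.append(Phase(snap(t), task, mi))
            t += task
    return EventSchedule(
        phases=phases, cue_onsets=cues, fs=fs,
        session_id=session_id, day_index=day_index, protocol=protocol,
    )


def mirror_responses(
    responses: pd.DataFrame,
    meta: SubjectMeta,
    montage: Montage,
) -> pd.DataFrame:
    """Mirror homotopic channels for right-lesioned subjects.

    After mirroring, left-side channel labels always denote the lesioned
    hemisphere across the patient cohort, and the task axis is re-expressed
    as {mi_affected, mi_intact} from the lesion side.  Healthy subjects pass
    through unchanged.  Applying the channel swap twice restores the input.

    ``responses`` is a tidy frame with at least columns
    ``channel, task, chromophore, coefficient``.
    """
    out = responses.copy()
    if meta.group == "healthy" or meta.lesion_side == "none":
        return out

    swap: dict[str, str] = {}
    for lch, rch in montage.symmetric_pairs:
        swap[lch] = rch
        swap[rch] = lch
    if meta.lesion_side == "right":
        unpaired = set(out["channel"]) - set(swap)
        if unpaired:
            warnings.warn(
                f"unpaired channels dropped from paired analyses: {sorted(unpaired)}"
            )
            out = out[~out["channel"].isin(unpaired)].copy()
        out["channel"] = out["channel"].map(swap)

    affected = "mi_" + meta.affected_hand
    task_map = {}
    for task in out["task"].unique():
        if task in ("mi_left", "mi_right"):
            task_map[task] = "mi_affected" if task == affected else "mi_intact"
        else:
            task_map[task] = task  # already relabeled, or a non-MI regressor
    out["task"] = out["task"].map(task_map)
    return out


def _load_yaml_config(name: str) -> dict:
    pkg_files = importlib.resources.files("nirsasym") / "configs"
    path = pkg_files / f"{name}.yaml"
    if path.is_file():
        return yaml.safe_load(path.read_text())
    with open(name) as fh:  # treat as a filesystem path
        return yaml.safe_load(fh)


def load_montage(name: str = "clinical28") -> Montage:
    """Load a bundled montage config ("clinical28", "healthy33") or a YAML path."""
    cfg = _load_yaml_config(name)
    channels = [str(c) for c in cfg["channels"]]
    hemis = {str(k): str(v) for k, v in cfg["hemispheres"].items()}
    pairs = [(str(a), str(b)) for a, b in cfg["symmetric_pairs"]]
    positions = None
    if cfg.get("positions"):
        positions = {str(k): (float(v[0]), float(v[1])) for k, v in cfg["positions"].items()}
    return Montage(
        name=str(cfg.get("name", name)),
        channels=channels,
        hemisphere_of_channel=hemis,
        symmetric_pairs=pairs,
        positions=positions,
    )
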