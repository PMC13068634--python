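"""Single-cell morphospace trajectories and state-transition (plasticity) counts.

Tracked cells are followed through (area, irregularity) space over time.  Each
trajectory carries per-step deltas and sample variances of area and
irregularity, and — once classified against a frozen gating model — a condensed
state sequence mapping the cell-level classes onto the senescent morphotypes:

    cLI -> E (enlarged, extension-rich, irregular)
    cLR -> F (enlarged, flattened, regular)
    cN  -> N (normal)
    everything else -> other

Adjacent-frame state changes are tallied into a :class:`TransitionSummary`
(self-transitions excluded), the cohort-level readout of senescent phenotype
plasticity: in the study system E->F transitions dominate, with rare F->E
reversions.

Track identity is taken from provided track IDs (tracking in the source study
was manual).  An optional greedy mutual-nearest-centroid linker is provided for
mask time series, but ID-based linking is the supported path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import AmbiguousTrackError, InputError
from .gating import ClassLabel, GatingModel, classify_frame
from .morphometry import MorphoRecord, records_to_frame

__all__ = [
    "Trajectory",
    "TransitionSummary",
    "CONDENSED_MAP",
    "build_trajectories",
    "trajectory_stats",
    "state_sequence",
    "count_transitions",
    "link_by_centroid",
]

logger = logging.getLogger(__name__)

CONDENSED_MAP = {
    ClassLabel.LI.value: "E",
    ClassLabel.LR.value: "F",
    ClassLabel.N.value: "N",
}
CONDENSED_STATES = ("N", "E", "F", "other")


def condense_class(label: str) -> str:
    return CONDENSED_MAP.get(label, "other")


@dataclass
class Trajectory:
    """Time-ordered measurements of one tracked cell."""

    track_id: str
    frame: pd.DataFrame  # rows sorted by timepoint
    class_sequence: Optional[list[str]] = None
    condensed_sequence: Optional[list[str]] = None

    @property
    def n_frames(self) -> int:
        return len(self.frame)

    @property
    def timepoints(self) -> np.ndarray:
        return self.frame["timepoint"].to_numpy(dtype=float)

    @property
    def areas(self) -> np.ndarray:
        return self.frame["area"].to_numpy(dtype=float)

    @property
    def irregularities(self) -> np.ndarray:
        return self.frame["irregularity"].to_numpy(dtype=float)

    @property
    def deltas(self) -> pd.DataFrame:
        return pd.DataFrame({
            "delta_area": np.diff(self.areas),
            "delta_irregularity": np.diff(self.irregularities),
        })

    @property
    def var_area(self) -> float:
        return float(np.var(self.areas, ddof=1))

    @property
    def var_irregularity(self) -> float:
        return float(np.var(self.irregularities, ddof=1))

    @property
    def start_class(self) -> Optional[str]:
        return self.class_sequence[0] if self.class_sequence else None

    @property
    def end_class(self) -> Optional[str]:
        return self.class_sequence[-1] if self.class_sequence else None


@dataclass
class TransitionSummary:
    """Tally of adjacent-frame condensed-state changes across a cohort."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    n_trajectories: int = 0
    start_end: dict[tuple[str, str], int] = field(default_factory=dict)
    exposures: dict[str, int] = field(default_factory=dict)  # frames at risk per state

    @property
    def n_E_to_F(self) -> int:
        return self.counts.get(("E", "F"), 0)

    @property
    def n_F_to_E(self) -> int:
        return self.counts.get(("F", "E"), 0)

    @property
    def total_transitions(self) -> int:
        return sum(self.counts.values())

    def frequency(self, src: str, dst: str) -> float:
        """Empirical per-frame transition probability src -> dst."""
        at_risk = self.exposures.get(src, 0)
        if at_risk == 0:
            return float("nan")
        return self.counts.get((src, dst), 0) / at_risk

    def to_dict(self) -> dict:
        return {
            "counts": {f"{a}->{b}": v for (a, b), v in sorted(self.counts.items())},
            "n_trajectories": self.n_trajectories,
            "n_E_to_F": self.n_E_to_F,
            "n_F_to_E": self.n_F_to_E,
            "start_end": {f"{a}->{b}": v for (a, b), v in sorted(self.start_end.items())},
            "exposures": dict(sorted(self.exposures.items())),
        }


def build_trajectories(
    records: Union[Sequence[MorphoRecord], pd.DataFrame],
) -> list[Trajectory]:
    """Group records by track ID into time-sorted trajectories.

    Tracks with timepoint gaps are retained (the gap is logged); a duplicate
    (track_id, timepoint) pair is ambiguous and raises.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(list(records))
    if "track_id" not in frame.columns:
        raise InputError("records carry no track_id column")
    frame = frame[frame["track_id"].astype(str) != ""]
    out = []
    for track_id, grp in frame.groupby("track_id", sort=True):
        if grp["timepoint"].duplicated().any():
            raise AmbiguousTrackError(
                f"track {track_id!r} has duplicate timepoints"
            )
        if len(grp) < 2:
            logger.info("track %s has a single frame; skipped", track_id)
            continue
        grp = grp.sort_values("timepoint").reset_index(drop=True)
        steps = np.diff(grp["timepoint"].to_numpy(dtype=float))
        if len(steps) > 1 and np.ptp(steps) > 1e-9 * max(steps.max(), 1.0):
            logger.info("track %s has uneven frame intervals (gap retained)", track_id)
        out.append(Trajectory(track_id=str(track_id), frame=grp))
    return out


def trajectory_stats(traj: Trajectory) -> dict:
    """Sample variances (n-1 denominator) and per-step delta series."""
    if traj.n_frames < 2:
        raise InputError(f"track {traj.track_id!r}: need >= 2 records")
    return {
        "track_id": traj.track_id,
        "var_area": traj.var_area,
        "var_irregularity": traj.var_irregularity,
        "deltas": traj.deltas,
    }


def state_sequence(
    traj: Trajectory,
    model: GatingModel,
    state_map: Optional[dict[str, str]] = None,
) -> tuple[list[str], list[str]]:
    """Classify every frame and condense to morphotype states.

    Returns ``(class_sequence, condensed_sequence)`` and stores both on the
    trajectory.  Condensed mapping defaults to LI->E, LR->F, N->N, else other.
    """
    state_map = dict(CONDENSED_MAP if state_map is None else state_map)
    classified = classify_frame(traj.frame, model)
    classes = classified["morpho_class"].tolist()
    condensed = [state_map.get(c, "other") for c in classes]
    traj.class_sequence = classes
    traj.condensed_sequence = condensed
    return classes, condensed


def count_transitions(
    trajectories: Sequence[Trajectory],
    model: Optional[GatingModel] = None,
) -> TransitionSummary:
    """Tally adjacent-frame condensed-state changes over a cohort.

    Self-transitions are excluded from ``counts`` but contribute to the
    per-state exposure denominators, so ``frequency(src, dst)`` estimates the
    per-frame transition probability.  Trajectory input order does not affect
    the tallies.
    """
    if len(trajectories) == 0:
        raise InputError("no trajectories")
    summary = TransitionSummary(n_trajectories=len(trajectories))
    for traj in trajectories:
        if traj.condensed_sequence is None:
            if model is None:
                raise InputError(
                    f"track {traj.track_id!r} not classified; pass a GatingModel"
                )
            state_sequence(traj, model)
        seq = traj.condensed_sequence
        key = (seq[0], seq[-1])
        summary.start_end[key] = summary.start_end.get(key, 0) + 1
        for a, b in zip(seq[:-1], seq[1:]):
            summary.exposures[a] = summary.exposures.get(a, 0) + 1
            if a != b:
                summary.counts[(a, b)] = summary.counts.get((a, b), 0) + 1
    return summary


def link_by_centroid(
    frames: Sequence[pd.DataFrame],
    max_displacement: float = 50.0,
) -> pd.DataFrame:
    """Greedy mutual-nearest-centroid linking across consecutive frames.

    Each input frame needs ``centroid_x``/``centroid_y`` columns (one detection
    table per timepoint, in time order).  A detection is linked to the nearest
    detection in the next frame when the assignment is mutual and within
    ``max_displacement``; unlinked detections start new tracks.  Convenience
    only — ID-based tracks are the supported acceptance path.
    """
    if not frames:
        raise InputError("no frames to link")
    next_track = 0
    linked = []
    prev = None
    for t, frame in enumerate(frames):
        frame = frame.copy()
        frame["__frame"] = t
        if prev is None:
            frame["track_id"] = [f"t{next_track + i}" for i in range(len(frame))]
            next_track += len(frame)
        else:
            a = prev[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
            b = frame[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
            ids = [None] * len(frame)
            if len(a) and len(b):
                d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
                fwd = d.argmin(axis=1)
                bwd = d.argmin(axis=0)
                for i, j in enumerate(fwd):
                    if bwd[j] == i and d[i, j] <= max_displacement:
                        ids[j] = prev["track_id"].iat[i]
            for j in range(len(frame)):
                if ids[j] is None:
                    ids[j] = f"t{next_track}"
                    next_track += 1
            frame["track_id"] = ids
        linked.append(frame)
        prev = frame
    return pd.concat(linked, ignore_index=True).drop(columns="__frame")
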