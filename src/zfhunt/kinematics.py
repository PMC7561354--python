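"""Hunt-event detection and kinematic feature extraction from tracking traces.

A hunting episode in larval zebrafish is marked by convergent eye posture:
the eyes verge beyond 45 degrees with each eye at least 19 degrees inward,
sustained for at least 100 video frames (at 410 fps), with episodes less
than 300 frames apart concatenated.  From each detected event this module
extracts the first-turn response to prey (azimuth theta, turn phi, turn
ratio gamma = phi / theta) and the capture-manoeuvre features (peak capture
speed, mouth-to-prey distance at capture-bout onset, time to reach prey).

Conventions
-----------
Angles are in degrees.  Heading and prey bearing are measured in arena
coordinates with a shared sign convention, so the prey azimuth
``theta = bearing - heading`` and the first-turn ``phi`` share sign when
the larva turns toward the prey.  "Inward" for the eyes means toward the
midline: left eye >= +19 deg, right eye <= -19 deg, so that vergence
(left - right) is large and positive during hunts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

__all__ = [
    "PX_TO_MM",
    "px_to_mm",
    "TrackingTrace",
    "HuntEvent",
    "HuntFeatures",
    "Bout",
    "filter_eye_traces",
    "compute_vergence",
    "detect_hunt_events",
    "detect_bouts",
    "extract_first_turn",
    "extract_capture_features",
    "extract_event_features",
    "events_to_frame",
    "read_trace_csv",
    "write_trace_csv",
]

# detection constants (printed thresholds)
VERGENCE_THRESHOLD_DEG = 45.0
EYE_INWARD_THRESHOLD_DEG = 19.0
MIN_EVENT_FRAMES = 100
MERGE_GAP_FRAMES = 300
SPEED_THRESHOLD_MM_S = 4.0
EYE_FILTER_CUTOFF_HZ = 28.0
SPEED_FILTER_CUTOFF_HZ = 24.0
FILTER_ORDER = 4
MIN_AZIMUTH_DEG = 3.0  # below this, turn-ratio is undefined
MOUTH_OFFSET_MM = 0.5  # mouth tip ahead of the head reference point

# arena scale: 35 mm dish spanning 790 px, ~44 um per pixel
PX_TO_MM = 35.0 / 790.0


def px_to_mm(pixels) -> float:
    """Convert a pixel count/length to millimetres (35 mm per 790 px)."""
    return np.asarray(pixels) * PX_TO_MM if np.ndim(pixels) else float(pixels) * PX_TO_MM


@dataclass
class TrackingTrace:
    """Per-frame tracking channels for one larva and condition."""

    frame: np.ndarray
    time_s: np.ndarray
    left_eye_deg: np.ndarray
    right_eye_deg: np.ndarray
    head_x_mm: np.ndarray
    head_y_mm: np.ndarray
    heading_deg: np.ndarray
    prey_x_mm: Optional[np.ndarray] = None
    prey_y_mm: Optional[np.ndarray] = None
    fps: float = 410.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self.frame = np.asarray(self.frame, dtype=int)
        n = len(self.frame)
        if n and not np.array_equal(np.diff(self.frame), np.ones(n - 1, dtype=int)):
            raise ValueError("frame index must be strictly increasing and gapless")
        for name in ("left_eye_deg", "right_eye_deg", "heading_deg"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def head_xy(self) -> np.ndarray:
        return np.column_stack([self.head_x_mm, self.head_y_mm])

    @property
    def has_prey(self) -> bool:
        return self.prey_x_mm is not None and np.any(np.isfinite(self.prey_x_mm))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame,
                "time_s": self.time_s,
                "left_eye_deg": self.left_eye_deg,
                "right_eye_deg": self.right_eye_deg,
                "head_x_mm": self.head_x_mm,
                "head_y_mm": self.head_y_mm,
                "heading_deg": self.heading_deg,
                "prey_x_mm": self.prey_x_mm if self.prey_x_mm is not None else np.nan,
                "prey_y_mm": self.prey_y_mm if self.prey_y_mm is not None else np.nan,
            }
        )


def write_trace_csv(trace: TrackingTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fps={trace.fps}\n")
        trace.to_frame().to_csv(fh, index=False)


def read_trace_csv(path, fps: Optional[float] = None) -> TrackingTrace:
    """Read a trace CSV; fps from a leading ``# fps=...`` comment or argument."""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "fps=" in first:
                fps = float(first.split("fps=")[1].strip())
            body = fh.read()
        else:
            body = first + fh.read()
    if fps is None:
        raise ValueError("fps not found in file header and not supplied")
    df = pd.read_csv(io.StringIO(body))
    return TrackingTrace(
        frame=df["frame"].to_numpy(),
        time_s=df["time_s"].to_numpy(),
        left_eye_deg=df["left_eye_deg"].to_numpy(),
        right_eye_deg=df["right_eye_deg"].to_numpy(),
        head_x_mm=df["head_x_mm"].to_numpy(),
        head_y_mm=df["head_y_mm"].to_numpy(),
        heading_deg=df["heading_deg"].to_numpy(),
        prey_x_mm=df["prey_x_mm"].to_numpy() if "prey_x_mm" in df else None,
        prey_y_mm=df["prey_y_mm"].to_numpy() if "prey_y_mm" in df else None,
        fps=fps,
    )


@dataclass
class HuntFeatures:
    """Kinematic features of one hunt event (NaN where undefined)."""

    prey_azimuth_deg: float = np.nan
    first_turn_deg: float = np.nan
    turn_ratio: float = np.nan
    capture_speed_mm_s: float = np.nan
    capture_distance_mm: float = np.nan
    t_prey_s: float = np.nan


@dataclass
class HuntEvent:
    """One vergence episode: [start_frame, end_frame) plus outcome/features."""

    start_frame: int
    end_frame: int
    larva_id: str = ""
    condition: str = "evoked"
    outcome: str = "unlabelled"
    features: Optional[HuntFeatures] = None

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass(frozen=True)
class Bout:
    """One motion bout: [start_frame, end_frame), with its peak speed."""

    start_frame: int
    end_frame: int
    peak_speed: float
    peak_frame: int


def _lowpass(x: np.ndarray, cutoff_hz: float, fps: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (forward-backward)."""
    b, a = butter(FILTER_ORDER, cutoff_hz, btype="low", fs=fps)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(x) <= padlen:
        raise ValueError(f"trace too short for filtering (need > {padlen} samples)")
    return filtfilt(b, a, x)


def filter_eye_traces(trace: TrackingTrace, cutoff_hz: float = EYE_FILTER_CUTOFF_HZ) -> TrackingTrace:
    """Low-pass filter the eye channels (28 Hz, zero phase); other channels untouched."""
    return replace(
        trace,
        left_eye_deg=_lowpass(trace.left_eye_deg, cutoff_hz, trace.fps),
        right_eye_deg=_lowpass(trace.right_eye_deg, cutoff_hz, trace.fps),
    )


def compute_vergence(trace: TrackingTrace) -> np.ndarray:
    """Eye vergence: left eye minus right eye angle (clockwise positive)."""
    return np.asarray(trace.left_eye_deg) - np.asarray(trace.right_eye_deg)


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal True runs of a boolean array as half-open (start, end) pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_hunt_events(
    trace: TrackingTrace,
    *,
    vergence_threshold: float = VERGENCE_THRESHOLD_DEG,
    eye_threshold: float = EYE_INWARD_THRESHOLD_DEG,
    min_frames: int = MIN_EVENT_FRAMES,
    merge_gap: int = MERGE_GAP_FRAMES,
    prefiltered: bool = False,
    larva_id: str = "",
    condition: str = "evoked",
) -> List[HuntEvent]:
    """Detect hunt events: maximal convergent-saccade runs.

    A frame is in hunting mode when vergence >= 45 deg AND the left eye is
    >= 19 deg inward AND the right eye is >= 19 deg inward (toward the
    midline).  Runs closer than 300 frames are concatenated first; runs
    shorter than 100 frames are then discarded (merge-then-filter order, so
    two short runs separated by a small gap can form one valid event).
    """
    if not prefiltered:
        trace = filter_eye_traces(trace)
    verg = compute_vergence(trace)
    mask = (
        (verg >= vergence_threshold)
        & (trace.left_eye_deg >= eye_threshold)
        & (trace.right_eye_deg <= -eye_threshold)
    )
    runs = _runs(mask)
    merged: List[List[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = [
        HuntEvent(
            start_frame=int(trace.frame[s]),
            end_frame=int(trace.frame[e - 1]) + 1,
            larva_id=larva_id,
            condition=condition,
        )
        for s, e in merged
        if e - s >= min_frames
    ]
    return events


def head_speed(trace: TrackingTrace, cutoff_hz: float = SPEED_FILTER_CUTOFF_HZ) -> np.ndarray:
    """Per-frame head speed in mm/s, low-pass filtered at 24 Hz (zero phase)."""
    d = np.diff(trace.head_xy, axis=0)
    speed = np.concatenate([[0.0], np.linalg.norm(d, axis=1) * trace.fps])
    return _lowpass(speed, cutoff_hz, trace.fps)


def detect_bouts(
    trace: TrackingTrace,
    *,
    speed_threshold: float = SPEED_THRESHOLD_MM_S,
    cutoff_hz: float = SPEED_FILTER_CUTOFF_HZ,
    speed: Optional[np.ndarray] = None,
) -> List[Bout]:
    """Segment motion bouts: maximal runs with filtered speed >= 4 mm/s."""
    if speed is None:
        speed = head_speed(trace, cutoff_hz)
    bouts = []
    for s, e in _runs(speed >= speed_threshold):
        k = s + int(np.argmax(speed[s:e]))
        bouts.append(
            Bout(
                start_frame=int(trace.frame[s]),
                end_frame=int(trace.frame[e - 1]) + 1,
                peak_speed=float(speed[k]),
                peak_frame=int(trace.frame[k]),
            )
        )
    return bouts


def _wrap_deg(a):
    """Wrap angle(s) to (-180, 180]."""
    return -((180.0 - np.asarray(a)) % 360.0 - 180.0)


def _index_of(trace: TrackingTrace, frame: int) -> int:
    return int(frame - trace.frame[0])


def mouth_xy(trace: TrackingTrace, idx) -> np.ndarray:
    """Mouth-tip position: head reference advanced along heading by 0.5 mm."""
    h = np.radians(np.asarray(trace.heading_deg)[idx])
    off = MOUTH_OFFSET_MM * np.stack([np.cos(h), np.sin(h)], axis=-1)
    return trace.head_xy[idx] + off


def extract_first_turn(
    event: HuntEvent,
    trace: TrackingTrace,
    bouts: Optional[Sequence[Bout]] = None,
    min_azimuth: float = MIN_AZIMUTH_DEG,
) -> Tuple[float, float]:
    """Prey azimuth theta at event onset and first-turn magnitude phi.

    theta is the signed angle from the larva's heading to the prey bearing
    at hunt onset; phi is the net heading change over the first motion bout
    after onset.  Returns (nan, nan) when no prey is tracked at onset.
    """
    i0 = _index_of(trace, event.start_frame)
    if trace.prey_x_mm is None or not np.isfinite(trace.prey_x_mm[i0]):
        return (np.nan, np.nan)
    m = mouth_xy(trace, i0)
    bearing = np.degrees(
        np.arctan2(trace.prey_y_mm[i0] - m[1], trace.prey_x_mm[i0] - m[0])
    )
    theta = float(_wrap_deg(bearing - trace.heading_deg[i0]))
    if bouts is None:
        bouts = detect_bouts(trace)
    turn_bouts = [b for b in bouts if b.start_frame >= event.start_frame]
    if not turn_bouts:
        return (theta, np.nan)
    b = turn_bouts[0]
    j0, j1 = _index_of(trace, b.start_frame), _index_of(trace, b.end_frame - 1)
    phi = float(_wrap_deg(trace.heading_deg[j1] - trace.heading_deg[j0]))
    return (theta, phi)


def extract_capture_features(
    event: HuntEvent,
    trace: TrackingTrace,
    bouts: Optional[Sequence[Bout]] = None,
    speed: Optional[np.ndarray] = None,
    speed_threshold: float = SPEED_THRESHOLD_MM_S,
) -> Tuple[float, float, float]:
    """Capture-bout features (peak speed s, onset distance d, time to prey).

    The capture bout is the last motion bout starting before the head
    passes the prey (closest-approach frame within the event); any bout
    beginning after closest approach (post-capture) is excluded.  The peak
    speed is taken from the bout onset until the speed first drops below
    4 mm/s after closest approach; distance is mouth tip to prey at bout
    onset; t_prey runs from bout onset to closest approach.
    """
    if speed is None:
        speed = head_speed(trace)
    if bouts is None:
        bouts = detect_bouts(trace, speed=speed)
    i0, i1 = _index_of(trace, event.start_frame), _index_of(trace, event.end_frame)
    if trace.prey_x_mm is None:
        return (np.nan, np.nan, np.nan)
    prey = np.column_stack([trace.prey_x_mm[i0:i1], trace.prey_y_mm[i0:i1]])
    valid = np.isfinite(prey).all(axis=1)
    if not valid.any():
        return (np.nan, np.nan, np.nan)
    mouth = mouth_xy(trace, slice(i0, i1))
    dist = np.full(i1 - i0, np.inf)
    dist[valid] = np.linalg.norm(mouth[valid] - prey[valid], axis=1)
    closest = i0 + int(np.argmin(dist))
    closest_frame = int(trace.frame[closest])

    cand = [b for b in bouts if event.start_frame <= b.start_frame <= closest_frame]
    if not cand:
        return (np.nan, np.nan, np.nan)
    bout = cand[-1]
    j0 = _index_of(trace, bout.start_frame)
    # window: bout onset -> first sub-threshold frame after closest approach
    below = np.flatnonzero(speed[closest:] < speed_threshold)
    j1 = closest + int(below[0]) if below.size else len(speed) - 1
    s = float(np.max(speed[j0 : j1 + 1]))
    d = float(dist[j0 - i0]) if np.isfinite(dist[j0 - i0]) else np.nan
    t_prey = (closest - j0) / trace.fps
    return (s, d, t_prey)


def extract_event_features(
    event: HuntEvent, trace: TrackingTrace, min_azimuth: float = MIN_AZIMUTH_DEG
) -> HuntFeatures:
    """Full kinematic feature set for one event (attached to the event too)."""
    speed = head_speed(trace)
    bouts = detect_bouts(trace, speed=speed)
    theta, phi = extract_first_turn(event, trace, bouts, min_azimuth)
    gamma = phi / theta if np.isfinite(theta) and abs(theta) >= min_azimuth else np.nan
    s, d, t_prey = extract_capture_features(event, trace, bouts, speed)
    feats = HuntFeatures(
        prey_azimuth_deg=theta,
        first_turn_deg=phi,
        turn_ratio=gamma,
        capture_speed_mm_s=s,
        capture_distance_mm=d,
        t_prey_s=t_prey,
    )
    event.features = feats
    return feats


def events_to_frame(events: Sequence[HuntEvent], group: str = "") -> pd.DataFrame:
    """Event table matching the package's event-CSV schema."""
    rows = []
    for ev in events:
        f = ev.features or HuntFeatures()
        rows.append(
            {
                "larva_id": ev.larva_id,
                "group": group,
                "condition": ev.condition,
                "start_frame": ev.start_frame,
                "end_frame": ev.end_frame,
                "outcome": ev.outcome,
                "theta_deg": f.prey_azimuth_deg,
                "phi_deg": f.first_turn_deg,
                "turn_ratio": f.turn_ratio,
                "capture_speed_mm_s": f.capture_speed_mm_s,
                "capture_distance_mm": f.capture_distance_mm,
                "t_prey_s": f.t_prey_s,
            }
        )
    return pd.DataFrame(rows)
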