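"""Synthetic two-rat sessions with scripted ground truth.

No raw videos or audio ship with the study this package models, so every
downstream stage is exercised against a generator that emits the same file
dialects with known ground truth: keypoint pose tracks in which scripted
behavior episodes produce the geometric signature their classifier relies
on, call-detection tables whose records satisfy the defining inequalities
of their scripted type, and a session index with second-resolution start
timestamps.

The arena is 500 x 500 px (a 50 x 50 cm box at a nominal 10 px/cm; origin
top-left, y down — the pose-estimation convention).  Rats are keyframed
from a two-segment body axis with fixed part offsets: a behavior episode
poses the animals it constrains, all other animals idle at their home
position.  Gaussian pixel jitter and a configurable fraction of
low-likelihood ("missing") keypoints are injected on top.

Sessions nominally last 1,200 s at 12 fps with the light change at 600 s;
audio and video start offsets are a few seconds at most.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as feat
from .calls import CALL_COLUMNS
from .pose import ANIMALS, BODY_PARTS, PoseTrack, _columns
from .classify import BEHAVIORS

ARENA_PX = 500.0
PX_PER_CM = 10.0
DEFAULT_FPS = 12.0
SESSION_S = 1200.0
LIGHT_CHANGE_S = 600.0

#: Skeleton part offsets in the body frame (+x toward the nose), px.
SKELETON: dict[str, tuple[float, float]] = {
    "nose": (70.0, 0.0),
    "left_eye": (58.0, -8.0),
    "right_eye": (58.0, 8.0),
    "head": (50.0, 0.0),
    "left_shoulder": (35.0, -18.0),
    "right_shoulder": (35.0, 18.0),
    "back": (15.0, 0.0),
    "middle": (0.0, 0.0),
    "pelvis": (-25.0, 0.0),
    "anogenital": (-45.0, 0.0),
    "tail_middle": (-70.0, 0.0),
    "tail_end": (-100.0, 0.0),
}

#: Curled posture used for self-grooming (head folded toward the flank).
CURLED: dict[str, tuple[float, float]] = {
    "nose": (-30.0, 12.0),
    "left_eye": (-22.0, 18.0),
    "right_eye": (-22.0, 6.0),
    "head": (-12.0, 16.0),
    "left_shoulder": (8.0, 20.0),
    "right_shoulder": (8.0, -20.0),
    "back": (15.0, 0.0),
    "middle": (0.0, 0.0),
    "pelvis": (-25.0, -6.0),
    "anogenital": (-45.0, -4.0),
    "tail_middle": (-62.0, 14.0),
    "tail_end": (-75.0, 30.0),
}

_OFFSETS = np.array([SKELETON[p] for p in BODY_PARTS])
_CURLED = np.array([CURLED[p] for p in BODY_PARTS])

HOME = {"A": ((130.0, 130.0), math.pi / 4), "B": ((370.0, 370.0), 5 * math.pi / 4)}

#: Behaviors posed for a single (subject) animal; all others pose both rats.
SOLO_BEHAVIORS = frozenset({"rearing", "self-grooming"})

# geometric thresholds shared by the generator and the recovery rules
ADJACENT_DIST_PX = 40.0
STATIONARY_PX = 2.0
SNIFF_DIST_PX = 20.0
NOSING_DIST_PX = 15.0
NOSING_BODY_DIST_PX = 100.0
OVERLAP_PCT = 70.0
MOUNT_MOVE_PX = 3.0
CRAWL_MOVE_PX = 5.0
FIGHT_MOVE_PX = 8.0
FOLLOW_MOVE_RANGE_PX = (4.0, 15.0)
FOLLOW_DIST_RANGE_PX = (60.0, 200.0)
FOLLOW_COS_MIN = 0.7
REARING_AREA_FRACTION = 0.35
SELFGROOM_NOSE_PELVIS_PX = 35.0
GROOM_HEAD_BACK_PX = 20.0

CALL_PARAM_RANGES = {
    # (duration_s, bandwidth_khz, principal_freq_khz, detector)
    "SHORT": ((0.004, 0.012), (1.0, 30.0), (40.0, 90.0), "hf"),
    "FLAT": ((0.015, 0.150), (0.5, 6.0), (45.0, 70.0), "hf"),
    "FM": ((0.015, 0.150), (6.5, 40.0), (45.0, 90.0), "hf"),
    "ALARM": ((0.300, 1.500), (0.5, 5.0), (18.0, 32.0), "lf"),
}


def _hull_area(points: np.ndarray) -> float:
    import shapely

    return float(shapely.area(shapely.convex_hull(shapely.multipoints(points))))


#: Hull area of the standard skeleton at scale 1 (px^2).
NOMINAL_HULL_AREA = _hull_area(_OFFSETS)


@dataclass(frozen=True)
class Episode:
    """One scripted behavior bout, in seconds from video start."""

    behavior: str
    start_s: float
    end_s: float
    animal: str = "A"  # subject for solo behaviors; ignored otherwise

    def claimed_animals(self) -> tuple[str, ...]:
        if self.behavior in SOLO_BEHAVIORS:
            return (self.animal,)
        return ANIMALS


@dataclass(frozen=True)
class CallBout:
    """Scripted calls of one type in one time window.

    ``count`` emits exactly that many calls; otherwise the number is
    Poisson with mean ``rate_per_min x window length``.
    """

    call_type: str
    window: tuple[float, float]
    rate_per_min: float | None = None
    count: int | None = None


@dataclass
class SyntheticSessionSpec:
    box_id: str = "A"
    session_type: str = "light_to_dark"
    day: int = 1
    video_duration: float = SESSION_S
    audio_duration: float = SESSION_S
    start_offset: float = 0.0  # audio start minus video start, s
    fps: float = DEFAULT_FPS
    seed: int = 0
    episode_script: list = field(default_factory=list)
    call_script: list = field(default_factory=list)
    noise_px: float = 1.5
    missing_fraction: float = 0.05
    baseline_speed: float = 0.0  # px/frame of idle wander
    p_cutoff: float = 0.6

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.video_duration <= 0 or self.audio_duration <= 0:
            raise ValueError("durations must be positive")
        if abs(self.audio_duration - self.video_duration) > 5.0:
            raise ValueError("audio/video durations may differ by at most 5 s")
        if self.session_type not in ("dark_to_light", "light_to_dark"):
            raise ValueError(f"unknown session type {self.session_type!r}")
        if not 1 <= int(self.day):
            raise ValueError("day must be >= 1")
        self.episode_script = [self._as_episode(e) for e in self.episode_script]
        self.call_script = [self._as_bout(c) for c in self.call_script]
        self._validate_episodes()

    @staticmethod
    def _as_episode(e) -> Episode:
        if isinstance(e, Episode):
            return e
        return Episode(*e)

    @staticmethod
    def _as_bout(c) -> CallBout:
        if isinstance(c, CallBout):
            return c
        call_type, rate, window = c
        return CallBout(call_type=call_type, window=tuple(window), rate_per_min=rate)

    def _validate_episodes(self) -> None:
        for e in self.episode_script:
            if e.behavior not in BEHAVIORS:
                raise ValueError(f"unknown behavior {e.behavior!r}")
            if not (0 <= e.start_s < e.end_s <= self.video_duration):
                raise ValueError(
                    f"episode {e} outside [0, {self.video_duration}] or empty"
                )
        # overlapping episodes may not claim the same animal: mutually
        # exclusive postures (e.g. adjacent lying + following) are rejected
        for i, e1 in enumerate(self.episode_script):
            for e2 in self.episode_script[i + 1 :]:
                if e1.start_s < e2.end_s and e2.start_s < e1.end_s:
                    shared = set(e1.claimed_animals()) & set(e2.claimed_animals())
                    if shared:
                        raise ValueError(
                            f"episodes {e1.behavior!r} and {e2.behavior!r} overlap "
                            f"in time and both pose animal(s) {sorted(shared)}"
                        )
        for c in self.call_script:
            if c.rate_per_min is not None and c.rate_per_min < 0:
                raise ValueError("negative call rate")
            if c.count is not None and c.count < 0:
                raise ValueError("negative call count")

    @property
    def n_frames(self) -> int:
        return math.floor(self.video_duration * self.fps)


@dataclass
class GroundTruth:
    """Scripted truth for one session, rasterised on the video frame grid."""

    behavior_frames: pd.DataFrame  # (n_frames, 11) 0/1
    call_events: pd.DataFrame  # typed call records


def _place(anchor, theta, scale=1.0, offsets=_OFFSETS) -> np.ndarray:
    """(12, 2) keypoints for one rat at an anchor with heading theta."""
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return np.asarray(anchor) + (offsets * scale) @ rot.T


def _home_pose(animal: str, f: int, speed: float) -> np.ndarray:
    (hx, hy), theta = HOME[animal]
    if speed <= 0:
        return _place((hx, hy), theta)
    r = 30.0
    omega = speed / r
    phase = omega * f + (0.0 if animal == "A" else math.pi)
    anchor = (hx + r * math.cos(phase), hy + r * math.sin(phase))
    heading = phase + math.pi / 2  # tangent of the wander circle
    return _place(anchor, heading)


def _episode_pose(behavior: str, f: int, subject: str) -> dict[str, np.ndarray]:
    """Clean keyframed pose(s) for frame ``f`` of an active episode.

    Returns ``{animal: (12, 2) keypoints}`` for the animals the behavior
    constrains.  Geometry is chosen so each behavior satisfies its own
    recovery rule (see :func:`recover_behaviors`) with a safety margin.
    """
    other = "B" if subject == "A" else "A"
    if behavior == "adjacent lying":
        return {
            "A": _place((250.0, 235.0), 0.0),
            "B": _place((250.0, 265.0), 0.0),
        }
    if behavior == "grooming":
        # A's head hovers over B's back, bodies perpendicular, motionless
        return {
            "A": _place((265.0, 208.0), math.pi / 2),
            "B": _place((250.0, 260.0), 0.0),
        }
    if behavior == "anogenital sniffing":
        # A's nose 5 px from B's anogenital centroid
        return {
            "A": _place((178.33, 300.0), 0.0),
            "B": _place((300.0, 300.0), 0.0),
        }
    if behavior == "nosing":
        return {
            "A": _place((176.0, 250.0), 0.0),
            "B": _place((324.0, 250.0), math.pi),
        }
    if behavior == "sniffing":
        # A's nose 12 px below B's flank (middle keypoint)
        return {
            "A": _place((300.0, 352.0), -math.pi / 2),
            "B": _place((300.0, 270.0), 0.0),
        }
    if behavior == "mounting":
        return {
            "A": _place((250.0, 250.0), 0.0),
            "B": _place((250.0, 250.0), 0.0, scale=0.75),
        }
    if behavior == "crawling":
        x = 150.0 + (7.0 * f) % 200.0
        return {
            "A": _place((x, 250.0), 0.0),
            "B": _place((x, 250.0), 0.0, scale=0.75),
        }
    if behavior == "fighting":
        dy = 10.0 if f % 2 == 0 else -10.0
        return {
            "A": _place((235.0, 250.0 + dy), 0.0),
            "B": _place((265.0, 250.0 - dy), math.pi),
        }
    if behavior == "following":
        r, omega, lag = 130.0, 6.0 / 130.0, 0.6
        phi = omega * f
        out = {}
        for animal, ang in (("A", phi), ("B", phi - lag)):
            anchor = (250.0 + r * math.cos(ang), 250.0 + r * math.sin(ang))
            out[animal] = _place(anchor, ang + math.pi / 2)
        return out
    if behavior == "rearing":
        (hx, hy), theta = HOME[subject]
        return {subject: _place((hx, hy), theta, scale=0.45)}
    if behavior == "self-grooming":
        (hx, hy), theta = HOME[subject]
        return {subject: _place((hx, hy), theta, offsets=_CURLED)}
    raise ValueError(f"no keyframe rule for behavior {behavior!r}")


def episode_frames(ep: Episode, fps: float) -> range:
    """Frames on which an episode is active: [floor(start*fps), floor(end*fps))."""
    return range(math.floor(ep.start_s * fps), math.floor(ep.end_s * fps))


def generate_pose_track(spec: SyntheticSessionSpec) -> tuple[PoseTrack, GroundTruth]:
    """Emit the pose track and its scripted ground truth for one session.

    Deterministic under the spec's seed: identical specs yield byte-identical
    tables.  With ``noise_px = 0`` and ``missing_fraction = 0`` the emitted
    coordinates satisfy each scripted behavior's geometric recovery rule on
    exactly the scripted frames.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    coords = {a: np.empty((n, 12, 2)) for a in ANIMALS}
    for a in ANIMALS:
        for f in range(n):
            coords[a][f] = _home_pose(a, f, spec.baseline_speed)

    truth = pd.DataFrame(
        0, index=range(n), columns=list(BEHAVIORS), dtype=int
    )
    for ep in spec.episode_script:
        frames = episode_frames(ep, spec.fps)
        for f in frames:
            poses = _episode_pose(ep.behavior, f, ep.animal)
            for a, pts in poses.items():
                coords[a][f] = pts
        truth.loc[list(frames), ep.behavior] = 1

    lik = {}
    for a in ANIMALS:
        if spec.noise_px > 0:
            coords[a] = coords[a] + rng.normal(0.0, spec.noise_px, coords[a].shape)
        p = rng.uniform(0.9, 1.0, (n, 12))
        if spec.missing_fraction > 0:
            miss = rng.random((n, 12)) < spec.missing_fraction
            p[miss] = rng.uniform(0.0, spec.p_cutoff * 0.99, int(miss.sum()))
        lik[a] = p

    data = np.empty((n, 72))
    col = 0
    for a in ANIMALS:
        for j in range(12):
            data[:, col] = coords[a][:, j, 0]
            data[:, col + 1] = coords[a][:, j, 1]
            data[:, col + 2] = lik[a][:, j]
            col += 3
    df = pd.DataFrame(data, columns=_columns())
    track = PoseTrack(df, fps=spec.fps)
    calls = generate_call_table(spec, typed=True)
    return track, GroundTruth(behavior_frames=truth, call_events=calls)


def generate_call_table(spec: SyntheticSessionSpec, typed: bool = False) -> pd.DataFrame:
    """Emit the raw call-detection table for one session.

    Counts per scripted bout are exact when given, else Poisson at the
    scripted per-minute rate.  Acoustic parameters are sampled strictly
    inside the defining region of the scripted type, so type recovery on
    clean data is exact.  ``typed=True`` appends the scripted type column
    (ground-truth variant).
    """
    rng = np.random.default_rng(spec.seed + 1_000_003)
    rows = []
    for bout in spec.call_script:
        if bout.call_type not in CALL_PARAM_RANGES:
            raise ValueError(f"unknown call type {bout.call_type!r}")
        lo, hi = bout.window
        lo = max(0.0, lo)
        hi = min(hi, spec.audio_duration)
        if hi <= lo:
            continue
        if bout.count is not None:
            k = bout.count
        else:
            k = rng.poisson(bout.rate_per_min * (hi - lo) / 60.0)
        (dlo, dhi), (blo, bhi), (flo, fhi), det = CALL_PARAM_RANGES[bout.call_type]
        for _ in range(k):
            dur = rng.uniform(dlo, dhi)
            begin = rng.uniform(lo, max(lo, hi - dur))
            rows.append(
                {
                    "begin_s": begin,
                    "end_s": begin + dur,
                    "duration_s": dur,
                    "principal_freq_khz": rng.uniform(flo, fhi),
                    "bandwidth_khz": rng.uniform(blo, bhi),
                    "detector": det,
                    "call_type": bout.call_type,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "begin_s",
            "end_s",
            "duration_s",
            "principal_freq_khz",
            "bandwidth_khz",
            "detector",
            "call_type",
        ],
    )
    table = table.sort_values("begin_s", kind="stable").reset_index(drop=True)
    table.insert(0, "id", range(len(table)))
    if not typed:
        table = table[list(CALL_COLUMNS)]
    return table


def ground_truth(spec: SyntheticSessionSpec) -> GroundTruth:
    """Scripted ground truth without synthesising coordinates.

    Identical to the truth returned by :func:`generate_pose_track` (same
    rasterisation, same call sampling stream) but skips the pose pass —
    useful when only the aggregation/statistics stages are under study.
    """
    n = spec.n_frames
    truth = pd.DataFrame(0, index=range(n), columns=list(BEHAVIORS), dtype=int)
    for ep in spec.episode_script:
        truth.loc[list(episode_frames(ep, spec.fps)), ep.behavior] = 1
    return GroundTruth(
        behavior_frames=truth, call_events=generate_call_table(spec, typed=True)
    )


# ---------------------------------------------------------------------------
# geometric recovery (the closed loop used to validate the generator)


def _sym_move(cent: np.ndarray) -> np.ndarray:
    """Per-frame movement robust to episode-boundary teleports: the smaller
    of the backward and forward displacement."""
    n = len(cent)
    step = np.linalg.norm(np.diff(cent, axis=0), axis=1)
    back = np.concatenate(([np.inf], step))
    fwd = np.concatenate((step, [np.inf]))
    out = np.minimum(back, fwd)
    if n == 1:
        return np.zeros(1)
    return out


def _sym_velocity(cent: np.ndarray) -> np.ndarray:
    """Per-frame velocity vector: the smaller-magnitude of the backward and
    forward difference."""
    n = len(cent)
    d = np.diff(cent, axis=0)
    out = np.zeros_like(cent)
    for f in range(n):
        fwd = d[f] if f < n - 1 else None
        bwd = d[f - 1] if f > 0 else None
        if fwd is None and bwd is None:
            continue
        if fwd is None:
            out[f] = bwd
        elif bwd is None:
            out[f] = fwd
        else:
            out[f] = fwd if np.linalg.norm(fwd) <= np.linalg.norm(bwd) else bwd
    return out


def recover_behaviors(track: PoseTrack) -> pd.DataFrame:
    """Apply each behavior's geometric definition to a clean track.

    This is the self-consistency loop of the generator: on noise-free data
    the recovered 0/1 matrix equals the scripted ground truth.  The rules
    mirror the signatures the classifiers learn (centroid distances, hull
    overlap, hull shrinkage, movement)."""
    cents = feat.centroids(track)
    poly = feat.polygon_features(track)
    overlap = poly["polygon_pct_overlap"].to_numpy()
    body = {a: cents[("body", a)] for a in ANIMALS}
    headc = {a: cents[("head", a)] for a in ANIMALS}
    agc = {a: cents[("anogenital", a)] for a in ANIMALS}
    xy = {(a, p): track.xy(a, p) for a in ANIMALS for p in BODY_PARTS}
    move = {a: _sym_move(body[a]) for a in ANIMALS}
    vel = {a: _sym_velocity(body[a]) for a in ANIMALS}
    d_body = np.linalg.norm(body["A"] - body["B"], axis=1)

    def dist(p, q):
        return np.linalg.norm(p - q, axis=1)

    areas = {
        a: feat._hull_areas(track.coords_array(a)) for a in ANIMALS
    }

    still = {a: move[a] < STATIONARY_PX for a in ANIMALS}
    both_still = still["A"] & still["B"]

    out = pd.DataFrame(0, index=track.data.index, columns=list(BEHAVIORS), dtype=int)
    # side-by-side rest: close centroids, no movement, but bodies not
    # stacked (high overlap means mounting/crawling, not huddling)
    out["adjacent lying"] = (
        (d_body < ADJACENT_DIST_PX) & both_still & (overlap < OVERLAP_PCT)
    ).astype(int)
    out["anogenital sniffing"] = (
        np.minimum(
            dist(xy[("A", "nose")], agc["B"]), dist(xy[("B", "nose")], agc["A"])
        )
        < SNIFF_DIST_PX
    ).astype(int)
    mean_move = (move["A"] + move["B"]) / 2
    out["crawling"] = ((overlap > OVERLAP_PCT) & (mean_move > CRAWL_MOVE_PX)).astype(int)
    out["mounting"] = ((overlap > OVERLAP_PCT) & (mean_move < MOUNT_MOVE_PX)).astype(int)
    out["fighting"] = (
        (d_body < ADJACENT_DIST_PX)
        & (move["A"] > FIGHT_MOVE_PX)
        & (move["B"] > FIGHT_MOVE_PX)
    ).astype(int)
    vcos = np.sum(vel["A"] * vel["B"], axis=1)
    norms = np.linalg.norm(vel["A"], axis=1) * np.linalg.norm(vel["B"], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vcos = np.where(norms > 0, vcos / norms, 0.0)
    lo_m, hi_m = FOLLOW_MOVE_RANGE_PX
    lo_d, hi_d = FOLLOW_DIST_RANGE_PX
    out["following"] = (
        (move["A"] > lo_m)
        & (move["A"] <= hi_m)
        & (move["B"] > lo_m)
        & (move["B"] <= hi_m)
        & (d_body > lo_d)
        & (d_body < hi_d)
        & (vcos > FOLLOW_COS_MIN)
    ).astype(int)
    out["grooming"] = (
        (
            (dist(headc["A"], xy[("B", "back")]) < GROOM_HEAD_BACK_PX)
            | (dist(headc["B"], xy[("A", "back")]) < GROOM_HEAD_BACK_PX)
        )
        & both_still
    ).astype(int)
    out["nosing"] = (
        (dist(xy[("A", "nose")], xy[("B", "nose")]) < NOSING_DIST_PX)
        & (d_body > NOSING_BODY_DIST_PX)
    ).astype(int)
    out["sniffing"] = (
        (dist(xy[("A", "nose")], xy[("B", "middle")]) < SNIFF_DIST_PX)
        | (dist(xy[("B", "nose")], xy[("A", "middle")]) < SNIFF_DIST_PX)
    ).astype(int)
    thr_area = REARING_AREA_FRACTION * NOMINAL_HULL_AREA
    out["rearing"] = ((areas["A"] < thr_area) | (areas["B"] < thr_area)).astype(int)
    out["self-grooming"] = (
        (
            (dist(xy[("A", "nose")], xy[("A", "pelvis")]) < SELFGROOM_NOSE_PELVIS_PX)
            & still["A"]
        )
        | (
            (dist(xy[("B", "nose")], xy[("B", "pelvis")]) < SELFGROOM_NOSE_PELVIS_PX)
            & still["B"]
        )
    ).astype(int)
    return out
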