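"""Whole-study synthesis: many boxes x days x transition sessions.

A full study is 6 housing boxes observed on 6 days, each day contributing a
dark-to-light session (lights on at 06:00) and a light-to-dark session
(lights off at 18:00); each session nominally 1,200 s of video at 12 fps
with a separately recorded audio file of slightly different start time and
duration.  Sessions can be dropped to emulate missing recordings, and a
programmed lights-off effect (more fighting and more ALARM/FLAT/SHORT call
time after the light change of light-to-dark sessions) supports end-to-end
recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import trim_to_common
from .calls import write_call_csv
from .classify import BEHAVIORS
from .pose import write_pose_csv
from .synthetic import (
    CallBout,
    Episode,
    LIGHT_CHANGE_S,
    SESSION_S,
    SOLO_BEHAVIORS,
    SyntheticSessionSpec,
    generate_call_table,
    generate_pose_track,
)

SESSION_TYPES = ("dark_to_light", "light_to_dark")
BASE_DATE = pd.Timestamp("2023-05-05")
SESSION_CLOCK = {"dark_to_light": "05:50:00", "light_to_dark": "17:50:00"}

#: Mean episode count per 10-minute phase and bout-duration range (s).
EPISODE_RATES: dict[str, tuple[float, tuple[float, float]]] = {
    "adjacent lying": (1.0, (20.0, 50.0)),
    "anogenital sniffing": (3.0, (2.0, 6.0)),
    "crawling": (2.0, (3.0, 8.0)),
    "fighting": (2.0, (3.0, 8.0)),
    "following": (3.0, (2.0, 6.0)),
    "grooming": (2.0, (3.0, 8.0)),
    "mounting": (2.0, (2.0, 6.0)),
    "nosing": (3.0, (1.0, 4.0)),
    "rearing": (3.0, (2.0, 6.0)),
    "self-grooming": (2.0, (3.0, 8.0)),
    "sniffing": (3.0, (1.0, 4.0)),
}

#: Mean calls per minute by type.
CALL_RATES: dict[str, float] = {"FLAT": 3.0, "FM": 4.0, "SHORT": 2.0, "ALARM": 0.5}

#: Categories boosted after lights-off in light-to-dark sessions.
LIGHTS_OFF_BEHAVIORS = ("fighting",)
LIGHTS_OFF_CALLS = ("ALARM", "FLAT", "SHORT")
DEFAULT_LIGHTS_OFF_FACTOR = 3.0


def build_episode_script(
    rng: np.random.Generator,
    session_type: str,
    video_duration: float,
    lights_off_factor: float = DEFAULT_LIGHTS_OFF_FACTOR,
) -> list[Episode]:
    """Random non-overlapping behavior episodes for one session.

    Episode counts per 10-minute phase are Poisson at the rates of
    :data:`EPISODE_RATES`; in light-to-dark sessions the fighting rate after
    the light change is multiplied by ``lights_off_factor``.  Episodes are
    rejection-packed so no two overlap (every episode poses at least one
    shared animal, so overlaps would be invalid)."""
    change = min(LIGHT_CHANGE_S, video_duration)
    phases = [(0.0, change), (change, video_duration)]
    occupied: list[tuple[float, float]] = []
    episodes: list[Episode] = []
    for phase_i, (lo, hi) in enumerate(phases):
        if hi <= lo:
            continue
        scale = (hi - lo) / LIGHT_CHANGE_S
        for behavior, (rate, (dlo, dhi)) in EPISODE_RATES.items():
            lam = rate * scale
            if (
                session_type == "light_to_dark"
                and phase_i == 1
                and behavior in LIGHTS_OFF_BEHAVIORS
            ):
                lam *= lights_off_factor
            for _ in range(rng.poisson(lam)):
                dur = rng.uniform(dlo, dhi)
                if dur >= hi - lo:
                    continue
                for _try in range(50):
                    start = rng.uniform(lo, hi - dur)
                    iv = (start - 0.5, start + dur + 0.5)
                    if all(iv[1] <= a or iv[0] >= b for a, b in occupied):
                        occupied.append(iv)
                        animal = "A" if behavior not in SOLO_BEHAVIORS else rng.choice(["A", "B"])
                        episodes.append(Episode(behavior, start, start + dur, str(animal)))
                        break
    episodes.sort(key=lambda e: e.start_s)
    return episodes


def build_call_script(
    rng: np.random.Generator,
    session_type: str,
    audio_duration: float,
    start_offset: float,
    lights_off_factor: float = DEFAULT_LIGHTS_OFF_FACTOR,
) -> list[CallBout]:
    """Per-type call bouts for the two lighting phases of one session.

    Windows are expressed in audio time, so the video-clock light change at
    600 s lands at ``600 - start_offset`` s of audio."""
    change = min(max(LIGHT_CHANGE_S - start_offset, 0.0), audio_duration)
    bouts = []
    for phase_i, (lo, hi) in enumerate([(0.0, change), (change, audio_duration)]):
        if hi <= lo:
            continue
        for call_type, rate in CALL_RATES.items():
            if (
                session_type == "light_to_dark"
                and phase_i == 1
                and call_type in LIGHTS_OFF_CALLS
            ):
                rate = rate * lights_off_factor
            bouts.append(CallBout(call_type, (lo, hi), rate_per_min=rate))
    return bouts


@dataclass
class StudySession:
    """One planned session: its generator spec plus true wall-clock starts."""

    box: str
    day: int
    session_type: str
    spec: SyntheticSessionSpec
    video_start: pd.Timestamp  # true, sub-second
    audio_start: pd.Timestamp

    @property
    def true_lag_s(self) -> float:
        return (self.audio_start - self.video_start).total_seconds()

    def index_row(self, early_late_available: bool) -> dict:
        stem = f"{self.box}_{self.video_start.date()}_{self.session_type}"
        return {
            "box": self.box,
            "date": str(self.video_start.date()),
            "session_type": self.session_type,
            "video_file": f"{stem}.csv",
            "audio_file": f"{stem}_usv.csv",
            # index timestamps are one-second resolution (floored)
            "video_start_iso": self.video_start.floor("s").isoformat(),
            "audio_start_iso": self.audio_start.floor("s").isoformat(),
            "video_duration_s": self.spec.video_duration,
            "audio_duration_s": self.spec.audio_duration,
            "fps": self.spec.fps,
            "day": self.day,
            "early_late_available": early_late_available,
        }


def plan_study(
    n_boxes: int = 6,
    n_days: int = 6,
    seed: int = 0,
    video_duration: float = SESSION_S,
    fps: float = 12.0,
    session_types: tuple[str, ...] = SESSION_TYPES,
    drop: set | None = None,
    lights_off_factor: float = DEFAULT_LIGHTS_OFF_FACTOR,
    noise_px: float = 1.5,
    missing_fraction: float = 0.05,
    baseline_speed: float = 1.5,
) -> tuple[list[StudySession], pd.DataFrame]:
    """Plan a study: one spec per surviving box x day x session type.

    ``drop`` holds (box, day, session_type) triples to omit, emulating the
    availability calendars of missing recordings.  An experiment with fewer
    than 4 days cannot contrast early (days 1-3) against late (days 4-6);
    the index flags this in ``early_late_available``.

    Returns the session list and the session index (ISO timestamps at
    one-second resolution).
    """
    if n_boxes < 1:
        raise ValueError("need at least one box")
    rng = np.random.default_rng(seed)
    drop = drop or set()
    early_late = n_days >= 4
    sessions = []
    for b in range(n_boxes):
        box = chr(ord("A") + b)
        for day in range(1, n_days + 1):
            for st in session_types:
                if (box, day, st) in drop:
                    continue
                offset = float(rng.uniform(-2.0, 2.0))
                audio_duration = video_duration + float(rng.uniform(-2.0, 2.0))
                video_start = (
                    BASE_DATE
                    + pd.Timedelta(days=day - 1)
                    + pd.Timedelta(SESSION_CLOCK[st])
                    + pd.Timedelta(seconds=float(rng.uniform(0, 1)))
                )
                audio_start = video_start + pd.Timedelta(seconds=offset)
                spec = SyntheticSessionSpec(
                    box_id=box,
                    session_type=st,
                    day=day,
                    video_duration=video_duration,
                    audio_duration=audio_duration,
                    start_offset=offset,
                    fps=fps,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    episode_script=build_episode_script(
                        rng, st, video_duration, lights_off_factor
                    ),
                    call_script=build_call_script(
                        rng, st, audio_duration, offset, lights_off_factor
                    ),
                    noise_px=noise_px,
                    missing_fraction=missing_fraction,
                    baseline_speed=baseline_speed,
                )
                sessions.append(
                    StudySession(
                        box=box,
                        day=day,
                        session_type=st,
                        spec=spec,
                        video_start=video_start,
                        audio_start=audio_start,
                    )
                )
    index = pd.DataFrame([s.index_row(early_late) for s in sessions])
    return sessions, index


def generate_study(out_dir, **plan_kwargs) -> pd.DataFrame:
    """Materialise a planned study on disk: pose CSVs, call CSVs, index CSV.

    Returns the index.  File dialects match the readers in
    :mod:`ethousv.pose`, :mod:`ethousv.calls` and :mod:`ethousv.alignment`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sessions, index = plan_study(**plan_kwargs)
    for sess, (_, row) in zip(sessions, index.iterrows()):
        track, _truth = generate_pose_track(sess.spec)
        write_pose_csv(track, out / row["video_file"])
        write_call_csv(generate_call_table(sess.spec), out / row["audio_file"])
    index.to_csv(out / "index.csv", index=False)
    return index


def sample_alignment_residuals(
    n_sessions: int = 50, seed: int = 0, fps: float = 12.0
) -> np.ndarray:
    """Residual audio/video misalignment (frames) over random sessions.

    Each trial draws a true audio-start offset and an audio/video duration
    difference uniformly within +/-2 s, quantises both start timestamps to
    whole seconds (the index resolution), trims on the recovered lag, and
    measures the residual against the true lag.  With second-resolution
    clocks the residual stays below one second (12 frames).
    """
    rng = np.random.default_rng(seed)
    residuals = np.empty(n_sessions)
    video_duration = SESSION_S
    for i in range(n_sessions):
        true_lag = float(rng.uniform(-2.0, 2.0))
        audio_duration = video_duration + float(rng.uniform(-2.0, 2.0))
        video_start = float(rng.uniform(0.0, 1.0))  # sub-second clock phase
        audio_start = video_start + true_lag
        recovered_lag = math.floor(audio_start) - math.floor(video_start)
        n_video = math.floor(video_duration * fps)
        n_audio = math.floor(audio_duration * fps)
        video = pd.DataFrame({"v": np.zeros(n_video)})
        audio = pd.DataFrame({"a": np.zeros(n_audio)})
        _, _, report = trim_to_common(
            video, audio, recovered_lag, fps, true_lag_s=true_lag
        )
        residuals[i] = report.residual_frames
    return residuals
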