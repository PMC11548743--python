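"""End-to-end orchestration: raw session data to the ANOVA battery.

The session path is: clean the pose track -> extract the 111 features ->
per-frame behavior predictions (or scripted truth) -> type and band-filter
the calls -> build the audio frame grid and mark call frames -> trim audio
and video to the common timeline -> merge into one frame-annotation table
-> 1-minute epoch durations.  The study path collapses epochs into the 2x2
cell means and runs the rank RM-ANOVA battery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aggregate import collapse_design, epoch_durations
from .alignment import make_audio_grid, mark_call_frames, merge_annotations, trim_to_common
from .anova import run_battery
from .calls import classify_calls, filter_calls
from .classify import BEHAVIORS, ClassifierBundle, predict_frames, train_classifiers
from .features import extract_features
from .pose import PoseTrack, interpolate_track
from .study import StudySession
from .synthetic import (
    Episode,
    SyntheticSessionSpec,
    generate_call_table,
    generate_pose_track,
    ground_truth,
)


def annotate_session(
    track: PoseTrack | None,
    calls_raw: pd.DataFrame,
    audio_duration_s: float,
    start_lag_s: float,
    bundle: ClassifierBundle | None = None,
    behavior_truth: pd.DataFrame | None = None,
    fps: float | None = None,
) -> pd.DataFrame:
    """Aligned frame-annotation table (behaviors + call types) for one session.

    Behavior columns come from the classifier bundle applied to ``track``,
    or from a supplied ground-truth matrix when the pose-to-classifier
    stage is not under study (then ``track`` may be None but ``fps`` is
    required).  ``start_lag_s`` is the audio start minus the video start as
    the session index records it.
    """
    if fps is None:
        if track is None:
            raise ValueError("need fps when no track is given")
        fps = track.fps
    if behavior_truth is not None:
        behaviors = behavior_truth.copy()
    elif bundle is not None:
        clean = interpolate_track(track)
        feats = extract_features(clean)
        behaviors, _proba = predict_frames(bundle, feats)
    else:
        raise ValueError("need either a classifier bundle or behavior truth")
    typed = filter_calls(classify_calls(calls_raw))
    grid = make_audio_grid(audio_duration_s, fps)
    grid = mark_call_frames(grid, typed, fps)
    behaviors, grid, _report = trim_to_common(behaviors, grid, start_lag_s, fps)
    return merge_annotations(behaviors, grid)


def session_epochs(session: StudySession, annotations: pd.DataFrame) -> pd.DataFrame:
    ep = epoch_durations(annotations, session.spec.fps)
    ep.insert(0, "box", session.box)
    ep.insert(1, "day", session.day)
    ep.insert(2, "session_type", session.session_type)
    return ep


def analyze_study(
    sessions: list[StudySession],
    bundle: ClassifierBundle | None = None,
    use_truth: bool = False,
    rank: bool | str = "auto",
) -> dict:
    """Run the full post-tracking analysis over planned synthetic sessions.

    With ``use_truth=True`` the scripted behavior frames stand in for
    classifier output (isolates the aggregation + statistics stages);
    otherwise every session's pose track is cleaned, featurised and scored
    by the bundle.  Returns the per-epoch table, the 2x2 cell means, the
    incomplete-cell report, and the ANOVA battery table.
    """
    all_epochs = []
    for sess in sessions:
        if use_truth:
            truth = ground_truth(sess.spec)
            track = None
            behavior_truth = truth.behavior_frames
        else:
            track, truth = generate_pose_track(sess.spec)
            behavior_truth = None
        calls_raw = generate_call_table(sess.spec)
        # recorded lag: what the one-second-resolution index would recover
        rec_lag = (
            sess.audio_start.floor("s") - sess.video_start.floor("s")
        ).total_seconds()
        ann = annotate_session(
            track,
            calls_raw,
            sess.spec.audio_duration,
            rec_lag,
            bundle=bundle,
            behavior_truth=behavior_truth,
            fps=sess.spec.fps,
        )
        all_epochs.append(session_epochs(sess, ann))
    epochs = pd.concat(all_epochs, ignore_index=True)
    cells, incomplete = collapse_design(epochs)
    battery = run_battery(cells, rank=rank)
    return {
        "epochs": epochs,
        "cells": cells,
        "incomplete": incomplete,
        "battery": battery,
    }


def make_training_data(
    seed: int = 0,
    n_episodes_per_behavior: int = 6,
    noise_px: float = 1.5,
    missing_fraction: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Labeled feature/label frames for classifier training.

    Builds a few richly scripted sessions in which every behavior recurs,
    mirroring the practice of labeling short recordings rich in the target
    behaviors, then returns (features, labels) on the pooled frames.
    """
    rng = np.random.default_rng(seed)
    feats = []
    labels = []
    episode_len = {b: 4.0 for b in BEHAVIORS}
    episode_len["adjacent lying"] = 10.0
    for rep in range(n_episodes_per_behavior):
        script = []
        t = 2.0
        order = list(BEHAVIORS)
        rng.shuffle(order)
        subject = "A" if rep % 2 == 0 else "B"
        for b in order:
            dur = episode_len[b] * float(rng.uniform(0.7, 1.3))
            script.append(Episode(b, t, t + dur, subject))
            t += dur + float(rng.uniform(1.0, 3.0))
        duration = t + 2.0
        spec = SyntheticSessionSpec(
            box_id="train",
            session_type="dark_to_light",
            day=1,
            video_duration=duration,
            audio_duration=duration,
            seed=int(rng.integers(0, 2**31 - 1)),
            episode_script=script,
            noise_px=noise_px,
            missing_fraction=missing_fraction,
            baseline_speed=1.5,
        )
        track, truth = generate_pose_track(spec)
        clean = interpolate_track(track)
        feats.append(extract_features(clean))
        labels.append(truth.behavior_frames)
    X = pd.concat(feats, ignore_index=True)
    y = pd.concat(labels, ignore_index=True)
    return X, y


def train_default_bundle(seed: int = 0, n_trees: int = 100) -> ClassifierBundle:
    """Train the 11-behavior bundle on freshly generated labeled sessions."""
    X, y = make_training_data(seed=seed)
    return train_classifiers(X, y, n_trees=n_trees, seed=seed)
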