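"""Frame-accurate alignment of audio-borne call events with video frames.

Video and audio are recorded by different devices whose files differ in
start time and duration.  All annotations are placed on a single per-frame
timeline (1/12 s at 12 fps): an audio "frame grid" with one row per video
frame duration is built, call events mark their spanning frames, and the two
streams are trimmed to a common start and length using the session index's
start timestamps.

Index timestamps are stored at one-second resolution, so even with
perfectly synchronised device clocks the recovered lag carries up to ~1 s of
quantisation error; the residual misalignment after trimming is reported and
stays within the 12-frame (1 s) acceptability bound for clock skews up to
2 s.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .calls import CALL_TYPES

logger = logging.getLogger(__name__)

INDEX_COLUMNS = (
    "box",
    "date",
    "session_type",
    "video_file",
    "audio_file",
    "video_start_iso",
    "audio_start_iso",
    "video_duration_s",
    "audio_duration_s",
    "fps",
)


def audio_frame_grid_rows(audio_duration_s: float, fps: float) -> int:
    """Number of rows of the audio frame grid: floor(duration x fps).

    A 1,200.005 s recording at 12 fps yields 14,400 rows; a 1,202.168 s
    recording yields 14,426.
    """
    if audio_duration_s <= 0 or fps <= 0:
        raise ValueError("duration and fps must be positive")
    return math.floor(audio_duration_s * fps)


def make_audio_grid(audio_duration_s: float, fps: float) -> pd.DataFrame:
    """Empty per-frame call-annotation grid for one audio recording.

    One row per video-frame duration; per call type a 0/1 presence column
    and a zero-filled probability placeholder column.
    """
    n = audio_frame_grid_rows(audio_duration_s, fps)
    cols: dict[str, np.ndarray] = {}
    for ct in CALL_TYPES:
        cols[f"Probability_{ct}"] = np.zeros(n)
        cols[ct] = np.zeros(n, dtype=int)
    return pd.DataFrame(cols)


def mark_call_frames(grid: pd.DataFrame, calls: pd.DataFrame, fps: float) -> pd.DataFrame:
    """Set the per-type 0/1 columns for every call in a typed call table.

    A call spanning [begin_s, end_s] marks frames floor(begin x fps) ..
    floor(end x fps) inclusive, so calls shorter than one frame still mark
    one frame.  Overlapping calls of different types may mark the same
    frame.  Calls extending past the recording are clipped with a warning.
    """
    out = grid.copy()
    n = len(out)
    for _, rec in calls.iterrows():
        ct = rec["call_type"]
        if ct not in CALL_TYPES:
            continue
        first = math.floor(rec["begin_s"] * fps)
        last = math.floor(rec["end_s"] * fps)
        if last < 0 or first >= n:
            logger.warning(
                "call %s at [%.3f, %.3f] s lies outside the recording; skipped",
                ct,
                rec["begin_s"],
                rec["end_s"],
            )
            continue
        if first < 0 or last >= n:
            logger.warning(
                "call %s at [%.3f, %.3f] s clipped to the recording span",
                ct,
                rec["begin_s"],
                rec["end_s"],
            )
        first = max(first, 0)
        last = min(last, n - 1)
        col = out.columns.get_loc(ct)
        out.iloc[first : last + 1, col] = 1
    return out


@dataclass
class TrimReport:
    """Bookkeeping for one audio/video trim."""

    video_head_cut: int
    audio_head_cut: int
    video_tail_cut: int
    audio_tail_cut: int
    common_frames: int
    #: Residual temporal misalignment between the two streams after the
    #: head cut, in frames.  Computed against the true lag when it is known
    #: (synthetic sessions); otherwise the sub-frame rounding residue.
    residual_frames: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def trim_to_common(
    video: pd.DataFrame,
    audio: pd.DataFrame,
    start_lag_s: float,
    fps: float,
    true_lag_s: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TrimReport]:
    """Trim the video and audio frame tables to one common timeline.

    ``start_lag_s`` is the audio start minus the video start as recovered
    from the session index.  The later-starting stream defines time zero:
    the earlier stream loses ``round(lag x fps)`` head frames, then the
    longer tail is cut so both tables have equal length.  Row content is
    never modified, only dropped.
    """
    shift = int(round(abs(start_lag_s) * fps))
    video_head = audio_head = 0
    if start_lag_s > 0:
        video_head = shift  # audio starts later; drop early video
    elif start_lag_s < 0:
        audio_head = shift
    if video_head >= len(video) or audio_head >= len(audio):
        raise ValueError("no overlap between audio and video after lag correction")
    v = video.iloc[video_head:]
    a = audio.iloc[audio_head:]
    common = min(len(v), len(a))
    if common < 1:
        raise ValueError("no overlap between audio and video after lag correction")
    video_tail = len(v) - common
    audio_tail = len(a) - common
    v = v.iloc[:common].reset_index(drop=True)
    a = a.iloc[:common].reset_index(drop=True)
    signed_shift = shift if start_lag_s >= 0 else -shift
    if true_lag_s is None:
        residual = abs(start_lag_s * fps - signed_shift)
    else:
        residual = abs(true_lag_s * fps - signed_shift)
    report = TrimReport(
        video_head_cut=video_head,
        audio_head_cut=audio_head,
        video_tail_cut=video_tail,
        audio_tail_cut=audio_tail,
        common_frames=common,
        residual_frames=float(residual),
    )
    return v, a, report


def merge_annotations(
    behaviors: pd.DataFrame,
    call_grid: pd.DataFrame,
    tolerance_frames: int = 0,
) -> pd.DataFrame:
    """Column-union of trimmed behavior predictions and the call grid.

    Both tables must already share the common timeline; a length mismatch
    beyond ``tolerance_frames`` is an error, a smaller one truncates to the
    shorter table.
    """
    diff = abs(len(behaviors) - len(call_grid))
    if diff > tolerance_frames:
        raise ValueError(
            f"length mismatch of {diff} frames exceeds tolerance "
            f"{tolerance_frames} (behaviors {len(behaviors)}, calls {len(call_grid)})"
        )
    n = min(len(behaviors), len(call_grid))
    merged = pd.concat(
        [
            behaviors.iloc[:n].reset_index(drop=True),
            call_grid.iloc[:n].reset_index(drop=True),
        ],
        axis=1,
    )
    merged.index.name = "frame"
    return merged


def start_lag_from_index(row: pd.Series) -> float:
    """Audio start minus video start, seconds, from index ISO timestamps.

    Timestamps are stored at one-second resolution, so the value is exact
    only to within the quantisation of the two clocks.
    """
    audio = pd.Timestamp(row["audio_start_iso"])
    video = pd.Timestamp(row["video_start_iso"])
    return (audio - video).total_seconds()


def read_index_csv(path) -> pd.DataFrame:
    idx = pd.read_csv(path)
    missing = set(INDEX_COLUMNS) - set(idx.columns)
    if missing:
        raise ValueError(f"index CSV missing columns: {sorted(missing)}")
    dup = idx.duplicated(subset=["box", "date", "session_type"])
    if dup.any():
        raise ValueError("index has duplicate (box, date, session_type) rows")
    if not (idx["video_duration_s"] > 0).all() or not (idx["audio_duration_s"] > 0).all():
        raise ValueError("index durations must be positive")
    return idx


def write_index_csv(index: pd.DataFrame, path) -> None:
    index.to_csv(path, index=False)
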