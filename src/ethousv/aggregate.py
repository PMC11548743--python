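"""Epoch aggregation of frame annotations and co-occurrence scoring.

Transition sessions are summarised in 1-minute epochs (20 per nominal
1,200-s session; the light change falls between epochs 10 and 11).  A
category positive for a whole epoch spans up to 720 frames = 60 s at
12 fps.  Durations are positive frames divided by fps; event ("bout")
counts are maximal runs of consecutive positive frames — with minimum bout
length 0 a single positive frame is one bout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calls import CALL_TYPES

EPOCH_S = 60.0
#: Epochs 1-10 precede the light change, 11-20 follow it.
LIGHT_CHANGE_EPOCH = 10
#: Days 1-3 form the early phase of the experiment, 4-6 the late phase.
EARLY_DAYS = (1, 2, 3)


def _runs(binary: np.ndarray) -> int:
    """Number of maximal runs of 1s in a 0/1 vector."""
    b = np.asarray(binary, dtype=bool).astype(np.int8)
    if b.size == 0:
        return 0
    return int(b[0] + np.sum(np.diff(b) == 1))


def _run_spans(binary: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs (half-open) of maximal runs of 1s."""
    b = np.asarray(binary, dtype=bool).astype(np.int8)
    if b.size == 0:
        return []
    edges = np.diff(np.concatenate(([0], b, [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def annotation_categories(annotations: pd.DataFrame) -> list[str]:
    """The 0/1 category columns of a frame-annotation table (probability
    placeholder columns are not categories)."""
    return [c for c in annotations.columns if not c.startswith("Probability_")]


def epoch_durations(
    annotations: pd.DataFrame,
    fps: float,
    epoch_s: float = EPOCH_S,
) -> pd.DataFrame:
    """Per-epoch duration (s) and bout count for every annotation category.

    Epochs are consecutive ``epoch_s`` blocks from the session start,
    numbered from 1.  A trailing partial epoch is kept with its true length
    in ``epoch_len_s``.
    """
    cats = annotation_categories(annotations)
    frames_per_epoch = int(round(epoch_s * fps))
    n = len(annotations)
    rows = []
    n_epochs = int(np.ceil(n / frames_per_epoch)) if n else 0
    values = {c: annotations[c].to_numpy() for c in cats}
    for e in range(n_epochs):
        lo, hi = e * frames_per_epoch, min((e + 1) * frames_per_epoch, n)
        epoch_len = (hi - lo) / fps
        for c in cats:
            seg = values[c][lo:hi]
            rows.append(
                {
                    "epoch": e + 1,
                    "category": c,
                    "duration_s": float(seg.sum() / fps),
                    "count": _runs(seg),
                    "epoch_len_s": epoch_len,
                }
            )
    return pd.DataFrame(
        rows, columns=["epoch", "category", "duration_s", "count", "epoch_len_s"]
    )


def collapse_design(
    epochs: pd.DataFrame,
    epoch_s: float = EPOCH_S,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse per-epoch durations to the 2x2 within-subject cell means.

    ``epochs`` is a long table with columns box, day, session_type plus the
    :func:`epoch_durations` columns.  Per box x session_type x category,
    epochs 1-10 ("before") and 11-20 ("after") are averaged, then days 1-3
    ("early") and 4-6 ("late"); a day missing from the study is simply
    absent from its mean.  Trailing partial epochs are excluded (only whole
    epochs are comparable).

    Returns ``(cells, incomplete)`` where ``incomplete`` flags
    (box, session_type, category) combinations missing at least one of the
    four cells; those boxes are to be excluded from the affected ANOVA.
    """
    df = epochs[epochs["epoch_len_s"] >= epoch_s - 1e-9].copy()
    df = df[df["epoch"] <= 2 * LIGHT_CHANGE_EPOCH]
    df["lighting"] = np.where(
        df["epoch"] <= LIGHT_CHANGE_EPOCH, "before_change", "after_change"
    )
    df["phase"] = np.where(df["day"].isin(EARLY_DAYS), "early", "late")
    # mean over epochs within a session, then over days within a phase
    per_session = (
        df.groupby(
            ["box", "session_type", "category", "day", "phase", "lighting"],
            as_index=False,
        )["duration_s"]
        .mean()
    )
    cells = (
        per_session.groupby(
            ["box", "session_type", "category", "lighting", "phase"], as_index=False
        )["duration_s"]
        .mean()
        .rename(columns={"duration_s": "value"})
    )
    counts = cells.groupby(["box", "session_type", "category"]).size()
    incomplete = (
        counts[counts < 4]
        .reset_index(name="n_cells")
        .sort_values(["session_type", "category", "box"])
        .reset_index(drop=True)
    )
    return cells, incomplete


def cooccurrence_sums(
    annotations: pd.DataFrame,
    fps: float,
    epoch_s: float = EPOCH_S,
    unit: str = "calls",
) -> pd.DataFrame:
    """Per-epoch co-occurrence sums between call types and behaviors.

    With ``unit="calls"`` (default): for two call types the sum is the
    total number of calls of either type in the epoch (1 SHORT + 4 FM
    -> 5); for a behavior and a call type it is the number of calls of
    that type whose marked frames intersect frames where the behavior is
    scored 1.  With ``unit="frames"`` both variants instead count seconds
    in which the two columns are simultaneously 1.

    Calls are recovered as maximal runs of the marked call-type columns, so
    abutting same-type calls merge into one event.
    """
    if unit not in ("calls", "frames"):
        raise ValueError("unit must be 'calls' or 'frames'")
    cats = annotation_categories(annotations)
    behaviors = sorted(c for c in cats if c not in CALL_TYPES)
    call_cols = sorted(c for c in cats if c in CALL_TYPES)
    frames_per_epoch = int(round(epoch_s * fps))
    n = len(annotations)
    n_epochs = int(np.ceil(n / frames_per_epoch)) if n else 0
    values = {c: annotations[c].to_numpy() for c in cats}
    rows = []
    for e in range(n_epochs):
        lo, hi = e * frames_per_epoch, min((e + 1) * frames_per_epoch, n)
        segs = {c: values[c][lo:hi] for c in cats}
        counts = {c: _runs(segs[c]) for c in call_cols}
        for i, c1 in enumerate(call_cols):
            for c2 in call_cols[i + 1 :]:
                if unit == "calls":
                    s = counts[c1] + counts[c2]
                else:
                    s = float(np.sum(segs[c1].astype(bool) & segs[c2].astype(bool)) / fps)
                rows.append({"cat1": c1, "cat2": c2, "epoch": e + 1, "sum": s})
        for b in behaviors:
            bmask = segs[b].astype(bool)
            for c in call_cols:
                if unit == "calls":
                    s = sum(
                        1
                        for (a, z) in _run_spans(segs[c])
                        if bmask[a:z].any()
                    )
                else:
                    s = float(np.sum(bmask & segs[c].astype(bool)) / fps)
                rows.append({"cat1": b, "cat2": c, "epoch": e + 1, "sum": s})
    return pd.DataFrame(rows, columns=["cat1", "cat2", "epoch", "sum"])


def bin_events(timestamps, bin_s: float, total_s: float | None = None) -> np.ndarray:
    """Count events in consecutive half-open bins [k*bin_s, (k+1)*bin_s).

    An event exactly on a boundary falls in the later bin; the total count
    is conserved.  ``total_s`` fixes the number of bins (else the span of
    the last event decides).
    """
    ts = np.asarray(sorted(timestamps), dtype=float)
    if total_s is None:
        total_s = ts[-1] + bin_s if ts.size else bin_s
    n_bins = int(np.ceil(total_s / bin_s))
    if ts.size == 0:
        return np.zeros(n_bins, dtype=int)
    idx = np.floor(ts / bin_s).astype(int)
    if (idx < 0).any() or (idx >= n_bins).any():
        raise ValueError("timestamps outside the recording span")
    return np.bincount(idx, minlength=n_bins)


def plot_cooccurrence_heatmap(pairs: pd.DataFrame, ax=None):
    """Flat heat-map of total co-occurrence sums per category pair."""
    import matplotlib.pyplot as plt

    mat = pairs.pivot_table(
        index="cat1", columns="cat2", values="sum", aggfunc="sum", fill_value=0
    )
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90)
    ax.set_yticks(range(len(mat.index)), mat.index)
    ax.figure.colorbar(im, ax=ax, label="co-occurrence sum")
    ax.set_title("Behavior / call-type co-occurrences")
    return ax
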