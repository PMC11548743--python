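"""Two-animal pose tracks: container, CSV dialect, and cleaning.

A track holds per-frame (x, y, likelihood) triplets for 12 body parts of
each of two rats, exported by a multi-animal pose estimator at a fixed frame
rate.  Cleaning replaces low-confidence detections by the temporally nearest
confident observation and zero-fills keypoints that were never detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 12 tracked body parts, rostral to caudal.
BODY_PARTS: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "head",
    "left_shoulder",
    "right_shoulder",
    "back",
    "middle",
    "pelvis",
    "anogenital",
    "tail_middle",
    "tail_end",
)

#: Animal identifiers, fixed order.
ANIMALS: tuple[str, str] = ("A", "B")

#: Default likelihood cutoff below which a detection is treated as missing.
DEFAULT_P_CUTOFF = 0.6

_COORDS = ("x", "y", "likelihood")


def _columns() -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [ANIMALS, BODY_PARTS, _COORDS], names=["animal", "bodypart", "coord"]
    )


@dataclass
class PoseTrack:
    """Per-frame keypoint table for two animals.

    Parameters
    ----------
    data : DataFrame with a 3-level column MultiIndex
        ``(animal, bodypart, coord)`` where coord is x, y or likelihood.
    fps : float
        Video frame rate (frames per second).
    zero_filled : set of (animal, bodypart)
        Keypoints that were missing for the entire session and were set to
        zero during cleaning; excluded from centroid means downstream.
    """

    data: pd.DataFrame
    fps: float
    zero_filled: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        expected = _columns()
        if not self.data.columns.equals(expected):
            # accept same labels in any layout
            self.data = self.data.reindex(columns=expected)
            if self.data.isna().all(axis=None):
                raise ValueError("track must carry 24 keypoint triplets per frame")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def _values(self) -> np.ndarray:
        cached = getattr(self, "_values_cache", None)
        if cached is None or cached.shape[0] != len(self.data):
            cached = self.data.to_numpy(float)
            object.__setattr__(self, "_values_cache", cached)
        return cached

    def _locs(self, cols: list[tuple[str, str, str]]) -> np.ndarray:
        return self.data.columns.get_indexer(cols)

    def xy(self, animal: str, part: str) -> np.ndarray:
        """(n_frames, 2) coordinate array for one keypoint."""
        i = self._locs([(animal, part, "x"), (animal, part, "y")])
        return self._values()[:, i]

    def likelihoods(self, animal: str) -> pd.DataFrame:
        """(n_frames, 12) likelihood table for one animal."""
        i = self._locs([(animal, p, "likelihood") for p in BODY_PARTS])
        return pd.DataFrame(
            self._values()[:, i], index=self.data.index, columns=list(BODY_PARTS)
        )

    def coords_array(self, animal: str) -> np.ndarray:
        """(n_frames, 12, 2) array of keypoint coordinates for one animal."""
        i = self._locs(
            [(animal, p, c) for p in BODY_PARTS for c in ("x", "y")]
        )
        return self._values()[:, i].reshape(len(self.data), 12, 2)

    def copy(self) -> "PoseTrack":
        return PoseTrack(self.data.copy(), self.fps, set(self.zero_filled))


def write_pose_csv(track: PoseTrack, path) -> None:
    """Write the 3-header-row pose CSV dialect (animal / bodypart / coord)."""
    track.data.to_csv(path, index=True, index_label="frame")


def read_pose_csv(path, fps: float) -> PoseTrack:
    """Read the 3-header-row pose CSV dialect written by :func:`write_pose_csv`."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    df.columns = df.columns.set_names(["animal", "bodypart", "coord"])
    df.index = df.index.astype(int)
    df.index.name = None
    return PoseTrack(df.astype(float), fps=fps)


def _nearest_fill(values: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Fill unobserved entries with the temporally nearest observed value.

    Ties between an earlier and a later observation break toward the earlier
    frame.  A series with no observed entry is returned as all zeros.
    """
    n = len(values)
    out = values.astype(float).copy()
    obs_idx = np.flatnonzero(observed)
    if obs_idx.size == 0:
        return np.zeros(n)
    if obs_idx.size == n:
        return out
    miss_idx = np.flatnonzero(~observed)
    # position of the first observed index >= each missing index
    right = np.searchsorted(obs_idx, miss_idx, side="left")
    left = right - 1
    left_c = np.clip(left, 0, obs_idx.size - 1)
    right_c = np.clip(right, 0, obs_idx.size - 1)
    d_left = np.where(left >= 0, miss_idx - obs_idx[left_c], np.iinfo(np.int64).max)
    d_right = np.where(
        right < obs_idx.size, obs_idx[right_c] - miss_idx, np.iinfo(np.int64).max
    )
    # earlier frame wins ties
    take_left = d_left <= d_right
    src = np.where(take_left, obs_idx[left_c], obs_idx[right_c])
    out[miss_idx] = values[src]
    return out


def interpolate_track(raw: PoseTrack, p_cutoff: float = DEFAULT_P_CUTOFF) -> PoseTrack:
    """Clean a raw track by temporal nearest-neighbour interpolation.

    Coordinates whose detection likelihood falls below ``p_cutoff`` (or that
    are NaN) are treated as missing and replaced by the value at the
    temporally nearest confident frame, ties breaking toward the earlier
    frame; leading/trailing gaps take the nearest confident value.  A
    keypoint confident in no frame at all is zero-filled for the whole
    session and recorded in ``zero_filled``.

    The operation is idempotent: likelihoods are kept as bookkeeping, so a
    second pass reconstructs the same fills.
    """
    if raw.n_frames == 0:
        raise ValueError("cannot interpolate an empty track")
    df = raw.data.copy()
    zero_filled: set[tuple[str, str]] = set(raw.zero_filled)
    for animal in ANIMALS:
        for part in BODY_PARTS:
            lik = df[(animal, part, "likelihood")].to_numpy(float)
            observed = (lik >= p_cutoff) & ~np.isnan(lik)
            for coord in ("x", "y"):
                col = (animal, part, coord)
                vals = df[col].to_numpy(float)
                observed_c = observed & ~np.isnan(vals)
                df[col] = _nearest_fill(vals, observed_c)
            if not observed.any():
                zero_filled.add((animal, part))
    df = df.fillna(0.0)
    return PoseTrack(df, fps=raw.fps, zero_filled=zero_filled)


def to_feature_input(track: PoseTrack) -> dict[str, np.ndarray]:
    """Unpack a cleaned track into fixed-order arrays for feature extraction.

    Returns a dict with, per animal, ``coords`` of shape (n_frames, 12, 2)
    in :data:`BODY_PARTS` order and ``likelihood`` of shape (n_frames, 12),
    plus the frame index.  Column order is fixed by :data:`BODY_PARTS` /
    :data:`ANIMALS` and stable across runs.
    """
    out: dict[str, np.ndarray] = {"frame": track.data.index.to_numpy()}
    for animal in ANIMALS:
        out[f"coords_{animal}"] = track.coords_array(animal)
        out[f"likelihood_{animal}"] = (
            track.likelihoods(animal).reindex(columns=list(BODY_PARTS)).to_numpy(float)
        )
    return out
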