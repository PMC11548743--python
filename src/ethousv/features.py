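"""Per-frame geometric features for a two-rat pose track.

The feature vector has exactly 111 columns: 2 hull-overlap ("polygon")
features plus 109 custom features spanning the families a frame-level
social-behavior classifier needs — detection likelihoods, body/head/anogenital
centroids and their 1-second rolling means, convex-hull areas, within- and
between-animal distances, per-frame and 1-second rolling movements, and
body-axis angles.

All coordinates are in pixels; areas in px^2; angles in degrees in [0, 180].
Rolling windows are trailing, one second long (``fps`` frames), truncated at
the session start.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely

from .pose import ANIMALS, BODY_PARTS, PoseTrack

#: Keypoints contributing to each centroid.
CENTROID_PARTS: dict[str, tuple[str, ...]] = {
    "body": BODY_PARTS,
    "head": ("nose", "left_eye", "right_eye", "head"),
    "anogenital": ("pelvis", "anogenital", "tail_middle"),
}

_CENTROID_KINDS = ("body", "head", "anogenital")
_HULL_KINDS = {"body": BODY_PARTS, "head": ("nose", "left_eye", "right_eye", "head")}

POLYGON_FEATURES = ("polygon_pct_overlap", "difference_area")


def _build_manifest() -> list[tuple[str, str]]:
    """(name, family) pairs for the 109 custom features, in column order."""
    m: list[tuple[str, str]] = []
    for a in ANIMALS:
        for part in BODY_PARTS:
            m.append((f"p_{a}_{part}", "likelihood"))
    for kind in _CENTROID_KINDS:
        for a in ANIMALS:
            for c in ("x", "y"):
                m.append((f"cent_{kind}_{a}_{c}", "centroid"))
    for kind in _CENTROID_KINDS:
        for a in ANIMALS:
            for c in ("x", "y"):
                m.append((f"cent_{kind}_{a}_{c}_roll", "centroid_rolling"))
    for kind in _HULL_KINDS:
        for a in ANIMALS:
            m.append((f"hull_{kind}_{a}_area", "hull"))
    for kind in _HULL_KINDS:
        for a in ANIMALS:
            m.append((f"hull_{kind}_{a}_area_roll", "hull_rolling"))
    for a in ANIMALS:
        m.append((f"hull_body_{a}_ratio", "hull_change"))
    for kind in _CENTROID_KINDS:
        for a in ANIMALS:
            m.append((f"move_{kind}_{a}", "movement"))
    for kind in _CENTROID_KINDS:
        for a in ANIMALS:
            m.append((f"move_{kind}_{a}_roll", "movement_rolling"))
    m.append(("move_total", "movement"))
    for ka in _CENTROID_KINDS:
        for kb in _CENTROID_KINDS:
            m.append((f"dist_{ka}A_{kb}B", "between_distance"))
    for ka in _CENTROID_KINDS:
        for kb in _CENTROID_KINDS:
            m.append((f"dist_{ka}A_{kb}B_roll", "between_distance_rolling"))
    m.append(("dist_min", "between_distance"))
    m.append(("dist_noseA_noseB", "cross_part_distance"))
    m.append(("dist_noseA_anogenB", "cross_part_distance"))
    m.append(("dist_noseB_anogenA", "cross_part_distance"))
    for a in ANIMALS:
        m.append((f"dist_nose_back_{a}", "within_distance"))
        m.append((f"dist_headcent_agcent_{a}", "within_distance"))
        m.append((f"dist_nose_tailend_{a}", "within_distance"))
    for a in ANIMALS:
        m.append((f"dist_nose_pelvis_{a}", "elongation"))
    for a in ANIMALS:
        m.append((f"angle_nose_head_back_{a}", "angle"))
        m.append((f"angle_head_back_pelvis_{a}", "angle"))
    for a in ANIMALS:
        m.append((f"p_mean_{a}", "likelihood_summary"))
        m.append((f"p_min_{a}", "likelihood_summary"))
    return m


_MANIFEST = _build_manifest()
CUSTOM_FEATURE_NAMES: tuple[str, ...] = tuple(name for name, _ in _MANIFEST)
assert len(CUSTOM_FEATURE_NAMES) == 109
ALL_FEATURE_NAMES: tuple[str, ...] = POLYGON_FEATURES + CUSTOM_FEATURE_NAMES


def feature_manifest() -> pd.DataFrame:
    """Machine-readable manifest of all 111 feature columns."""
    rows = [(n, "polygon") for n in POLYGON_FEATURES] + list(_MANIFEST)
    return pd.DataFrame(rows, columns=["name", "family"])


def _hull_areas(coords: np.ndarray) -> np.ndarray:
    """Vectorised convex-hull areas for (n_frames, k, 2) point sets.

    Degenerate hulls (fewer than 3 distinct points, or collinear) get 0.
    """
    geoms = shapely.multipoints(coords)
    hulls = shapely.convex_hull(geoms)
    return shapely.area(hulls)


def _hulls(coords: np.ndarray):
    return shapely.convex_hull(shapely.multipoints(coords))


def polygon_features(track: PoseTrack) -> pd.DataFrame:
    """Body-polygon overlap features per frame.

    The body polygon of each animal is the convex hull of its 12 keypoints.
    ``polygon_pct_overlap`` is 100 x intersection area / min(area_A, area_B)
    (the smaller hull as denominator captures one animal atop the other);
    ``difference_area`` is |area_A - area_B| in px^2.  A degenerate hull
    contributes area 0 and overlap 0.
    """
    hulls_a = _hulls(track.coords_array("A"))
    hulls_b = _hulls(track.coords_array("B"))
    area_a = shapely.area(hulls_a)
    area_b = shapely.area(hulls_b)
    inter = shapely.area(shapely.intersection(hulls_a, hulls_b))
    min_area = np.minimum(area_a, area_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(min_area > 0, 100.0 * inter / min_area, 0.0)
    pct = np.clip(pct, 0.0, 100.0)
    return pd.DataFrame(
        {"polygon_pct_overlap": pct, "difference_area": np.abs(area_a - area_b)},
        index=track.data.index,
    )


def centroids(track: PoseTrack) -> dict[tuple[str, str], np.ndarray]:
    """Body, head and anogenital centroids per frame for both animals.

    Returns ``{(kind, animal): (n_frames, 2) array}``.  Keypoints that were
    zero-filled as wholly missing are excluded from the mean; if every
    constituent of a centroid is zero-filled the centroid is (0, 0).
    """
    out: dict[tuple[str, str], np.ndarray] = {}
    for a in ANIMALS:
        coords = track.coords_array(a)  # (n, 12, 2)
        for kind, parts in CENTROID_PARTS.items():
            idx = [
                BODY_PARTS.index(p)
                for p in parts
                if (a, p) not in track.zero_filled
            ]
            if idx:
                out[(kind, a)] = coords[:, idx, :].mean(axis=1)
            else:
                out[(kind, a)] = np.zeros((track.n_frames, 2))
    return out


def _angle_deg(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Angle at the middle vertex p2, in degrees in [0, 180]; 0 if degenerate."""
    v1 = p1 - p2
    v2 = p3 - p2
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    denom = n1 * n2
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.where(denom > 0, (v1 * v2).sum(axis=1) / denom, 1.0)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dist(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return np.linalg.norm(p - q, axis=1)


def custom_features(track: PoseTrack) -> pd.DataFrame:
    """The 109-column custom feature table for a cleaned track.

    Requires the track's ``fps`` for the 1-second rolling windows.  Rolling
    means/sums are trailing and truncated at the session start; per-frame
    movements are 0 at frame 0.
    """
    if track.fps is None or track.fps <= 0:
        raise ValueError("track fps must be set: rolling windows are undefined")
    n = track.n_frames
    window = max(int(round(track.fps)), 1)
    cols: dict[str, np.ndarray] = {}

    lik = {a: track.likelihoods(a).reindex(columns=list(BODY_PARTS)) for a in ANIMALS}
    for a in ANIMALS:
        arr = lik[a].to_numpy(float)
        for j, part in enumerate(BODY_PARTS):
            cols[f"p_{a}_{part}"] = arr[:, j]

    cent = centroids(track)

    def roll_mean(x: np.ndarray) -> np.ndarray:
        return pd.Series(x).rolling(window, min_periods=1).mean().to_numpy()

    def roll_sum(x: np.ndarray) -> np.ndarray:
        return pd.Series(x).rolling(window, min_periods=1).sum().to_numpy()

    for kind in _CENTROID_KINDS:
        for a in ANIMALS:
            c = cent[(kind, a)]
            cols[f"cent_{kind}_{a}_x"] = c[:, 0]
            cols[f"cent_{kind}_{a}_y"] = c[:, 1]
    for kind in _CENTROID_KINDS:
        for a in ANIMALS:
            c = cent[(kind, a)]
            cols[f"cent_{kind}_{a}_x_roll"] = roll_mean(c[:, 0])
            cols[f"cent_{kind}_{a}_y_roll"] = roll_mean(c[:, 1])

    hull_area: dict[tuple[str, str], np.ndarray] = {}
    for kind, parts in _HULL_KINDS.items():
        idx = [BODY_PARTS.index(p) for p in parts]
        for a in ANIMALS:
            hull_area[(kind, a)] = _hull_areas(track.coords_array(a)[:, idx, :])
    for kind in _HULL_KINDS:
        for a in ANIMALS:
            cols[f"hull_{kind}_{a}_area"] = hull_area[(kind, a)]
    for kind in _HULL_KINDS:
        for a in ANIMALS:
            cols[f"hull_{kind}_{a}_area_roll"] = roll_mean(hull_area[(kind, a)])
    for a in ANIMALS:
        area = hull_area[("body", a)]
        mean_area = cols[f"hull_body_{a}_area_roll"]
        cols[f"hull_body_{a}_ratio"] = np.where(
            mean_area > 0, area / np.where(mean_area > 0, mean_area, 1.0), 1.0
        )

    move: dict[tuple[str, str], np.ndarray] = {}
    for kind in _CENTROID_KINDS:
        for a in ANIMALS:
            c = cent[(kind, a)]
            m = np.zeros(n)
            if n > 1:
                m[1:] = _dist(c[1:], c[:-1])
            move[(kind, a)] = m
    for kind in _CENTROID_KINDS:
        for a in ANIMALS:
            cols[f"move_{kind}_{a}"] = move[(kind, a)]
    for kind in _CENTROID_KINDS:
        for a in ANIMALS:
            cols[f"move_{kind}_{a}_roll"] = roll_sum(move[(kind, a)])
    cols["move_total"] = move[("body", "A")] + move[("body", "B")]

    between: dict[str, np.ndarray] = {}
    for ka in _CENTROID_KINDS:
        for kb in _CENTROID_KINDS:
            between[f"dist_{ka}A_{kb}B"] = _dist(cent[(ka, "A")], cent[(kb, "B")])
    cols.update(between)
    for name, d in between.items():
        cols[f"{name}_roll"] = roll_mean(d)
    cols["dist_min"] = np.min(np.stack(list(between.values()), axis=1), axis=1)

    xy = {(a, p): track.xy(a, p) for a in ANIMALS for p in BODY_PARTS}
    cols["dist_noseA_noseB"] = _dist(xy[("A", "nose")], xy[("B", "nose")])
    cols["dist_noseA_anogenB"] = _dist(xy[("A", "nose")], xy[("B", "anogenital")])
    cols["dist_noseB_anogenA"] = _dist(xy[("B", "nose")], xy[("A", "anogenital")])

    for a in ANIMALS:
        cols[f"dist_nose_back_{a}"] = _dist(xy[(a, "nose")], xy[(a, "back")])
        cols[f"dist_headcent_agcent_{a}"] = _dist(
            cent[("head", a)], cent[("anogenital", a)]
        )
        cols[f"dist_nose_tailend_{a}"] = _dist(xy[(a, "nose")], xy[(a, "tail_end")])
    for a in ANIMALS:
        cols[f"dist_nose_pelvis_{a}"] = _dist(xy[(a, "nose")], xy[(a, "pelvis")])

    for a in ANIMALS:
        cols[f"angle_nose_head_back_{a}"] = _angle_deg(
            xy[(a, "nose")], xy[(a, "head")], xy[(a, "back")]
        )
        cols[f"angle_head_back_pelvis_{a}"] = _angle_deg(
            xy[(a, "head")], xy[(a, "back")], xy[(a, "pelvis")]
        )

    for a in ANIMALS:
        arr = lik[a].to_numpy(float)
        cols[f"p_mean_{a}"] = arr.mean(axis=1)
        cols[f"p_min_{a}"] = arr.min(axis=1)

    out = pd.DataFrame(cols, index=track.data.index)
    out = out[list(CUSTOM_FEATURE_NAMES)]
    return out


def merge_features(polygon_table: pd.DataFrame, custom_table: pd.DataFrame) -> pd.DataFrame:
    """Merge polygon and custom feature tables into the final 111-column set.

    Row counts are truncated to the shorter table (sessions processed by
    different stages can differ by a few trailing frames).
    """
    n = min(len(polygon_table), len(custom_table))
    if n == 0:
        raise ValueError("no overlapping rows between feature tables")
    merged = pd.concat(
        [
            polygon_table.iloc[:n].reset_index(drop=True),
            custom_table.iloc[:n].reset_index(drop=True),
        ],
        axis=1,
    )
    return merged[list(ALL_FEATURE_NAMES)]


def extract_features(track: PoseTrack) -> pd.DataFrame:
    """Full 111-column feature table (polygon + custom) for a cleaned track."""
    return merge_features(polygon_features(track), custom_features(track))
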