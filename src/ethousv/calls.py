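"""Ultrasonic-call typing from detector export tables.

Rat ultrasonic vocalizations fall into two families: 50-kHz calls (arousal /
positive affect, detected by the high-frequency path) and 22-kHz "alarm"
calls (aversive states, low-frequency path).  Within the 50-kHz family the
acoustic rules are:

* SHORT — duration <= 12 ms;
* FLAT  — duration > 12 ms and bandwidth <= 6 kHz;
* FM    — duration > 12 ms and bandwidth > 6 kHz (frequency modulated).

Low-frequency detections are ALARM calls.  FM calls are not sub-typed into
trills or steps.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CALL_TYPES = ("ALARM", "FLAT", "FM", "SHORT")

#: Maximum duration of a SHORT call, seconds.
SHORT_MAX_DURATION_S = 0.012
#: Maximum bandwidth of a FLAT call, kHz.
FLAT_MAX_BANDWIDTH_KHZ = 6.0
#: Principal-frequency band retained for the high-frequency (50-kHz) path.
BAND_HF_KHZ = (35.0, 95.0)
#: Principal-frequency band retained for the low-frequency (22-kHz) path.
#: The detector configuration prints its cutoffs in the reversed order
#: (high: 10, low: 35); they are read here as the ordered band [10, 35].
BAND_LF_KHZ = (10.0, 35.0)
#: Below this principal frequency an untagged call is treated as low-frequency.
LF_SPLIT_KHZ = 32.0

CALL_COLUMNS = (
    "id",
    "begin_s",
    "end_s",
    "duration_s",
    "principal_freq_khz",
    "bandwidth_khz",
    "detector",
)

#: Spectrogram settings of the upstream detector, kept as provenance only.
DETECTOR_PROVENANCE = {
    "fft_window_s": 0.0032,
    "overlap_fraction": 0.90,
    "contour_entropy_threshold": 0.215,
    "contour_amplitude_percentile": 0.825,
}


def classify_call(
    duration_s: float,
    bandwidth_khz: float,
    principal_freq_khz: float | None = None,
    detector: str | None = None,
) -> str:
    """Assign one call its type.

    A low-frequency-path detection is ALARM regardless of shape.  When the
    detector path is unknown, a principal frequency below 32 kHz routes the
    call to ALARM before the 50-kHz rules apply.  Otherwise: duration
    <= 12 ms -> SHORT; bandwidth <= 6 kHz -> FLAT; else FM.  Both boundaries
    are inclusive.
    """
    if duration_s <= 0:
        raise ValueError(f"non-positive call duration: {duration_s}")
    if detector == "lf":
        return "ALARM"
    if detector is None and principal_freq_khz is not None:
        if principal_freq_khz < LF_SPLIT_KHZ:
            return "ALARM"
    if duration_s <= SHORT_MAX_DURATION_S:
        return "SHORT"
    if bandwidth_khz <= FLAT_MAX_BANDWIDTH_KHZ:
        return "FLAT"
    return "FM"


def classify_calls(table: pd.DataFrame) -> pd.DataFrame:
    """Append a ``call_type`` column to a call table (vectorised rules)."""
    t = table.copy()
    if len(t) == 0:
        t["call_type"] = pd.Series([], dtype=object)
        return t
    dur = t["duration_s"].to_numpy(float)
    if (dur <= 0).any():
        raise ValueError("non-positive call duration in table")
    bw = t["bandwidth_khz"].to_numpy(float)
    det = t.get("detector")
    if det is not None:
        is_lf = det.to_numpy() == "lf"
    else:
        is_lf = t["principal_freq_khz"].to_numpy(float) < LF_SPLIT_KHZ
    call_type = np.where(
        is_lf,
        "ALARM",
        np.where(
            dur <= SHORT_MAX_DURATION_S,
            "SHORT",
            np.where(bw <= FLAT_MAX_BANDWIDTH_KHZ, "FLAT", "FM"),
        ),
    )
    t["call_type"] = call_type
    return t


def filter_calls(
    table: pd.DataFrame,
    band_hf: tuple[float, float] = BAND_HF_KHZ,
    band_lf: tuple[float, float] = BAND_LF_KHZ,
) -> pd.DataFrame:
    """Drop calls whose principal frequency falls outside the band of their
    detector path (inclusive bounds).  Dropped counts are logged."""
    for name, (lo, hi) in (("band_hf", band_hf), ("band_lf", band_lf)):
        if not lo < hi:
            raise ValueError(f"{name} must be ordered low < high, got {(lo, hi)}")
    if band_lf == BAND_LF_KHZ:
        logger.info(
            "low-frequency band read as the ordered pair [10, 35] kHz; "
            "detector configuration dumps sometimes print the cutoffs transposed"
        )
    if len(table) == 0:
        return table.copy()
    freq = table["principal_freq_khz"].to_numpy(float)
    is_lf = table["detector"].to_numpy() == "lf"
    lo = np.where(is_lf, band_lf[0], band_hf[0])
    hi = np.where(is_lf, band_lf[1], band_hf[1])
    keep = (freq >= lo) & (freq <= hi)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "filter_calls dropped %d/%d records outside their frequency band",
            n_drop,
            len(table),
        )
    return table.loc[keep].reset_index(drop=True)


def validate_call_table(table: pd.DataFrame) -> None:
    """Check the call-table contract: end > begin, duration consistent to
    1e-6 s, bandwidth non-negative."""
    if len(table) == 0:
        return
    if not (table["end_s"] > table["begin_s"]).all():
        raise ValueError("call table contains end_s <= begin_s")
    resid = np.abs(
        table["duration_s"] - (table["end_s"] - table["begin_s"])
    ).to_numpy(float)
    if (resid > 1e-6).any():
        raise ValueError("duration_s inconsistent with begin/end times")
    if (table["bandwidth_khz"] < 0).any():
        raise ValueError("negative bandwidth")


def read_call_csv(path) -> pd.DataFrame:
    """Read the call CSV dialect (columns :data:`CALL_COLUMNS`)."""
    t = pd.read_csv(path)
    missing = set(CALL_COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"call CSV missing columns: {sorted(missing)}")
    return t


def write_call_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
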