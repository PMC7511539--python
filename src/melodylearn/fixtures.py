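"""Packaged participant tables.

``load_table1`` returns the 25-row per-participant descriptive table
(demographics, GXT and interval-exercise-test outcomes) used by the
between-group analyses; ``load_table2`` returns the completed high-intensity
dose for the five HIIT participants who stopped before finishing the
protocol.  Both are checksum-verified on load so silent fixture edits fail
loudly.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .exercise import parse_dose

__all__ = ["load_table1", "load_table2", "TABLE1_SHA256", "TABLE2_SHA256"]

TABLE1_SHA256 = "541ba9b783fbda8436efa5773947f8bf992c22fd777f4c4e32bdab6090ab3181"
TABLE2_SHA256 = "a77d83254d6cd51427c4b5a11dd83395f0478dbbc81d668fe137c728c70ce16f"

INCOMPLETE_HIIT_IDS = frozenset({16, 17, 20, 21, 24})


def _read(name: str, expected_sha: str) -> pd.DataFrame:
    raw = resources.files("melodylearn.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected_sha:
        raise RuntimeError(f"fixture {name} failed checksum verification ({digest})")
    import io

    return pd.read_csv(io.BytesIO(raw))


def load_table1() -> pd.DataFrame:
    """The 25-participant descriptive table (13 High / 12 Low).

    Columns: pt, group (High/Low intensity), sex, age, competitiveness,
    eft (extra familiarization trials), m_train (musical training, months),
    ipaq (MET-minutes/week), vo2peak (ml/kg/min), wmax (W), GXT HRmax /
    RERmax / RPEmax, and interval-exercise-test HRmax / RPEmax.
    """
    df = _read("table1.csv", TABLE1_SHA256)
    if len(df) != 25:
        raise RuntimeError("participant table must have 25 rows")
    counts = df["group"].value_counts()
    if counts.get("High") != 13 or counts.get("Low") != 12:
        raise RuntimeError("group sizes must be 13 High / 12 Low")
    return df


def load_table2() -> pd.DataFrame:
    """Completed high-intensity dose for the five participants who did not
    finish the HIIT protocol.  Adds ``dose_seconds`` parsed from the m:s text."""
    df = _read("table2.csv", TABLE2_SHA256)
    if set(df["pt"]) != set(INCOMPLETE_HIIT_IDS):
        raise RuntimeError("dose table ids must be {16, 17, 20, 21, 24}")
    df["dose_seconds"] = df["dose"].map(parse_dose)
    return df
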