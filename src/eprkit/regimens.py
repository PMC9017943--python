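"""Regimen-episode segmentation of a patient's administration history.

A regimen episode is a maximal run of administration days sharing the same
drug combination (set of INNs given that day) without a treatment-free gap
longer than ``gap_days``. Episodes are the unit used by truncation
detection (rule R1) and by the stage/line inference rules: stage is filled
within an episode, and treatment-line numbering increments at episode
boundaries.

Regimen identity is exact INN-set equality; records whose INN could not be
resolved contribute their raw name so that unknown drugs still separate
episodes deterministically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_GAP_DAYS = 60


def segment_regimens(patient_records: pd.DataFrame, gap_days: int = DEFAULT_GAP_DAYS) -> np.ndarray:
    """Assign a 0-based episode id to each record of one patient.

    ``patient_records`` must be in canonical order. All records of one
    administration day share an episode; a new episode starts when the
    day's INN set differs from the previous day's, or when more than
    ``gap_days`` days elapsed since the previous administration day.
    """
    n = len(patient_records)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    dates = patient_records["administration_date"].to_numpy()
    inns = patient_records["drug_inn"].astype("object").to_numpy()
    raws = patient_records["drug_raw"].astype("object").to_numpy()

    day_sets: list[tuple] = []  # (date, frozenset of drug tokens)
    day_of_record = np.empty(n, dtype=np.int64)
    cur_date = None
    cur_set: set = set()
    for i in range(n):
        d = dates[i]
        token = inns[i] if not pd.isna(inns[i]) else f"?{raws[i]}"
        if cur_date is None or d != cur_date:
            if cur_date is not None:
                day_sets.append((cur_date, frozenset(cur_set)))
            cur_date, cur_set = d, set()
        cur_set.add(token)
        day_of_record[i] = len(day_sets)
    day_sets.append((cur_date, frozenset(cur_set)))

    episode_of_day = np.empty(len(day_sets), dtype=np.int64)
    episode = 0
    for j, (d, s) in enumerate(day_sets):
        if j > 0:
            prev_d, prev_s = day_sets[j - 1]
            gap = (d - prev_d) / np.timedelta64(1, "D")
            if s != prev_s or gap > gap_days:
                episode += 1
        episode_of_day[j] = episode
    return episode_of_day[day_of_record]
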