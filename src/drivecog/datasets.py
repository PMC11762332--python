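"""Packaged reference tables.

``pilot_roster`` is the 21-subject pilot cohort (13 cognitively healthy,
8 MCI) with age, sex and expert-assigned status.  ``pilot_fold_map`` is
the published subject-to-fold assignment used in the pilot's 4-fold
inter-subject cross-validation; it is stored verbatim for regression use.
Note the fold map references subject numbers up to 22 for a 21-subject
roster and its status groupings do not fully agree with the roster — the
anomalies are preserved as published rather than silently repaired.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["pilot_roster", "pilot_fold_map"]


def _data_path(name: str):
    return resources.files("drivecog.data").joinpath(name)


def pilot_roster() -> pd.DataFrame:
    """The pilot cohort roster: ``subject_id, age, sex, status``."""
    with resources.as_file(_data_path("pilot_roster.csv")) as p:
        return pd.read_csv(p)


def pilot_fold_map() -> pd.DataFrame:
    """Published fold assignment, one row per (fold, role, group).

    ``subject_numbers`` is expanded to a list of ints per row.
    """
    with resources.as_file(_data_path("pilot_fold_map.csv")) as p:
        df = pd.read_csv(p)
    df["subject_numbers"] = df["subject_numbers"].map(
        lambda s: [int(x) for x in str(s).split()]
    )
    return df
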