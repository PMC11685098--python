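"""Within-person / between-person centring of trial-level predictors.

Trial-level predictors (curiosity, interest, path/head roaming entropy) are
split into a within-person deviation (the trial value minus the participant's
own mean, suffix ``_w``) and a between-person component (the participant mean
centred at the grand mean of participant means, suffix ``_m``).  Duration is
grand-centred (``duration_c``) and trait subscales centred across
participants (suffix ``_c``).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

WITHIN_PREDICTORS = ["curiosity", "interest", "path_re", "head_re"]
TRAIT_COLUMNS = ["trait_JE", "trait_DS", "trait_ST", "trait_TS"]

__all__ = ["build_design", "WITHIN_PREDICTORS", "TRAIT_COLUMNS"]


def build_design(
    trials: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    composites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the centred one-row-per-trial analysis table.

    Parameters
    ----------
    trials : frame with participant_id, room_id, curiosity, interest,
        duration_s, path_re, head_re (one row per trial).
    traits : optional per-participant trait subscales.
    composites : optional per participant x room composite sketch scores
        (columns participant_id, room_id, composite).

    Incomplete rows are dropped listwise with a logged count; participants
    contributing a single trial are flagged (their within-person deviations
    are degenerate zeros).
    """
    df = trials.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["room_id"] = df["room_id"].astype(str)

    if composites is not None:
        comp = composites.copy()
        comp["participant_id"] = comp["participant_id"].astype(str)
        comp["room_id"] = comp["room_id"].astype(str)
        df = df.merge(comp[["participant_id", "room_id", "composite"]],
                      on=["participant_id", "room_id"], how="left")
    if traits is not None:
        tr = traits.copy()
        tr["participant_id"] = tr["participant_id"].astype(str)
        df = df.merge(tr, on="participant_id", how="left")

    required = ["curiosity", "interest", "duration_s", "path_re", "head_re"]
    n_before = len(df)
    df = df.dropna(subset=required).reset_index(drop=True)
    n_dropped = n_before - len(df)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} incomplete trials (listwise exclusion)", stacklevel=2)
    if df.empty:
        raise ValueError("no complete trials left after listwise exclusion")

    singles = df.groupby("participant_id").size()
    singles = singles[singles < 2].index.tolist()
    if singles:
        warnings.warn(
            f"participants with a single trial have degenerate within-person "
            f"deviations: {singles}",
            stacklevel=2,
        )

    for col in WITHIN_PREDICTORS:
        pmean = df.groupby("participant_id")[col].transform("mean")
        df[f"{col}_w"] = df[col] - pmean
        person_means = df.groupby("participant_id")[col].mean()
        grand = person_means.mean()
        df[f"{col}_m"] = df["participant_id"].map(person_means) - grand

    df["duration_c"] = df["duration_s"] - df["duration_s"].mean()

    if traits is not None:
        per_person = df.drop_duplicates("participant_id")
        for col in TRAIT_COLUMNS:
            if col in df.columns:
                df[f"{col}_c"] = df[col] - per_person[col].mean()

    df.attrs["n_dropped"] = n_dropped
    df.attrs["single_trial_participants"] = singles
    return df
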