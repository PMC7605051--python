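"""CSV/JSON interchange for response tables and fit artifacts.

The response table is the pipeline's central format: one row per trial with
columns subject_id, experiment, trial_index, disparity_arcmin, condition,
response, coupled_correct.  Positive disparity means convex/near throughout.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .observers import RESPONSE_COLUMNS

__all__ = ["read_responses", "write_responses", "write_json", "read_json"]

logger = logging.getLogger("stereocoupling")

REQUIRED_COLUMNS = RESPONSE_COLUMNS


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read and validate a response CSV.

    Raises a format error naming any missing column; a row whose disparity is
    not numeric raises an error citing the (1-based, data) row number.  Unknown
    columns are preserved but ignored downstream.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"response file {path} is missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        logger.warning("response file %s contains a header but no trials", path)
        return df
    disparity = pd.to_numeric(df["disparity_arcmin"], errors="coerce")
    bad = disparity.isna() & df["disparity_arcmin"].notna() | df["disparity_arcmin"].isna()
    if bad.any():
        row = int(np.flatnonzero(bad.values)[0]) + 1
        raise ValueError(f"non-numeric disparity_arcmin on row {row} of {path}")
    df["disparity_arcmin"] = disparity.astype(float)
    df["trial_index"] = df["trial_index"].astype(int)
    bad_exp = ~df["experiment"].isin(["baseline", "coupling"])
    if bad_exp.any():
        row = int(np.flatnonzero(bad_exp.values)[0]) + 1
        raise ValueError(f"unknown experiment label on row {row} of {path}")
    # coupled_correct round-trips through CSV as True/False strings or blanks
    df["coupled_correct"] = df["coupled_correct"].map(
        {True: True, False: False, "True": True, "False": False}
    ).astype(object)
    df.loc[df["experiment"] == "baseline", "coupled_correct"] = None
    return df


def write_responses(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
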