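"""CSV ingestion and the validated in-memory data table.

A ``DataTable`` couples a covariate frame (continuous and/or categorical
columns, missing values allowed) with an outcome: a scalar column or a
(time, event) pair for survival data.  Column types are declared in the
config or inferred (numeric -> continuous, anything else -> categorical);
rows with a missing outcome are dropped and both events are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .targets import SurvivalOutcome

logger = logging.getLogger("primbox")

__all__ = ["DataTable", "read_csv_table"]


@dataclass
class DataTable:
    X: pd.DataFrame
    y: Union[np.ndarray, SurvivalOutcome]
    column_types: dict = field(default_factory=dict)

    @property
    def is_survival(self) -> bool:
        return isinstance(self.y, SurvivalOutcome)


def read_csv_table(path, outcome: Optional[str] = None,
                   time_col: Optional[str] = None,
                   event_col: Optional[str] = None,
                   column_types: Optional[dict] = None,
                   na_values=("", "NA", "NaN")) -> DataTable:
    """Read a headered CSV into a validated DataTable.

    Exactly one of ``outcome`` (scalar outcome column) or the
    ``time_col``/``event_col`` pair (survival outcome) must be given.
    Empty strings and the configured sentinels become missing values.
    """
    survival = time_col is not None or event_col is not None
    if survival and (time_col is None or event_col is None):
        raise ValueError("survival data needs both time_col and event_col")
    if survival == (outcome is not None):
        raise ValueError("name either an outcome column or a time/event pair")

    df = pd.read_csv(path, na_values=list(na_values), keep_default_na=True,
                     skipinitialspace=True)
    outcome_cols = [time_col, event_col] if survival else [outcome]
    for col in outcome_cols:
        if col not in df.columns:
            raise ValueError(f"outcome column {col!r} not found in {path}")

    n_before = len(df)
    df = df.dropna(subset=outcome_cols).reset_index(drop=True)
    dropped = n_before - len(df)
    if dropped:
        logger.warning("dropped %d rows with missing outcome", dropped)
    if len(df) == 0:
        raise ValueError("no rows with a complete outcome")

    X = df.drop(columns=outcome_cols)
    column_types = dict(column_types or {})
    for name in X.columns:
        if name not in column_types:
            inferred = ("continuous"
                        if pd.api.types.is_numeric_dtype(X[name])
                        else "categorical")
            column_types[name] = inferred
            logger.info("inferred column %r as %s", name, inferred)
        elif column_types[name] == "continuous":
            try:
                X[name] = pd.to_numeric(X[name])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"column {name!r} declared continuous but holds "
                    f"non-numeric values") from exc
        if X[name].isna().all():
            logger.warning("column %r contains only missing values", name)

    if survival:
        y = SurvivalOutcome(pd.to_numeric(df[time_col]).to_numpy(),
                            pd.to_numeric(df[event_col]).to_numpy())
    else:
        y = pd.to_numeric(df[outcome]).to_numpy(dtype=float)
    return DataTable(X=X, y=y, column_types=column_types)
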