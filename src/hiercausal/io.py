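"""Trial tables: CSV schema, validation, and the synthetic observer.

The trial CSV schema is::

    observer,session,condition,center_dir_deg,surround_moving,
    n_surround_patches,report_deg

with an Experiment-2 variant that adds ``inner_offset_deg,report_target``.
Angles are degrees; reports must lie in [0, 360).  Malformed rows are
collected into an error report rather than silently dropped.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .experiments import StimulusCondition, exp1_condition, exp2_condition
from .model import ModelParams

EXP1_COLUMNS = [
    "observer",
    "session",
    "condition",
    "center_dir_deg",
    "surround_moving",
    "n_surround_patches",
    "report_deg",
]
EXP2_EXTRA_COLUMNS = ["inner_offset_deg", "report_target"]


class SchemaError(ValueError):
    """Raised when a trial file is missing required columns."""


@dataclass
class TrialTable:
    """Per-trial stimulus condition and reported direction.

    ``df`` holds one row per trial in the CSV schema; ``conditions`` maps
    condition labels to :class:`StimulusCondition` objects; ``errors``
    lists rejected input rows as (row_index, message) pairs.
    """

    df: pd.DataFrame
    conditions: dict[str, StimulusCondition] = field(default_factory=dict)
    errors: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_trials(self) -> int:
        return len(self.df)

    def condition_of(self, label: str) -> StimulusCondition:
        return self.conditions[label]

    def reports_for(self, label: str) -> np.ndarray:
        return self.df.loc[self.df["condition"] == label, "report_deg"].to_numpy()

    def data_hash(self) -> str:
        cols = [c for c in self.df.columns]
        payload = self.df[cols].round(9).to_csv(index=False).encode()
        return hashlib.sha1(payload).hexdigest()

    @classmethod
    def from_frame(cls, df: pd.DataFrame, errors=None) -> "TrialTable":
        df = df.reset_index(drop=True)
        conditions: dict[str, StimulusCondition] = {}
        is_exp2 = "inner_offset_deg" in df.columns
        for row in df.itertuples():
            if row.condition in conditions:
                continue
            if is_exp2:
                conditions[row.condition] = exp2_condition(
                    float(row.inner_offset_deg), str(row.report_target)
                )
            else:
                conditions[row.condition] = exp1_condition(
                    float(row.center_dir_deg),
                    bool(row.surround_moving),
                    int(row.n_surround_patches),
                )
        return cls(df=df, conditions=conditions, errors=list(errors or []))


def _coerce_bool(x):
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {x!r}")


def read_trials(path) -> TrialTable:
    """Read and validate a trial CSV.

    Missing columns raise :class:`SchemaError` listing every absence;
    malformed rows (out-of-range reports, unparsable fields) are removed
    from the table and collected in ``TrialTable.errors``.
    """
    raw = pd.read_csv(path)
    missing = [c for c in EXP1_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    rows = []
    errors: list[tuple[int, str]] = []
    is_exp2 = all(c in raw.columns for c in EXP2_EXTRA_COLUMNS)
    for i, row in raw.iterrows():
        try:
            rec = {
                "observer": str(row["observer"]),
                "session": str(row["session"]),
                "condition": str(row["condition"]),
                "center_dir_deg": float(row["center_dir_deg"]),
                "surround_moving": _coerce_bool(row["surround_moving"]),
                "n_surround_patches": int(row["n_surround_patches"]),
                "report_deg": float(row["report_deg"]),
            }
            if not 0.0 <= rec["report_deg"] < 360.0:
                raise ValueError(
                    f"report_deg {rec['report_deg']} outside [0, 360)"
                )
            if abs(rec["center_dir_deg"]) >= 90.0:
                raise ValueError("center direction outside (-90, 90)")
            if is_exp2:
                rec["inner_offset_deg"] = float(row["inner_offset_deg"])
                rec["report_target"] = str(row["report_target"])
            rows.append(rec)
        except (ValueError, TypeError) as exc:
            errors.append((int(i), str(exc)))
    cols = EXP1_COLUMNS + (EXP2_EXTRA_COLUMNS if is_exp2 else [])
    df = pd.DataFrame(rows, columns=cols)
    return TrialTable.from_frame(df, errors=errors)


def write_trials(trials: TrialTable, path) -> None:
    """Write a trial table with the canonical column order."""
    cols = EXP1_COLUMNS + [
        c for c in EXP2_EXTRA_COLUMNS if c in trials.df.columns
    ]
    if len(trials.df) == 0:
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return
    trials.df[cols].to_csv(path, index=False)


def simulate_trials(
    grid: list[StimulusCondition],
    params: ModelParams,
    strategy: str,
    trials_per_condition: int,
    rng: np.random.Generator | int | None = None,
    observer: str = "synthetic",
    session: str = "1",
) -> TrialTable:
    """Synthetic observer: simulate a full trial table over a condition grid."""
    from .readout import simulate_responses

    rng = np.random.default_rng(rng)
    rows = []
    conditions: dict[str, StimulusCondition] = {}
    for cond in grid:
        conditions[cond.label] = cond
        reports = simulate_responses(
            cond, params, strategy, trials_per_condition, rng=rng
        )
        meta = cond.meta
        for r in reports:
            rows.append(
                {
                    "observer": observer,
                    "session": session,
                    "condition": cond.label,
                    "center_dir_deg": meta.get("center_dir_deg", 0.0),
                    "surround_moving": meta.get("surround_moving", True),
                    "n_surround_patches": meta.get("n_surround_patches", 1),
                    "report_deg": float(r),
                    **(
                        {
                            "inner_offset_deg": meta["inner_offset_deg"],
                            "report_target": meta["report_target"],
                        }
                        if "inner_offset_deg" in meta
                        else {}
                    ),
                }
            )
    df = pd.DataFrame(rows)
    return TrialTable(df=df, conditions=conditions)
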