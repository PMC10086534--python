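"""Run configuration, provenance, and tabular result aggregation.

Results flow through a long-format table (animal, tissue, field, metric,
value, units).  Aggregation is hierarchical — field means roll up to
tissue means, tissue means to animal means, animal means to group means
— matching the per-tissue-then-per-animal averaging order used for the
imaging readouts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .errors import ValidationError

__all__ = ["RunConfig", "ResultTable", "aggregate", "AGGREGATION_LEVELS"]

RESULT_COLUMNS = ("animal", "tissue", "field", "metric", "value", "units")

AGGREGATION_LEVELS = {
    "field_to_tissue": ("animal", "tissue", "metric", "units"),
    "tissue_to_animal": ("animal", "metric", "units"),
    "animal_to_group": ("metric", "units"),
}


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters of one CLI/pipeline run."""

    command: str
    params: Mapping[str, Any] = field(default_factory=dict)
    inputs: tuple[str, ...] = ()
    output_dir: str = "."
    seed: int | None = None
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "command": self.command,
                "params": dict(self.params),
                "inputs": list(self.inputs),
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def provenance(self) -> dict[str, Any]:
        return {
            "package_version": __version__,
            "config_hash": self.config_hash(),
            "command": self.command,
            "seed": self.seed,
        }


class ResultTable:
    """Long-format result rows with one row per (animal, tissue, field, metric)."""

    def __init__(self, df: pd.DataFrame | None = None) -> None:
        if df is None:
            df = pd.DataFrame(columns=list(RESULT_COLUMNS))
        missing = set(RESULT_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"result table missing columns: {sorted(missing)}")
        if len(df) and (df["units"].astype(str).str.len() == 0).any():
            raise ValidationError("every row needs nonempty units")
        key_cols = ["animal", "tissue", "field", "metric"]
        if len(df) and df.duplicated(subset=key_cols).any():
            raise ValidationError("duplicate (animal, tissue, field, metric) rows")
        self.df = df.reset_index(drop=True)[list(RESULT_COLUMNS)]

    def add_row(self, animal: str, tissue: str, field_id: str, metric: str, value: float, units: str) -> None:
        row = pd.DataFrame(
            [
                {
                    "animal": animal,
                    "tissue": tissue,
                    "field": field_id,
                    "metric": metric,
                    "value": value,
                    "units": units,
                }
            ]
        )
        frames = [row] if self.df.empty else [self.df, row]
        self.df = ResultTable(pd.concat(frames, ignore_index=True)).df

    def to_csv(self, path: str | Path, provenance: Mapping[str, Any] | None = None) -> None:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            if provenance:
                fh.write("# " + json.dumps(dict(provenance), sort_keys=True) + "\n")
            self.df.to_csv(fh, index=False)

    def __len__(self) -> int:
        return len(self.df)


def aggregate(table: ResultTable, level: str) -> pd.DataFrame:
    """Arithmetic means at the next hierarchy level, with group sizes.

    ``level`` is one of ``field_to_tissue``, ``tissue_to_animal``,
    ``animal_to_group``.  Rows with missing values are excluded and the
    exclusion count is reported in the ``n_missing`` column.
    """
    if level not in AGGREGATION_LEVELS:
        raise ValidationError(
            f"level must be one of {sorted(AGGREGATION_LEVELS)}, got {level!r}"
        )
    keys = list(AGGREGATION_LEVELS[level])
    df = table.df
    if len(df) == 0:
        raise ValidationError("cannot aggregate an empty table")
    grouped = df.groupby(keys, sort=True, dropna=False)
    out = grouped.agg(
        value=("value", "mean"),
        n=("value", lambda s: int(s.notna().sum())),
        n_missing=("value", lambda s: int(s.isna().sum())),
    ).reset_index()
    if (out["n"] == 0).any():
        raise ValidationError("a group contains no non-missing values")
    return out


def aggregate_hierarchical(table: ResultTable) -> pd.DataFrame:
    """Full field -> tissue -> animal -> group roll-up (hierarchical means)."""
    tissue = aggregate(table, "field_to_tissue")
    t_table = ResultTable(
        tissue.assign(field="__tissue_mean__")[list(RESULT_COLUMNS)]
    )
    animal = aggregate(t_table, "tissue_to_animal")
    a_table = ResultTable(
        animal.assign(tissue="__animal_mean__", field="__animal_mean__")[list(RESULT_COLUMNS)]
    )
    return aggregate(a_table, "animal_to_group")
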