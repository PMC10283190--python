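"""The common data container: one row per child, nested in communities and states.

Columns: ``y`` (count outcome, 0..max_count), one column per categorical
covariate, ``community_id``, ``state_id``, ``year`` and a sampling
``weight``.  Every community belongs to exactly one state.  The container
round-trips to CSV with a JSON sidecar carrying provenance (generator
design, true parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("y", "community_id", "state_id", "year", "weight")


class DataValidationError(ValueError):
    """Raised when a dataset violates the schema; carries every violation."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid dataset:\n" + "\n".join(self.errors))


def validate_frame(df: pd.DataFrame, max_count: int = 9) -> list[str]:
    """Return a list of schema violations (empty if the frame is valid).

    Checks are exhaustive rather than fail-fast so a caller can report
    every problem with its row number at once.
    """
    errors: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        errors.append(f"missing required columns: {missing}")
        return errors
    y = pd.to_numeric(df["y"], errors="coerce")
    bad = df.index[y.isna() | (y < 0) | (y != np.floor(y))].tolist()
    for i in bad[:20]:
        errors.append(f"row {i}: y={df['y'].iloc[i]!r} is not a non-negative integer")
    high = df.index[y > max_count].tolist()
    for i in high[:20]:
        errors.append(f"row {i}: y={df['y'].iloc[i]!r} exceeds max_count={max_count}")
    w = pd.to_numeric(df["weight"], errors="coerce")
    bad_w = df.index[w.isna() | (w <= 0)].tolist()
    for i in bad_w[:20]:
        errors.append(f"row {i}: weight={df['weight'].iloc[i]!r} is not strictly positive")
    # cross-level integrity: a community must sit inside a single state
    n_states = df.groupby("community_id")["state_id"].nunique()
    for cid in n_states.index[n_states > 1].tolist():
        errors.append(f"community {cid!r} is mapped to {n_states[cid]} different states")
    return errors


@dataclass
class HierarchicalCountData:
    """A validated long-format hierarchical count dataset."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        errors = validate_frame(self.df, max_count=self.meta.get("max_count", 9))
        if errors:
            raise DataValidationError(errors)
        self.df = self.df.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("y", "community_id", "state_id", "weight")]

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy(dtype=np.int64)

    @property
    def weights(self) -> np.ndarray:
        return self.df["weight"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV plus a ``<stem>.meta.json`` sidecar."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        sidecar = path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps(_jsonable(self.meta), indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "HierarchicalCountData":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        # covariates round-trip as plain strings; category order is
        # restored from the sidecar when present
        for name, levels in meta.get("covariate_levels", {}).items():
            if name in df.columns:
                df[name] = pd.Categorical(df[name].astype(str), categories=levels)
        return cls(df=df, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return {f: _jsonable(getattr(obj, f)) for f in obj.__dataclass_fields__}
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str)):
        return obj.value
    return obj
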