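"""Dataset readers and report writers shared by the CLI and tests."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import Dataset

__all__ = ["load_dataset_csv", "save_dataset_csv", "save_report", "RunConfig"]

SCHEMA_VERSION = 1


@dataclasses.dataclass
class RunConfig:
    """Round-trippable run configuration (JSON or YAML by extension).

    Holds command parameters as a flat mapping; every stochastic run
    records its seed here. CLI flags take precedence over config values.
    """

    params: dict = dataclasses.field(default_factory=dict)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml
            path.write_text(yaml.safe_dump(self.params, sort_keys=True))
        else:
            path.write_text(json.dumps(self.params, sort_keys=True, indent=1))

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            return cls(params=yaml.safe_load(text) or {})
        return cls(params=json.loads(text))


def load_dataset_csv(path) -> Dataset:
    """Read a dataset CSV: numeric feature columns plus a ``label`` column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such dataset file: {path}")
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing required 'label' column")
    features = [c for c in df.columns if c != "label"]
    if not features:
        raise ValueError(f"{path}: no feature columns")
    X = df[features].to_numpy()
    if not np.issubdtype(X.dtype, np.number):
        bad = [c for c in features
               if not np.issubdtype(df[c].dtype, np.number)]
        raise ValueError(f"{path}: non-numeric feature columns {bad}")
    if df[features].isna().any().any():
        raise ValueError(f"{path}: missing values in feature columns")
    y = df["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError(f"{path}: fewer than 2 classes in 'label'")
    return Dataset(X=X.astype(float), y=y, feature_names=features)


def save_dataset_csv(ds: Dataset, path) -> None:
    ds.to_csv(path)


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, frozenset):
        return sorted(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def save_report(result, path) -> None:
    """Write a result object as schema-versioned JSON (+ CSV if tabular).

    Objects exposing ``to_json``/``to_csv`` use their own serialization;
    anything else is converted field-by-field.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if hasattr(result, "to_json"):
        payload = json.loads(result.to_json())
    else:
        payload = _to_jsonable(result)
    if isinstance(payload, dict):
        payload.setdefault("schema_version", SCHEMA_VERSION)
    path.write_text(json.dumps(payload, indent=1))
    if hasattr(result, "to_csv") and callable(getattr(result, "to_csv")):
        try:
            csv_text = result.to_csv()
        except TypeError:
            csv_text = None
        if isinstance(csv_text, str):
            path.with_suffix(".csv").write_text(csv_text)
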