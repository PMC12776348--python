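"""Reading and writing datasets, models, and derived tables.

Dataset CSV dialect: comma-separated UTF-8 with a required header row of
event labels and "." decimals. An optional leading sample-id column is
auto-detected by non-binary content (override with ``id_column``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .histories import TrajectoryTree, most_likely_order
from .model import Dataset, EventCatalog, MutualHazardNetwork, ValidationError
from .simulate import History

__all__ = [
    "read_dataset",
    "write_dataset",
    "dataset_from_dataframe",
    "dataset_to_dataframe",
    "write_histories",
    "write_cv_scores",
    "reconstruction_table",
]


def _is_binary(col: pd.Series) -> bool:
    return col.astype(str).str.strip().isin({"0", "1"}).all()


def dataset_from_dataframe(df: pd.DataFrame, id_column: bool | None = None) -> Dataset:
    """Build a Dataset from a DataFrame of 0/1 entries.

    ``id_column``: True/False forces the first column to be (or not be)
    sample ids; None auto-detects by non-binary content.
    """
    if df.shape[1] == 0:
        raise ValidationError("dataset has no columns")
    if id_column is None:
        id_column = df.shape[1] > 1 and not _is_binary(df.iloc[:, 0])
    ids = None
    if id_column:
        ids = tuple(str(v) for v in df.iloc[:, 0])
        df = df.iloc[:, 1:]
    catalog = EventCatalog(df.columns)
    cells = df.astype(str).apply(lambda col: col.str.strip())
    ok = cells.isin(["0", "1"]).to_numpy()
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise ValidationError(
            f"non-binary cell in row {r}, column {catalog.names[c]!r}: "
            f"{df.iloc[r, c]!r}"
        )
    values = (cells == "1").to_numpy().astype(np.int8)
    return Dataset(values, catalog, ids)


def dataset_to_dataframe(data: Dataset) -> pd.DataFrame:
    df = pd.DataFrame(data.genotypes, columns=list(data.catalog.names))
    if data.sample_ids is not None:
        df.insert(0, "sample_id", list(data.sample_ids))
    return df


def read_dataset(path: str | Path, id_column: bool | None = None) -> Dataset:
    """Read a cross-sectional binary event matrix from CSV."""
    try:
        df = pd.read_csv(path, dtype=str, header=0, skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed CSV {path}: {exc}") from exc
    if df.isna().any().any():
        r = int(df.isna().any(axis=1).idxmax())
        raise ValidationError(f"missing value in row {r} of {path} (ragged CSV?)")
    return dataset_from_dataframe(df, id_column)


def write_dataset(data: Dataset, path: str | Path) -> None:
    dataset_to_dataframe(data).to_csv(path, index=False)


def write_histories(histories: list[History], data: Dataset, path: str | Path) -> None:
    """One JSON record per sample: {id, events: [{label, time}], observed_at}."""
    ids = data.sample_ids or tuple(str(i) for i in range(len(data)))
    records = [h.to_json_dict(i) for h, i in zip(histories, ids)]
    Path(path).write_text(json.dumps(records, indent=1) + "\n")


def write_cv_scores(cv, path: str | Path) -> None:
    """Fold-score table: one row per penalty strength."""
    df = pd.DataFrame(
        cv.fold_scores,
        columns=[f"fold_{f}" for f in range(cv.fold_scores.shape[1])],
    )
    df.insert(0, "strength", cv.grid)
    df["mean_score"] = cv.mean_scores
    df["selected"] = cv.grid == cv.selected_strength
    df.to_csv(path, index=False)


def reconstruction_table(model: MutualHazardNetwork, data: Dataset) -> pd.DataFrame:
    """Per-sample most likely event ordering and its path probability."""
    ids = data.sample_ids or tuple(str(i) for i in range(len(data)))
    cache: dict[tuple, tuple[str, float]] = {}
    rows = []
    for sid, g in zip(ids, data.genotypes):
        key = tuple(g)
        if key not in cache:
            rec = most_likely_order(model, g)
            cache[key] = (">".join(rec.labels(model)), rec.probability)
        order, prob = cache[key]
        rows.append({"sample_id": sid, "ordering": order, "probability": prob})
    return pd.DataFrame(rows)
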