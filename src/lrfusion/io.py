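"""CSV readers/writers for datasets and prediction tables."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .datasets import LabeledDataset
from .exceptions import InvalidConfigError
from .metrics import LRResult

__all__ = ["read_dataset", "write_dataset", "write_predictions"]

logger = logging.getLogger(__name__)

# full repeatable precision for all numeric CSV output
_FLOAT_FORMAT = "%.17g"


def read_dataset(
    path,
    class_column: str = "class",
    positive_label: str = "positive",
    strict: bool = True,
) -> LabeledDataset:
    """Read a CSV with feature columns and one binary class column.

    In strict mode rows with missing values are an error (reported with row
    numbers); in lenient mode they are dropped with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[0] < 1:
        raise InvalidConfigError(f"{path} contains no data rows")
    if class_column not in df.columns:
        raise InvalidConfigError(
            f"class column {class_column!r} not found in {list(df.columns)}"
        )
    classes = df[class_column].astype(str)
    values = sorted(classes.unique())
    if len(values) > 2:
        raise InvalidConfigError(
            f"class column must be binary; found values {values}"
        )
    if positive_label not in values:
        raise InvalidConfigError(
            f"positive label {positive_label!r} absent from class column {values}"
        )
    negative_label = next(
        (v for v in values if v != positive_label), f"not-{positive_label}"
    )

    feats = df.drop(columns=[class_column]).apply(pd.to_numeric, errors="coerce")
    bad = feats.isna().any(axis=1)
    if bad.any():
        rows = (bad[bad].index + 2).tolist()  # +2: header + 1-based
        if strict:
            raise InvalidConfigError(
                f"missing/non-numeric values in file rows {rows[:20]}"
            )
        logger.warning("dropping %d rows with missing values", int(bad.sum()))
        feats = feats[~bad]
        classes = classes[~bad]
    return LabeledDataset(
        features=feats.to_numpy(dtype=float),
        labels=(classes == positive_label).to_numpy().astype(int),
        variable_names=tuple(feats.columns),
        positive_label=positive_label,
        negative_label=negative_label,
    )


def write_dataset(data: LabeledDataset, path) -> None:
    df = pd.DataFrame(data.features, columns=list(data.variable_names))
    df["class"] = data.label_strings()
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def write_predictions(results: Sequence[LRResult], path) -> None:
    """Prediction table: row_id, posterior, LR, log10 LR, class, verbal."""
    if not results:
        raise InvalidConfigError("no prediction results to write")
    df = pd.DataFrame(
        {
            "row_id": range(len(results)),
            "posterior_p": [r.posterior_p for r in results],
            "lr": [r.lr for r in results],
            "log10_lr": [r.log10_lr for r in results],
            "predicted_class": [r.predicted_class for r in results],
            "verbal": [r.verbal for r in results],
            "saturated": [r.saturated for r in results],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
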