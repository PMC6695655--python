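"""CSV and config readers/writers.

CSV is the single tabular interchange format (UTF-8, "." decimal
separator).  Undefined metric values are serialized as the tokens ``+inf``,
``-inf`` and ``NA``; every matrix file carries a one-line ``#`` comment
legend.  Floats are written with ``repr`` so numeric round-trips are exact.
Configs are plain ``key = value`` text files.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import ScoredPredictions
from .synthetic import DatasetSpec, LabelledDataset

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_config",
    "read_config",
    "write_dataset",
    "read_dataset",
    "read_predictions",
]

_LEGEND = "# tokens: +inf / -inf = undefined-denominator infinities, NA = undefined value\n"


def _format_cell(v) -> str:
    if isinstance(v, (float, np.floating)):
        if math.isnan(v):
            return "NA"
        if math.isinf(v):
            return "+inf" if v > 0 else "-inf"
        return repr(float(v))
    return str(v)


def write_matrix(frame: pd.DataFrame, path, index_label: str = "object") -> None:
    """Write a labelled numeric matrix with the token legend."""
    path = Path(path)
    out = frame.map(_format_cell)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_LEGEND)
        out.to_csv(fh, index_label=index_label)


def _parse_cell(v):
    if isinstance(v, str):
        s = v.strip()
        if s == "NA" or s == "":
            return math.nan
        if s == "+inf" or s == "inf":
            return math.inf
        if s == "-inf":
            return -math.inf
        return float(s)
    return float(v)


def read_matrix(path) -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix` (values to 1e-15)."""
    path = Path(path)
    frame = pd.read_csv(path, comment="#", index_col=0, dtype=str, keep_default_na=False)
    for col in frame.columns:
        try:
            frame[col] = [_parse_cell(v) for v in frame[col]]
        except ValueError as exc:
            bad = next(
                (i, v) for i, v in enumerate(frame[col]) if not _is_numeric_token(v)
            )
            raise ValueError(
                f"{path}: non-numeric cell at row {bad[0] + 1}, column {col!r}: {bad[1]!r}"
            ) from exc
    return frame


def _is_numeric_token(v) -> bool:
    try:
        _parse_cell(v)
        return True
    except ValueError:
        return False


def write_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in cfg.items():
            fh.write(f"{key} = {value}\n")


def read_config(path) -> dict[str, str]:
    cfg: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        cfg[key.strip()] = value.strip()
    return cfg


def write_dataset(dataset: LabelledDataset, directory, spec: DatasetSpec | None = None) -> None:
    """Write train.csv / test.csv (last column ``label``) plus a sidecar config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for split, X, y in (
        ("train", dataset.X_train, dataset.y_train),
        ("test", dataset.X_test, dataset.y_test),
    ):
        frame = pd.DataFrame(X, columns=dataset.feature_names)
        frame["label"] = y
        frame.to_csv(directory / f"{split}.csv", index=False)
    if spec is not None:
        write_config(spec.to_config(), directory / "dataset.cfg")


def read_dataset(directory) -> LabelledDataset:
    directory = Path(directory)
    parts = {}
    for split in ("train", "test"):
        frame = pd.read_csv(directory / f"{split}.csv")
        if "label" not in frame.columns:
            raise ValueError(f"{directory / f'{split}.csv'}: missing 'label' column")
        parts[split] = (
            frame.drop(columns="label").to_numpy(dtype=float),
            frame["label"].to_numpy(dtype=int),
            [c for c in frame.columns if c != "label"],
        )
    return LabelledDataset(
        X_train=parts["train"][0], y_train=parts["train"][1],
        X_test=parts["test"][0], y_test=parts["test"][1],
        feature_names=parts["train"][2],
    )


def read_predictions(path) -> ScoredPredictions:
    """Read a predictions CSV: columns ``true_label`` and ``prob_1..prob_k``."""
    frame = pd.read_csv(path)
    if "true_label" not in frame.columns:
        raise ValueError(f"{path}: missing 'true_label' column")
    prob_cols = sorted(
        (c for c in frame.columns if c.startswith("prob_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if len(prob_cols) < 2:
        raise ValueError(f"{path}: need at least two prob_<class> columns")
    return ScoredPredictions(
        probabilities=frame[prob_cols].to_numpy(dtype=float),
        true_labels=frame["true_label"].to_numpy(dtype=int),
    )
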