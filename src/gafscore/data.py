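"""Response-matrix container and delimited-text I/O.

Responses are integer Likert categories 1..K (a 0..K-1 coding is detected
and shifted), stored as float with NaN for missing.  CSV files are UTF-8,
comma-separated, with a header row; missing cells are empty or "NA".
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["ResponseMatrix", "read_responses", "write_scores"]


@dataclasses.dataclass
class ResponseMatrix:
    """n x J integer category matrix with optional group labels.

    ``values`` is float with NaN marking missing responses; observed entries
    are integers in 1..K.
    """

    values: np.ndarray
    items: list
    group: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (respondents x items)")
        if v.shape[1] != len(self.items):
            raise ValueError("number of item labels must match columns")
        obs = v[np.isfinite(v)]
        if obs.size and (np.any(obs != np.round(obs)) or np.any(obs < 0)):
            raise ValueError("responses must be non-negative integers (or NaN)")
        # 0-based coding shim: shift 0..K-1 up to 1..K
        if obs.size and obs.min() == 0:
            v = v + 1.0
        self.values = v
        if self.group is not None:
            g = np.asarray(self.group)
            if g.shape[0] != v.shape[0]:
                raise ValueError("group labels must match number of rows")
            self.group = g

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def J(self) -> int:
        return self.values.shape[1]

    def complete_cases(self) -> "ResponseMatrix":
        keep = np.all(np.isfinite(self.values), axis=1)
        return ResponseMatrix(
            self.values[keep],
            list(self.items),
            None if self.group is None else self.group[keep],
        )

    def subset_items(self, labels) -> "ResponseMatrix":
        idx = [self.items.index(l) for l in labels]
        return ResponseMatrix(self.values[:, idx], list(labels), self.group)

    def to_frame(self, prefix: str = "tas") -> pd.DataFrame:
        cols = [
            f"{prefix}{l:02d}" if isinstance(l, (int, np.integer)) else str(l)
            for l in self.items
        ]
        df = pd.DataFrame(self.values, columns=cols)
        if self.group is not None:
            df["group"] = self.group
        return df


def read_responses(
    path,
    item_columns: list | None = None,
    group_column: str | None = None,
) -> ResponseMatrix:
    """Read a response CSV into a :class:`ResponseMatrix`.

    Item columns default to every column whose name starts with "tas" or
    "item" (label parsed from the trailing integer); otherwise pass
    ``item_columns`` explicitly.  Malformed rows raise with the offending
    line number.
    """
    df = pd.read_csv(path, na_values=["NA", ""])
    if item_columns is None:
        item_columns = [
            c for c in df.columns
            if c.lower().startswith(("tas", "item")) and c[-1].isdigit()
        ]
        if not item_columns:
            item_columns = [c for c in df.columns if c != group_column]
    labels = []
    for c in item_columns:
        digits = "".join(ch for ch in str(c) if ch.isdigit())
        labels.append(int(digits) if digits else c)
    vals = df[item_columns].to_numpy(dtype=float)
    bad = np.isfinite(vals) & (vals != np.round(vals))
    if bad.any():
        row = int(np.argwhere(bad)[0][0])
        raise ValueError(
            f"{path}: non-integer response on data line {row + 2}"
        )
    group = None
    if group_column is not None:
        if group_column not in df.columns:
            raise KeyError(f"{path}: no column {group_column!r}")
        group = df[group_column].to_numpy()
    return ResponseMatrix(vals, labels, group)


def write_scores(df: pd.DataFrame, path) -> None:
    """Write a score table as CSV."""
    df.to_csv(path, index=False)
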