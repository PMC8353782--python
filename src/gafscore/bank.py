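"""Item parameter containers and the published GAFS-8 item bank.

The GAFS-8 is scored from eight TAS-20 items (1, 2, 6, 9, 11, 12, 13, 14)
under a logistic graded response model.  Items are parameterized in the
slope/intercept metric: the cumulative probability of responding in category
k+1 or above is ``logistic(a * theta + d_k)``, so more positive intercepts
mean the boundary is crossed at lower trait levels ("easier" items).
"""

from __future__ import annotations

import dataclasses
import io
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ItemParameters",
    "LatentDist",
    "LoadingRecord",
    "GAFS8_ITEMS",
    "gafs8_bank",
    "read_bank",
    "write_bank",
]


@dataclasses.dataclass(frozen=True)
class ItemParameters:
    """One polytomous item of a graded response model.

    Parameters
    ----------
    label : item identifier (for GAFS-8 items, the TAS-20 item number).
    a : discrimination slope on the logistic metric.
    d : ordered intercept vector of length K-1, strictly decreasing.
    """

    label: object
    a: float
    d: tuple[float, ...]

    def __post_init__(self):
        d = tuple(float(x) for x in self.d)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "a", float(self.a))
        if len(d) < 1:
            raise ValueError(f"item {self.label}: need at least one intercept (K >= 2)")
        if not np.isfinite(self.a):
            raise ValueError(f"item {self.label}: slope must be finite")
        if not all(np.isfinite(d)):
            raise ValueError(f"item {self.label}: intercepts must be finite")
        if not all(d[i] > d[i + 1] for i in range(len(d) - 1)):
            raise ValueError(
                f"item {self.label}: intercepts must be strictly decreasing, got {d}"
            )

    @property
    def K(self) -> int:
        """Number of response categories."""
        return len(self.d) + 1


@dataclasses.dataclass(frozen=True)
class LatentDist:
    """Normal latent trait distribution N(mu, sigma^2)."""

    mu: float = 0.0
    sigma: float = 1.0

    def __post_init__(self):
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclasses.dataclass(frozen=True)
class LoadingRecord:
    """Standardized factor loading and its communality (h2 = lambda^2)."""

    lam: float
    h2: float


#: TAS-20 item numbers that make up the GAFS-8, in scoring order.
GAFS8_ITEMS: tuple[int, ...] = (1, 2, 6, 9, 11, 12, 13, 14)

# Published GAFS-8 graded-response-model parameters: the multi-group
# calibration with the general-population group fixed at N(0, 1).
# Slopes and intercepts on the logistic metric.
_GAFS8_PARAMS = {
    1: (2.802, (3.092, -0.689, -2.740, -6.336)),
    2: (2.190, (3.478, 0.491, -0.931, -3.841)),
    6: (2.335, (2.090, -0.805, -2.413, -5.497)),
    9: (2.402, (3.137, 0.072, -1.434, -5.170)),
    11: (1.870, (2.745, -0.234, -1.505, -4.340)),
    12: (1.235, (1.739, -0.526, -1.636, -3.644)),
    13: (1.892, (2.054, -0.646, -2.231, -4.771)),
    14: (1.538, (1.285, -1.133, -2.201, -4.361)),
}


def gafs8_bank() -> list[ItemParameters]:
    """Return the published GAFS-8 item bank as a fresh list."""
    return [ItemParameters(label=i, a=a, d=d) for i, (a, d) in _GAFS8_PARAMS.items()]


def write_bank(bank: Sequence[ItemParameters], path) -> None:
    """Serialize a bank as delimited text with columns label, a, d1..dK-1."""
    kmax = max(it.K for it in bank)
    rows = []
    for it in bank:
        row = {"label": it.label, "a": it.a}
        for j, dj in enumerate(it.d, start=1):
            row[f"d{j}"] = dj
        rows.append(row)
    cols = ["label", "a"] + [f"d{j}" for j in range(1, kmax)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_bank(path) -> list[ItemParameters]:
    """Read a bank written by :func:`write_bank` (NaN-padded rows allowed)."""
    df = pd.read_csv(path)
    dcols = sorted((c for c in df.columns if c.startswith("d")), key=lambda c: int(c[1:]))
    bank = []
    for _, row in df.iterrows():
        d = [row[c] for c in dcols if np.isfinite(row[c])]
        bank.append(ItemParameters(label=row["label"], a=row["a"], d=tuple(d)))
    return bank
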