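"""Count-table types for paired-test verification-bias designs.

A verification-bias study cross-tabulates the outcomes of two tests over all
subjects, but only a subset of subjects is referred to the gold standard.  For
every joint test-outcome cell the observed data are

* ``s`` — verified subjects found diseased,
* ``r`` — verified subjects found non-diseased,
* ``u`` — subjects whose disease status was never verified,

with cell total ``m = s + r + u``.  Under the missing-at-random assumption
(verification depends only on the test outcomes) the posterior for the
cell-wise disease probabilities and the joint outcome probabilities is
conjugate: independent beta distributions per cell and a Dirichlet over the
cell totals.  This module holds the table types, prior handling (improper vs
uniform, zero-cell policy), JSON/CSV readers and writers, and Monte-Carlo
summary statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "TableValidationError",
    "ZeroCellError",
    "BinaryVerificationTable",
    "OrdinalVerificationTable",
    "PriorSpec",
    "Hyperparameters",
    "PosteriorSummary",
    "DrawMatrix",
    "hyperparameters",
    "summarize",
    "load_table",
    "write_table",
]


class TableValidationError(ValueError):
    """A count table violates its structural invariants."""


class ZeroCellError(ValueError):
    """A beta hyperparameter would be zero under the improper prior."""


def _as_count_array(x, shape, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.shape != shape:
        raise TableValidationError(f"{name} must have shape {shape}, got {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise TableValidationError(f"{name} must contain integers")
        arr = np.round(arr).astype(np.int64)
    arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise TableValidationError(f"{name} must be non-negative")
    return arr


@dataclass(frozen=True)
class BinaryVerificationTable:
    """Paired binary tests with partial verification.

    Counts are indexed ``[y1, y2]`` with 0 = negative, 1 = positive, so
    ``s[1, 0]`` counts verified diseased subjects positive on test 1 and
    negative on test 2.  The flat cell order used for Dirichlet vectors is
    (00, 01, 10, 11).
    """

    s: np.ndarray
    r: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        for name in ("s", "r", "u"):
            object.__setattr__(self, name, _as_count_array(getattr(self, name), (2, 2), name))

    @property
    def m(self) -> np.ndarray:
        """Cell totals ``m[i, j] = s + r + u``."""
        return self.s + self.r + self.u

    @property
    def n_subjects(self) -> int:
        return int(self.m.sum())

    def flat(self, which: str) -> np.ndarray:
        """Counts in flat cell order (00, 01, 10, 11)."""
        return getattr(self, which).reshape(4) if which != "m" else self.m.reshape(4)

    def to_dict(self) -> dict:
        return {
            "design": "binary",
            "s": self.s.tolist(),
            "r": self.r.tolist(),
            "u": self.u.tolist(),
        }


@dataclass(frozen=True)
class OrdinalVerificationTable:
    """Paired ordinal tests (levels 1..K each) with partial verification.

    Cells are stored flat in row-major order with test 1 as the slower index:
    cell ``c = (t1 - 1) * K + (t2 - 1)``.
    """

    K: int
    s: np.ndarray
    r: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        if self.K < 2:
            raise TableValidationError("K must be at least 2")
        n = self.K * self.K
        for name in ("s", "r", "u"):
            object.__setattr__(self, name, _as_count_array(getattr(self, name), (n,), name))

    @property
    def m(self) -> np.ndarray:
        return self.s + self.r + self.u

    @property
    def n_subjects(self) -> int:
        return int(self.m.sum())

    def patterns(self) -> list[tuple[int, int]]:
        """(t1, t2) pairs in flat cell order."""
        return [(i + 1, j + 1) for i in range(self.K) for j in range(self.K)]

    def to_dict(self) -> dict:
        return {
            "design": "ordinal",
            "K": self.K,
            "s": self.s.tolist(),
            "r": self.r.tolist(),
            "u": self.u.tolist(),
        }


AnyTable = Union[BinaryVerificationTable, OrdinalVerificationTable]


@dataclass(frozen=True)
class PriorSpec:
    """Prior for the conjugate analysis.

    ``improper`` uses the reciprocal density, giving beta(s, r) and
    Dirichlet(m) posteriors; ``uniform`` adds one to every hyperparameter.
    ``zero_fix`` governs cells with s = 0 or r = 0 under the improper prior:
    ``error`` refuses (the posterior would be improper), ``add_one`` replaces
    just the offending zeros by one.  The substitution is recorded in the
    resulting :class:`Hyperparameters` notes because it changes the posterior.
    """

    kind: str = "improper"
    zero_fix: str = "error"

    def __post_init__(self) -> None:
        if self.kind not in ("improper", "uniform"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.zero_fix not in ("error", "add_one"):
            raise ValueError(f"unknown zero_fix {self.zero_fix!r}")


@dataclass(frozen=True)
class Hyperparameters:
    """Posterior hyperparameters: per-cell beta pairs and the Dirichlet vector.

    ``a``/``b`` are the beta parameters of the cell-wise disease probabilities
    (shape (2, 2) for binary, flat length K² for ordinal); ``d`` is the
    Dirichlet parameter over cells in flat order.  ``notes`` records any
    zero-cell substitutions.
    """

    a: np.ndarray
    b: np.ndarray
    d: np.ndarray
    notes: tuple[str, ...] = ()


def hyperparameters(table: AnyTable, prior: PriorSpec = PriorSpec()) -> Hyperparameters:
    """Map a verification table and prior to its conjugate posterior parameters.

    Improper prior: (a, b, d) = (s, r, m).  Uniform prior: (s+1, r+1, m+1).
    """
    a = table.s.astype(float).copy()
    b = table.r.astype(float).copy()
    if isinstance(table, BinaryVerificationTable):
        d = table.flat("m").astype(float)
    else:
        d = table.m.astype(float)
    notes: list[str] = []
    if prior.kind == "uniform":
        a += 1.0
        b += 1.0
        d = d + 1.0
    else:
        zero_a = a == 0
        zero_b = b == 0
        if zero_a.any() or zero_b.any():
            if prior.zero_fix == "error":
                raise ZeroCellError(
                    "cells with zero verified diseased or non-diseased counts "
                    "make the improper posterior undefined; use zero_fix='add_one' "
                    "or a uniform prior"
                )
            if zero_a.any():
                a[zero_a] = 1.0
                notes.append(f"set s=1 in {int(zero_a.sum())} zero cell(s)")
            if zero_b.any():
                b[zero_b] = 1.0
                notes.append(f"set r=1 in {int(zero_b.sum())} zero cell(s)")
    return Hyperparameters(a=a, b=b, d=d, notes=tuple(notes))


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior summary in the usual node-statistics layout.

    mean, sd, Monte-Carlo standard error of the mean, and the 2.5%, 50% and
    97.5% posterior quantiles.
    """

    mean: float
    sd: float
    mc_error: float
    q025: float
    median: float
    q975: float
    n_draws: int

    def __post_init__(self) -> None:
        if not (self.q025 <= self.median <= self.q975):
            raise ValueError("quantiles out of order")

    def as_row(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "mc_error": self.mc_error,
            "2.5%": self.q025,
            "median": self.median,
            "97.5%": self.q975,
        }


@dataclass(frozen=True)
class DrawMatrix:
    """Labelled Monte-Carlo draws: one column per named quantity."""

    names: tuple
    draws: np.ndarray  # (n_draws, n_quantities)
    seed: int

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        draws = np.asarray(self.draws, dtype=float)
        if draws.ndim != 2 or draws.shape[1] != len(names):
            raise ValueError("draws must be (n_draws, n_quantities)")
        if len(set(names)) != len(names):
            raise ValueError("quantity names must be unique")
        object.__setattr__(self, "draws", draws)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=list(self.names))


def _batch_means_se(x: np.ndarray, n_batches: int) -> float:
    # iid draws here, but batch means is the convention for MC error;
    # remainder draws beyond an even split are dropped.
    n = x.size
    per = n // n_batches
    means = x[: per * n_batches].reshape(n_batches, per).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def summarize(draws: DrawMatrix, n_batches: int = 50) -> dict:
    """Summaries per quantity: sample moments, type-7 quantiles, batch-means MC error."""
    if draws.n_draws < 100:
        raise ValueError("need at least 100 draws to summarize")
    if draws.n_draws < n_batches:
        raise ValueError("fewer draws than batches")
    out = {}
    for name in draws.names:
        x = draws.column(name)
        q025, med, q975 = np.quantile(x, [0.025, 0.5, 0.975])  # linear (type 7)
        out[name] = PosteriorSummary(
            mean=float(x.mean()),
            sd=float(x.std(ddof=1)),
            mc_error=_batch_means_se(x, n_batches),
            q025=float(q025),
            median=float(med),
            q975=float(q975),
            n_draws=draws.n_draws,
        )
    return out


# ---------------------------------------------------------------------------
# I/O

def _table_from_dict(doc: Mapping) -> AnyTable:
    design = doc.get("design")
    if design == "binary":
        s = np.asarray(doc["s"])
        r = np.asarray(doc["r"])
        u = np.asarray(doc["u"])
        table = BinaryVerificationTable(s=s, r=r, u=u)
    elif design == "ordinal":
        table = OrdinalVerificationTable(
            K=int(doc["K"]),
            s=np.asarray(doc["s"]),
            r=np.asarray(doc["r"]),
            u=np.asarray(doc["u"]),
        )
    else:
        raise TableValidationError(f"unknown design {design!r}")
    if "m" in doc:
        m_given = np.asarray(doc["m"])
        m_calc = table.m
        if not np.array_equal(m_given.reshape(m_calc.shape), m_calc):
            bad = np.argwhere(m_given.reshape(m_calc.shape) != m_calc)
            raise TableValidationError(
                f"m != s + r + u at cell index {tuple(bad[0].tolist())}"
            )
    return table


def _table_from_csv(path: Path) -> AnyTable:
    df = pd.read_csv(path)
    required = {"y1", "y2", "s", "r", "u"}
    if not required.issubset(df.columns):
        raise TableValidationError(f"CSV must have columns {sorted(required)}")
    levels = sorted(set(df["y1"]) | set(df["y2"]))
    if levels == [0, 1]:
        s = np.zeros((2, 2), dtype=int)
        r = np.zeros((2, 2), dtype=int)
        u = np.zeros((2, 2), dtype=int)
        for _, row in df.iterrows():
            i, j = int(row["y1"]), int(row["y2"])
            s[i, j], r[i, j], u[i, j] = int(row["s"]), int(row["r"]), int(row["u"])
        return BinaryVerificationTable(s=s, r=r, u=u)
    K = max(levels)
    if levels != list(range(1, K + 1)):
        raise TableValidationError("ordinal CSV levels must be 1..K")
    n = K * K
    s = np.zeros(n, dtype=int)
    r = np.zeros(n, dtype=int)
    u = np.zeros(n, dtype=int)
    for _, row in df.iterrows():
        c = (int(row["y1"]) - 1) * K + (int(row["y2"]) - 1)
        s[c], r[c], u[c] = int(row["s"]), int(row["r"]), int(row["u"])
    return OrdinalVerificationTable(K=K, s=s, r=r, u=u)


def load_table(path, design: str | None = None) -> AnyTable:
    """Read a verification table from JSON or CSV.

    ``design`` optionally asserts the expected design ("binary"/"ordinal").
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        table = _table_from_csv(path)
    else:
        with open(path) as fh:
            doc = json.load(fh)
        table = _table_from_dict(doc)
    if design is not None:
        got = "binary" if isinstance(table, BinaryVerificationTable) else "ordinal"
        if got != design:
            raise TableValidationError(f"expected a {design} table, got {got}")
    return table


def write_table(table: AnyTable, path) -> None:
    """Write a table as JSON (counts round-trip exactly)."""
    with open(path, "w") as fh:
        json.dump(table.to_dict(), fh, indent=1)
        fh.write("\n")
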