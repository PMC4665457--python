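"""Inverse-probability-weighting imputation of verification-biased tables.

Within each joint test-outcome cell the verified counts are scaled up by the
reciprocal of that cell's verification rate (s+r)/m.  Under missing-at-random
verification the resulting "selected" table has the same cell-wise disease
fractions as the biased table — the unverified subjects are redistributed
over D in proportion to the verified ones — so accuracy estimators computed
naively on the imputed table are free of verification bias.

``expand_records`` turns a rounded imputed table into per-subject records
(t1, t2, d), the input format for the risk-score logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import BinaryVerificationTable, OrdinalVerificationTable

__all__ = ["ImputedTable", "PatientRecord", "impute_ipw", "expand_records"]


@dataclass(frozen=True)
class PatientRecord:
    """One subject: ordinal test values and imputed disease indicator."""

    t1: int
    t2: int
    d: int

    def __post_init__(self) -> None:
        if self.d not in (0, 1):
            raise ValueError("d must be 0 or 1")
        if self.t1 < 0 or self.t2 < 0:
            raise ValueError("test values must be non-negative")


@dataclass(frozen=True)
class ImputedTable:
    """IPW-imputed cell counts.

    ``s`` and ``r`` are fractional before rounding and satisfy
    s_c + r_c = m_c exactly (the unverified mass is reallocated, not
    created).  ``patterns`` gives the (t1, t2) value pair per flat cell.
    """

    s: np.ndarray
    r: np.ndarray
    m: np.ndarray
    patterns: tuple
    rounding: str

    def __post_init__(self) -> None:
        for name in ("s", "r", "m"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "patterns", tuple(tuple(p) for p in self.patterns))
        if self.rounding not in ("none", "nearest"):
            raise ValueError("rounding must be 'none' or 'nearest'")

    @property
    def n_cells(self) -> int:
        return self.s.size


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x) + 0.5)


def impute_ipw(table, rounding: str = "none") -> ImputedTable:
    """Scale each cell's verified counts by the inverse verification rate.

    s'_c = s_c m_c / (s_c + r_c), r'_c = r_c m_c / (s_c + r_c); the imputed
    table has no unverified subjects.  ``rounding="nearest"`` rounds half
    away from zero (needed before expanding to per-subject records).
    """
    if isinstance(table, BinaryVerificationTable):
        s = table.flat("s").astype(float)
        r = table.flat("r").astype(float)
        m = table.flat("m").astype(float)
        patterns = ((0, 0), (0, 1), (1, 0), (1, 1))
    elif isinstance(table, OrdinalVerificationTable):
        s = table.s.astype(float)
        r = table.r.astype(float)
        m = table.m.astype(float)
        patterns = tuple(table.patterns())
    else:
        raise TypeError(f"unsupported table type {type(table).__name__}")

    verified = s + r
    zero = (verified == 0) & (m > 0)
    if zero.any():
        raise ValueError(
            f"verification rate undefined in cell(s) {np.flatnonzero(zero).tolist()}: "
            "no verified subjects"
        )
    scale = np.divide(m, verified, out=np.ones_like(m), where=verified > 0)
    s_imp = s * scale
    r_imp = r * scale
    if rounding == "nearest":
        s_imp = _round_half_away(s_imp)
        r_imp = _round_half_away(r_imp)
    elif rounding != "none":
        raise ValueError("rounding must be 'none' or 'nearest'")
    return ImputedTable(s=s_imp, r=r_imp, m=m, patterns=patterns, rounding=rounding)


def expand_records(imputed: ImputedTable) -> list[PatientRecord]:
    """Emit one record per imputed subject (requires rounded integer counts).

    Diseased records come first within each cell; record order is flat cell
    order.
    """
    if imputed.rounding != "nearest":
        raise ValueError("expand_records requires an imputed table with rounding='nearest'")
    records: list[PatientRecord] = []
    for (t1, t2), s_c, r_c in zip(imputed.patterns, imputed.s, imputed.r):
        records.extend(PatientRecord(t1, t2, 1) for _ in range(int(s_c)))
        records.extend(PatientRecord(t1, t2, 0) for _ in range(int(r_c)))
    return records
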