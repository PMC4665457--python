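"""Built-in worked-example datasets.

Small cross-tabulated studies shipped with the package:

* ``lung_ct_mri`` — paired binary CT/MRI lung-cancer risk assessment with
  partial verification (116 subjects).
* ``lung_ct_mri_extreme`` — the same study modified so that only subjects
  positive on at least one test are verified (82 subjects; the
  double-negative cell is entirely unverified).
* ``mammography_two_readers`` — two readers rating mammograms on a 3-point
  scale with verification bias (1,768 subjects).  The printed source table
  carries a typo in one cell total; the shipped counts are the internally
  consistent ones (cell 4 total 124 = 43 + 67 + 14).
* ``mammography_imputed`` — the IPW-imputed, rounded version of the
  two-reader study (1,078 diseased / 690 non-diseased; one diseased cell
  count corrected from the misprinted source to keep the totals consistent).
* ``mammography_auc_hyperparameters`` — the Dirichlet hyperparameter vectors
  used for the published combined-AUC run, reproduced verbatim including the
  0.125 entry (evidently a misprint for 125) and a transposed pair of cells;
  kept as printed so the published number can be reproduced exactly.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .tables import BinaryVerificationTable, OrdinalVerificationTable, _table_from_dict

__all__ = [
    "lung_ct_mri",
    "lung_ct_mri_extreme",
    "mammography_two_readers",
    "mammography_imputed",
    "mammography_auc_hyperparameters",
    "fixture_path",
]


def _load(name: str) -> dict:
    with resources.files("veribayes.data").joinpath(name).open() as fh:
        return json.load(fh)


def fixture_path(name: str):
    """Filesystem path of a shipped fixture (for CLI examples)."""
    return resources.files("veribayes.data").joinpath(name)


def lung_ct_mri() -> BinaryVerificationTable:
    """Paired binary CT/MRI study with partial verification."""
    return _table_from_dict(_load("table2.json"))


def lung_ct_mri_extreme() -> BinaryVerificationTable:
    """CT/MRI study with extreme verification bias (double negatives unverified)."""
    return _table_from_dict(_load("table4.json"))


def mammography_two_readers() -> OrdinalVerificationTable:
    """Two-reader 3-level mammography study with verification bias."""
    return _table_from_dict(_load("table6.json"))


def mammography_imputed() -> OrdinalVerificationTable:
    """IPW-imputed, rounded two-reader study (no unverified subjects)."""
    return _table_from_dict(_load("imputed_table8.json"))


def mammography_auc_hyperparameters() -> tuple[np.ndarray, np.ndarray]:
    """(diseased, non-diseased) Dirichlet vectors of the published AUC run."""
    doc = _load("bugscode4_list.json")
    return np.asarray(doc["a_diseased"], float), np.asarray(doc["a_nondiseased"], float)
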