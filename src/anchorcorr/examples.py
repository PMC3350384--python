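"""Bundled worked-example validation tables.

Two small tables from a four-cancer tissue-array survey of the
proteasome activator REGγ (PSME3) ship with the package as worked
examples:

* ``ihc_tissue_array.tsv`` — IHC staining score counts (-, +, pooled
  ++/+++) for 92 lung, 48 colon, 49 thyroid and 206 liver carcinoma
  cases;
* ``qpcr_knockdown.tsv`` — relative qRT-PCR expression in anchor
  knockdown (shR) vs control (shN) cell lines for thirty genes predicted
  to correlate with the anchor, with the predicted correlation sign.

These are inputs to :mod:`anchorcorr.validation`, used by the README
walkthrough and the acceptance checks.
"""

from __future__ import annotations

import csv
from importlib import resources

from .validation import IHCScoreTable, QPCRRecord


def _data_rows(name: str) -> list[dict[str, str]]:
    text = resources.files("anchorcorr").joinpath(f"data/{name}").read_text()
    return list(csv.DictReader(text.splitlines(), delimiter="\t"))


def load_ihc_example() -> list[IHCScoreTable]:
    """IHC score counts for the four-cancer tissue-array example."""
    return [
        IHCScoreTable(
            cancer_type=row["cancer_type"],
            counts={
                "neg": int(row["n_neg"]),
                "plus": int(row["n_plus"]),
                "plusplus": int(row["n_plusplus"]),
            },
        )
        for row in _data_rows("ihc_tissue_array.tsv")
    ]


def load_qpcr_example() -> list[QPCRRecord]:
    """Thirty-gene knockdown qRT-PCR panel with predicted signs."""
    return [
        QPCRRecord(
            gene=row["gene"],
            tissue=row["tissue"],
            rel_value_shr=float(row["rel_value_shr"]),
            predicted_sign=row["predicted_sign"],
            p_value=float(row["p_value"]),
        )
        for row in _data_rows("qpcr_knockdown.tsv")
    ]
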