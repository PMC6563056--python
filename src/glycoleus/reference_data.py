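"""Bundled reference data.

``reference_noe.tsv`` holds the published experimental NOE upper bounds and
the reported r^-6-averaged simulation distances (with block errors and
violations, in Angstrom) for the four model glycopeptide systems
(1: alpha-GalNAc-Ser, 2: alpha-GalNAc-Thr, 3: beta-GalNAc-Ser,
4: beta-GalNAc-Thr). Two printed cells are internally inconsistent with their
own printed inputs (rounding in the source): system 2 d(H,HN2) MD violation
(printed 0.6, the printed average and bound give 0.7) and system 4 d(HA,H)
(printed 0.1 in both columns, the printed average 2.7 is below the printed
bound 2.8). ``consistent_md`` / ``consistent_leus`` flag this.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd


def load_reference_noe_table() -> pd.DataFrame:
    """Reference NOE bounds and reported averages for the four systems.

    Adds ``consistent_md`` / ``consistent_leus`` columns: True where the
    printed violation equals max(0, printed average - bound) to the printed
    precision.
    """
    with resources.files("glycoleus").joinpath("data/reference_noe.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    for col in ("md", "leus"):
        implied = np.maximum(0.0, df[f"{col}_avg_A"] - df["exp_A"])
        df[f"consistent_{col}"] = np.isclose(
            implied, df[f"{col}_violation_A"], atol=5e-3
        )
    return df
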