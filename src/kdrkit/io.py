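"""Delimited-text I/O for specimen tables.

The specimen schema is one UTF-8 row per bioassayed sand fly with a
required header.  Columns:

========  ==========================================================
id                 specimen identifier (required)
district           collection district (optional)
phc                primary health centre (optional)
village            village (optional)
insecticide        DDT / deltamethrin / alpha-cypermethrin (required)
exposure_minutes   exposure duration (optional)
outcome            alive / dead, scored 24 h post-exposure (required)
role               test / control (required)
cohort             F1 / colony / wild (optional)
genotype           "TTA/TCA"-style codon genotype; empty = ungenotyped
========  ==========================================================
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

from .genotypes import KdrGenotype

REQUIRED_COLUMNS = ("id", "insecticide", "outcome", "role", "genotype")
VALID_OUTCOMES = {"alive", "dead"}
VALID_ROLES = {"test", "control"}

__all__ = ["REQUIRED_COLUMNS", "read_specimen_table", "write_specimen_table"]


def read_specimen_table(path: Union[str, Path], sep: str = "\t") -> pd.DataFrame:
    """Read and validate a delimited specimen table."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"specimen table missing required column(s): {missing}")
    bad_outcome = set(df["outcome"].dropna()) - VALID_OUTCOMES
    if bad_outcome:
        raise ValueError(f"invalid outcome value(s): {sorted(bad_outcome)}")
    bad_role = set(df["role"].dropna()) - VALID_ROLES
    if bad_role:
        raise ValueError(f"invalid role value(s): {sorted(bad_role)}")
    for label in df["genotype"].dropna():
        KdrGenotype.from_label(label)  # validates codons
    if "exposure_minutes" in df.columns:
        df["exposure_minutes"] = pd.to_numeric(df["exposure_minutes"])
    return df


def write_specimen_table(
    df: pd.DataFrame, path: Union[str, Path], sep: str = "\t"
) -> None:
    df.to_csv(path, sep=sep, index=False)
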