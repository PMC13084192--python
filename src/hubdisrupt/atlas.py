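"""Region-label tables (AAL 90-region parcellation shipped as a fixture)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd


def aal90_labels() -> pd.DataFrame:
    """The 90-region AAL cerebrum parcellation: index (1-90), abbreviation, name.

    Odd indices are left-hemisphere parcels, even indices right, in the
    atlas's canonical ordering.
    """
    with resources.files("hubdisrupt.data").joinpath("aal90_labels.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Read a user label table (TSV: index, abbreviation, name)."""
    df = pd.read_csv(path, sep="\t")
    required = {"index", "abbreviation"}
    if not required.issubset(df.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    return df
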