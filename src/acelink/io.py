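"""TSV input/output for pairs and registry tables.

Files are plain tab-separated tables with ``#``-prefixed header comments
recording the preset name and root seed, so any output file identifies the
configuration that produced it.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_tsv(df: pd.DataFrame, path, preset: str | None = None,
              seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if preset is not None:
            fh.write(f"# preset: {preset}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
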