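"""Bundled reference data.

``chinese_spring_alpha_gliadins.tsv`` carries the published characteristics
of the 25 intact α-gliadin proteins encoded at the Gli-2 loci of bread
wheat cv. Chinese Spring: predicted MW (Da) and pI, glutamine counts in
the two polyQ tracts, per-epitope counts for the five major CD epitopes,
and 33-mer / CSTT presence flags.  Per-epitope columns for a few D-genome
proteins reflect a best-effort reading of the printed table; row totals
and the polyQ columns are exact.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

EPITOPE_COLUMNS = [
    "DQ2.5-glia-a1a",
    "DQ2.5-glia-a1b",
    "DQ2.5-glia-a2",
    "DQ2.5-glia-a3",
    "DQ8-glia-a1",
]


def load_chinese_spring_table() -> pd.DataFrame:
    """The published Chinese Spring intact α-gliadin characteristics table."""
    with resources.files("glia.data").joinpath(
        "chinese_spring_alpha_gliadins.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["has_33mer"] = df["has_33mer"].astype(bool)
    df["has_cstt"] = df["has_cstt"].astype(bool)
    df["total"] = df[EPITOPE_COLUMNS].sum(axis=1)
    return df
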