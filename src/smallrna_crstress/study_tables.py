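"""Machine-readable copies of the printed result tables of the radish
Cr(VI) small RNA sequencing study.

These are the published raw counts, library totals, normalized values and
fold changes that the arithmetic of this package (RPM normalization, zero
substitution, log2 fold change, direction calls, category accounting) must
reproduce, and they double as regression fixtures.  The clean-read totals
are N_CK = 18,127,561 and N_CR200 = 19,552,260.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "N_CK",
    "N_CR200",
    "category_table",
    "family_table",
    "known_de_table",
    "novel_de_table",
    "de_counts",
    "table_fixtures",
]

N_CK = 18_127_561
N_CR200 = 19_552_260


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("smallrna_crstress.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def category_table() -> pd.DataFrame:
    """Unique/total small RNA counts per annotation category and library."""
    return _load("table1_categories.tsv")


def family_table() -> pd.DataFrame:
    """Known miRNA family abundances (conserved and non-conserved)."""
    df = _load("table2_families.tsv")
    df["conserved"] = df["conserved"].astype(bool)
    return df


def known_de_table() -> pd.DataFrame:
    """Per-miRNA counts and calls for the known differentially expressed set."""
    return _load("table3_known_de.tsv")


def novel_de_table() -> pd.DataFrame:
    """Per-miRNA counts and calls for the novel differentially expressed set."""
    return _load("table4_novel_de.tsv")


def de_counts() -> dict[str, tuple[int, int]]:
    """Raw (CK, Cr200) counts for all printed DE rows, known and novel."""
    out: dict[str, tuple[int, int]] = {}
    for df in (known_de_table(), novel_de_table()):
        for row in df.itertuples():
            out[row.mirna] = (int(row.count_ck), int(row.count_cr200))
    return out


def table_fixtures() -> dict[str, pd.DataFrame]:
    """All printed-table fixtures keyed by a short name."""
    return {
        "categories": category_table(),
        "families": family_table(),
        "known_de": known_de_table(),
        "novel_de": novel_de_table(),
    }
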