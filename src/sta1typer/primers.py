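"""Default oligonucleotide set for STA1 genotyping.

The packaged TSV carries the published detection, promoter, qPCR and
sequencing oligos used for diastatic-yeast screening (SD-5A/SD-6B for the
gene itself, the UAS pairs for the intact promoter, Sdia-f/-r for the
79-bp ORF marker, plus the walking/sequencing primers and repair oligos).
Custom primer sets can be loaded from any two-column ``name<TAB>sequence``
TSV.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_MIN_PRIMER_LEN = 15


def load_primer_table(path=None) -> pd.DataFrame:
    """Load a primer TSV (columns ``name``, ``sequence``[, ``category``])."""
    if path is None:
        with resources.files("sta1typer.data").joinpath("primers.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    if not {"name", "sequence"}.issubset(table.columns):
        raise ValueError("primer TSV needs 'name' and 'sequence' columns")
    table["sequence"] = table["sequence"].str.upper()
    return table


def primer_dict(path=None) -> dict[str, str]:
    table = load_primer_table(path)
    return dict(zip(table["name"], table["sequence"]))


# Module-level defaults, loaded once.
PRIMERS: dict[str, str] = primer_dict()
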