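"""Published reference tables shipped with the package.

Two small TSVs from the white/brown alpaca skin small-RNA study are used
as computation inputs (never as precomputed answers):

* ``expression_table()`` — the significantly differential conserved
  miRNAs with their normalised expression levels (NEL, reads per million
  clean reads) in brown and white skin and the printed fold change;
* ``novel_mfei_table()`` — the novel miRNA mature sequences with their
  reported MFEI values;
* ``library_stats()`` — per-library raw/clean/genome-matched read
  counts.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: per-library read accounting of the two sequenced skin libraries
LIBRARY_STATS = {
    "white": {"raw_reads": 17_427_359, "clean_reads": 16_834_090,
              "unique_tags": 1_058_335, "genome_matched_reads": 10_389_135},
    "brown": {"raw_reads": 19_748_517, "clean_reads": 19_069_600,
              "unique_tags": 977_308, "genome_matched_reads": 12_630_855},
}

#: published novel-miRNA set sizes per library and their overlap
NOVEL_SET_SIZES = {"white": 55, "brown": 63, "shared": 31}


def _load(name: str) -> pd.DataFrame:
    with resources.files("mirskin.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def expression_table() -> pd.DataFrame:
    return _load("alpaca_skin_expression.tsv")


def novel_mfei_table() -> pd.DataFrame:
    return _load("novel_mirna_mfei.tsv")


def library_stats() -> pd.DataFrame:
    return pd.DataFrame(
        [{"library": lib, **vals} for lib, vals in LIBRARY_STATS.items()]
    )
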