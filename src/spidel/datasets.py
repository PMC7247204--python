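"""Bundled datasets.

``load_brain_mutants`` returns the sequenced Spi- deletion junctions
recovered from the brain of wild-type and scid (DNA-PKcs-deficient) gpt
delta mice, sham-treated or whole-body X-irradiated with 10 Gy, transcribed
from published sequencing results (one row per mutant; 25 / 72 / 8 / 95
records in the WT-0Gy / WT-10Gy / scid-0Gy / scid-10Gy groups).  Positions
up to 422 are local to the *gam* selection gene; larger positions are
transgene coordinates.  The ``flag`` column marks rows whose printed size,
placement range and junction annotation are mutually inconsistent in the
source; such rows are retained (the junction-sequence annotation is taken
as authoritative for microhomology length) rather than silently corrected.

``load_brain_group_mf`` returns the group mean Spi- mutant frequencies
(x1e-6, with SD and animal counts) for the same four groups.  Per-animal
counts behind these means were not published; they enter the analysis as
given inputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import MutantRecord, read_mutant_table

__all__ = ["load_brain_mutants", "load_brain_group_mf"]


def _data_path(name: str):
    return resources.files("spidel.data").joinpath(name)


def load_brain_mutants() -> list[MutantRecord]:
    """Sequenced Spi- deletion mutants from mouse brain (four groups)."""
    with resources.as_file(_data_path("brain_mutants.tsv")) as path:
        return read_mutant_table(path)


def load_brain_group_mf() -> pd.DataFrame:
    """Group mean Spi- mutant frequencies (x1e-6), indexed by (strain, dose_gy)."""
    with resources.as_file(_data_path("brain_group_mf.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    return df.set_index(["strain", "dose_gy"])
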