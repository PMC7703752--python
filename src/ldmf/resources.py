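"""Loaders for the small reference tables and fixtures bundled with ldmf.

Bundled artifacts:

* ``aaindex_properties.tsv`` — three AAindex scales: KYTJ820101
  (Kyte-Doolittle hydropathy), GRAR740103 (Grantham residue volume) and
  KLEP840101 (net charge). These are the default hydrophobicity / volume
  / charge encodings; any AAindex-style table can be substituted.
* ``background_composition.tsv`` — SwissProt-like amino-acid frequencies
  used as the default PWM background.
* ``ss_propensities.tsv`` — Chou-Fasman-style helix/strand/coil
  propensities backing the built-in secondary-structure predictor.
* ``printed_peptides.fasta`` — the 20 assay peptides (positive controls,
  candidates, scrambled control) used as a desk-scale test surface.
* ``positive_set_synthetic.{fasta,tsv}`` — a synthetic stand-in for the
  initial positive training set: 18 motif sites on 6 carrier proteins
  (4 each on four paxillin-family-like carriers, 1 DLC1-like, 1
  RoXaN-like). Motif cores are seeded from published peptide sequences
  where printed, the remainder instantiate the canonical consensus; the
  carrier scaffolds are generated, not real proteins (see the fixture
  docnotes and ``scripts/make_positive_fixture.py``).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from ldmf.io_formats import (
    MotifSiteRecord,
    PropertyTable,
    ProteinRecord,
    read_fasta,
    read_motif_sites,
    read_property_tables,
)

#: feature order expected by the physicochemical profile
PROPERTY_ROLES = ("hydrophobicity", "volume", "charge")
_ROLE_TO_ID = {
    "hydrophobicity": "KYTJ820101",
    "volume": "GRAR740103",
    "charge": "KLEP840101",
}


def _data_path(name: str):
    return resources.files("ldmf") / "data" / name


@lru_cache(maxsize=None)
def load_property_tables() -> dict[str, PropertyTable]:
    """Default property tables keyed by role (hydrophobicity/volume/charge)."""
    with resources.as_file(_data_path("aaindex_properties.tsv")) as p:
        by_id = read_property_tables(p)
    return {role: by_id[aid] for role, aid in _ROLE_TO_ID.items()}


@lru_cache(maxsize=None)
def load_background_composition() -> dict[str, float]:
    """SwissProt-like background amino-acid frequencies (sums to 1)."""
    with resources.as_file(_data_path("background_composition.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    total = df["frequency"].sum()
    return {r.letter: r.frequency / total for r in df.itertuples(index=False)}


@lru_cache(maxsize=None)
def load_ss_propensities() -> pd.DataFrame:
    with resources.as_file(_data_path("ss_propensities.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="letter")


def load_printed_peptides() -> list[ProteinRecord]:
    """The 20 assay peptides treated as mini-proteins."""
    with resources.as_file(_data_path("printed_peptides.fasta")) as p:
        return read_fasta(p)


def load_reference_positive_set() -> tuple[list[ProteinRecord], list[MotifSiteRecord]]:
    """Synthetic stand-in for the initial 18-motif / 6-protein positive set."""
    with resources.as_file(_data_path("positive_set_synthetic.fasta")) as p:
        proteins = read_fasta(p)
    with resources.as_file(_data_path("positive_set_synthetic.tsv")) as p:
        sites = read_motif_sites(p, proteins=proteins)
    return proteins, sites
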