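"""Readers and writers for on-disk artifacts.

Handles FASTA proteins, 3-state secondary-structure tracks (FASTA-like
``plain3state`` and PSIPRED ``.ss2``), motif-site TSVs, AAindex-style
property tables and scan-hit reports. Model-bundle persistence lives in
:mod:`ldmf.classifier`; thin wrappers are re-exported here so every disk
artifact has an entry point in this module.

Coordinates are 0-based half-open everywhere. The anchor of a motif site
is the index of the motif's first leucine (L0); the 10-residue core spans
sequence positions ``[anchor - 1, anchor + 9)`` (L0-relative -1..+8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: letters silently collapsed to X on input (ambiguity codes, U/O, stop)
NONCANONICAL_AA = frozenset("BZJUO*")
SS_STATES = "HEC"
SITE_LABELS = frozenset({"positive", "negative", "candidate"})


class LdmfError(Exception):
    """Base class for errors raised by this package."""


class FormatError(LdmfError):
    """Malformed or inconsistent on-disk input."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence (the scanning substrate)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record with empty id")
        if len(self.sequence) < 1:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - set(CANONICAL_AA + "X")
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SecondaryStructureTrack:
    """Per-residue 3-state secondary structure for one protein."""

    protein_id: str
    states: str

    def __post_init__(self) -> None:
        bad = set(self.states) - set(SS_STATES)
        if bad:
            raise FormatError(
                f"track {self.protein_id!r}: unknown state letter(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class MotifSiteRecord:
    """A motif site: L0 anchor plus the 10-residue core (-1..+8)."""

    protein_id: str
    anchor: int
    core: str
    label: str

    def __post_init__(self) -> None:
        if len(self.core) != 10:
            raise FormatError(
                f"site {self.protein_id}@{self.anchor}: core must be 10 residues, "
                f"got {len(self.core)}"
            )
        if self.label not in SITE_LABELS:
            raise FormatError(
                f"site {self.protein_id}@{self.anchor}: label {self.label!r} not in "
                f"{sorted(SITE_LABELS)}"
            )


@dataclass(frozen=True)
class PropertyTable:
    """AAindex-style scale: one real value per canonical amino acid.

    ``X`` and the pad symbol ``-`` map to the mean of the 20 values.
    """

    property_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(CANONICAL_AA):
            raise FormatError(
                f"property table {self.property_id!r} must cover exactly the 20 "
                "canonical amino acids"
            )

    @property
    def mean(self) -> float:
        return sum(self.values.values()) / len(self.values)

    def value(self, letter: str) -> float:
        if letter in ("X", "-"):
            return self.mean
        try:
            return self.values[letter]
        except KeyError:
            raise FormatError(
                f"property table {self.property_id!r}: unknown letter {letter!r}"
            ) from None


# ---------------------------------------------------------------------------
# FASTA


def _sanitize_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper()
    found = set(seq) & NONCANONICAL_AA
    if found:
        log.warning(
            "record %s: mapping non-canonical residue(s) %s to X",
            record_id,
            "".join(sorted(found)),
        )
        seq = "".join("X" if c in NONCANONICAL_AA else c for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records; uppercases and collapses ambiguity codes to X."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=_sanitize_sequence(str(rec.seq), rec.id),
                description=rec.description,
            )
        )
    if not records:
        raise FormatError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Secondary-structure tracks


def _normalize_states(raw: str, source_id: str) -> str:
    states = raw.upper().replace("-", "C")
    bad = set(states) - set(SS_STATES)
    if bad:
        raise FormatError(
            f"track {source_id!r}: unknown state letter(s) {sorted(bad)!r}"
        )
    return states


def _read_ss2(path: Path, protein_id: str) -> SecondaryStructureTrack:
    states: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        cols = stripped.split()
        if len(cols) < 3:
            raise FormatError(f"{path}:{lineno}: malformed ss2 row")
        states.append(cols[2])
    if not states:
        raise FormatError(f"no records in {path}")
    return SecondaryStructureTrack(
        protein_id=protein_id, states=_normalize_states("".join(states), protein_id)
    )


def read_ss_track(
    path: str | Path,
    dialect: str = "plain3state",
    protein_id: str | None = None,
) -> list[SecondaryStructureTrack]:
    """Read secondary-structure tracks.

    ``plain3state`` is a FASTA-like file whose sequence lines are H/E/C
    strings (``-`` accepted as coil); ``psipred_ss2`` is the standard
    per-residue ss2 column format (one protein per file; *protein_id*
    defaults to the file stem).
    """
    path = Path(path)
    if dialect == "plain3state":
        tracks = []
        seen: set[str] = set()
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate track id {rec.id!r} in {path}")
            seen.add(rec.id)
            tracks.append(
                SecondaryStructureTrack(
                    protein_id=rec.id,
                    states=_normalize_states(str(rec.seq), rec.id),
                )
            )
        if not tracks:
            raise FormatError(f"no records in {path}")
        return tracks
    if dialect == "psipred_ss2":
        return [_read_ss2(path, protein_id or path.stem)]
    raise ValueError(f"unknown dialect {dialect!r}")


def write_ss_tracks(
    tracks: Iterable[SecondaryStructureTrack], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            fh.write(f">{t.protein_id}\n{t.states}\n")


def validate_tracks(
    tracks: Sequence[SecondaryStructureTrack],
    proteins: Sequence[ProteinRecord],
) -> None:
    """Raise if any track length disagrees with its protein sequence."""
    lengths = {p.id: len(p) for p in proteins}
    mismatched = [
        t.protein_id
        for t in tracks
        if t.protein_id in lengths and len(t) != lengths[t.protein_id]
    ]
    if mismatched:
        raise FormatError("length mismatch: " + ", ".join(sorted(mismatched)))


# ---------------------------------------------------------------------------
# Motif-site TSV

_SITE_COLUMNS = ["protein_id", "anchor", "core", "label"]


def read_motif_sites(
    path: str | Path,
    proteins: Sequence[ProteinRecord] | None = None,
    allow_padded: bool = False,
) -> list[MotifSiteRecord]:
    """Read a motif-site TSV (columns protein_id, anchor, core, label).

    Anchors are 0-based indices of L0. When *proteins* is given, each core
    is checked against the parent slice ``[anchor-1, anchor+9)``. Anchors
    < 1 (position -1 off the N-terminus) require *allow_padded*.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_SITE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    by_id = {p.id: p for p in proteins} if proteins is not None else {}
    sites: list[MotifSiteRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        core = str(row.core)
        if len(core) != 10:
            raise FormatError(f"{path} row {i}: core must be 10 residues")
        label = str(row.label)
        if label not in SITE_LABELS:
            raise FormatError(f"{path} row {i}: unknown label {label!r}")
        try:
            anchor = int(row.anchor)
        except ValueError:
            raise FormatError(f"{path} row {i}: anchor must be an integer") from None
        if anchor < 1 and not allow_padded:
            raise FormatError(
                f"{path} row {i}: anchor {anchor} has no position -1 "
                "(pass allow_padded to accept)"
            )
        site = MotifSiteRecord(
            protein_id=str(row.protein_id), anchor=anchor, core=core, label=label
        )
        parent = by_id.get(site.protein_id)
        if parent is not None:
            observed = parent.sequence[max(anchor - 1, 0) : anchor + 9]
            if observed != core.strip("-"):
                raise FormatError(
                    f"{path} row {i}: core {core!r} does not match parent slice "
                    f"{observed!r}"
                )
        sites.append(site)
    return sites


def write_motif_sites(sites: Iterable[MotifSiteRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.protein_id, s.anchor, s.core, s.label) for s in sites],
        columns=_SITE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Property tables (wide TSV: property_id, then one column per amino acid)


def read_property_tables(path: str | Path) -> dict[str, PropertyTable]:
    df = pd.read_csv(path, sep="\t")
    if "property_id" not in df.columns:
        raise FormatError(f"{path}: missing 'property_id' column")
    tables: dict[str, PropertyTable] = {}
    letters = [c for c in df.columns if c != "property_id"]
    for _, row in df.iterrows():
        pid = str(row["property_id"])
        tables[pid] = PropertyTable(
            property_id=pid,
            values={letter: float(row[letter]) for letter in letters},
        )
    if not tables:
        raise FormatError(f"no records in {path}")
    return tables


# ---------------------------------------------------------------------------
# Hit reports


def write_hits(hits: Iterable, path: str | Path) -> None:
    """Write scan hits as TSV, one row per retained site.

    ``anchor`` is the 0-based L0 index; ``motif_span`` restates the core in
    the human-facing L0-relative convention.
    """
    rows = [
        (
            h.protein_id,
            h.anchor,
            f"{h.anchor - 1}..{h.anchor + 8} (L0-relative -1..+8)",
            h.core,
            h.decision_score,
            h.pattern_match,
            h.inverse_pattern_match,
            h.model_round,
        )
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "anchor",
            "motif_span",
            "core",
            "decision_score",
            "pattern_match",
            "inverse_pattern_match",
            "model_round",
        ],
    ).to_csv(path, sep="\t", index=False)


def save_model_bundle(bundle, path: str | Path) -> None:
    from ldmf.classifier import save_model_bundle as _save

    _save(bundle, path)


def load_model_bundle(path: str | Path):
    from ldmf.classifier import load_model_bundle as _load

    return _load(path)
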