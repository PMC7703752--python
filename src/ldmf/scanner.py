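"""Proteome scanning and degenerate-pattern baselines.

``pattern_scan`` implements the classic degenerate LD-motif search
pattern (L,V)(D,E)X(L,M)(L,M)XXL — a necessary-but-unspecific baseline
that fires thousands of times per proteome. ``inverse_pattern_scan``
flags class-II (reverse-orientation) motifs, where the acidic/leucine
pair sits at the helix C-terminus (D/E at +6, L at +7) instead of the
N-terminus; this is an exploratory reporting flag only and never feeds
training. ``scan_proteome`` runs a trained SVM bundle over every
leucine-anchored window and reports thresholded, overlap-suppressed
hits ranked by decision score.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ldmf.classifier import ModelBundle
from ldmf.io_formats import (
    LdmfError,
    ProteinRecord,
    SecondaryStructureTrack,
)
from ldmf.sspred import default_propensity_model, predict_ss
from ldmf.windows import CORE_WIDTH, WindowInstance, attach_ss, enumerate_candidates

#: (L,V)(D,E)X(L,M)(L,M)XXL, anchored on L0. An unknown residue X can sit
#: in a wildcard slot but never satisfies a constrained one.
CANONICAL_PATTERN = re.compile(r"(?=([LV][DE].[LM][LM]..L))")
CANONICAL_FULL = re.compile(r"[LV][DE].[LM][LM]..L")

#: the canonical pattern read C-to-N (class II / inverse orientation).
#: The mid-helix hydrophobic class is widened to include Ile, which the
#: experimentally confirmed inverse motifs use at these slots.
INVERSE_PATTERN = re.compile(r"(?=(L..[ILM][ILM].[DE][LV]))")


@dataclass(frozen=True)
class ScanHit:
    protein_id: str
    anchor: int  # 0-based L0 index
    core: str
    decision_score: float
    pattern_match: bool
    inverse_pattern_match: bool
    model_round: int


def pattern_scan(protein: ProteinRecord) -> list[tuple[int, str]]:
    """All (offset, 8-mer) matches of the degenerate LD pattern; overlaps kept."""
    seq = protein.sequence
    return [(m.start(), m.group(1)) for m in CANONICAL_PATTERN.finditer(seq)]


def inverse_pattern_scan(protein: ProteinRecord) -> list[tuple[int, str]]:
    """All (offset, 8-mer) matches of the reverse-orientation pattern."""
    seq = protein.sequence
    return [(m.start(), m.group(1)) for m in INVERSE_PATTERN.finditer(seq)]


def _suppress_overlaps(hits: list[ScanHit]) -> list[ScanHit]:
    """Greedy per-protein suppression: keep the best-scoring window among
    any set of cores overlapping by >= 1 residue."""
    kept: list[ScanHit] = []
    spans: list[tuple[int, int]] = []
    for h in sorted(hits, key=lambda h: (-h.decision_score, h.anchor)):
        start, stop = h.anchor - 1, h.anchor + CORE_WIDTH - 1
        if any(start < s2 and s1 < stop for s1, s2 in spans):
            continue
        kept.append(h)
        spans.append((start, stop))
    return kept


def scan_proteome(
    bundle: ModelBundle,
    proteins: Sequence[ProteinRecord],
    ss_source: Mapping[str, SecondaryStructureTrack] | str = "builtin",
    threshold: float = 0.0,
    overlap_suppression: bool = True,
    mode: str = "anchored_L",
) -> list[ScanHit]:
    """Score every candidate window; report hits above *threshold*.

    *ss_source* is either ``"builtin"`` (propensity predictor) or a
    mapping protein_id -> track covering every scanned protein. The
    returned hits are sorted by decision score, descending; within each
    protein overlapping cores are greedily suppressed (the per-protein
    maximum is never discarded).
    """
    if isinstance(ss_source, str):
        if ss_source != "builtin":
            raise ValueError(f"unknown ss_source {ss_source!r}")
        model = default_propensity_model()
        tracks = {p.id: predict_ss(p, model) for p in proteins}
    else:
        tracks = dict(ss_source)
        missing = sorted(p.id for p in proteins if p.id not in tracks)
        if missing:
            raise LdmfError("missing SS track(s) for: " + ", ".join(missing))

    all_hits: list[ScanHit] = []
    for p in sorted(proteins, key=lambda p: p.id):
        windows = [
            attach_ss(w, tracks[p.id]) for w in enumerate_candidates(p, mode)
        ]
        if not windows:
            continue
        scores = bundle.decision_function(bundle.featurize_windows(windows))
        hits = []
        for w, s in zip(windows, scores):
            if s <= threshold:
                continue
            eight = w.core[1:9]
            hits.append(
                ScanHit(
                    protein_id=p.id,
                    anchor=w.anchor,
                    core=w.core,
                    decision_score=float(s),
                    pattern_match=bool(CANONICAL_FULL.fullmatch(eight)),
                    inverse_pattern_match=bool(INVERSE_PATTERN.search(w.core)),
                    model_round=bundle.round,
                )
            )
        if overlap_suppression:
            hits = _suppress_overlaps(hits)
        all_hits.extend(hits)
    all_hits.sort(key=lambda h: (-h.decision_score, h.protein_id, h.anchor))
    return all_hits


def per_protein_maxima(hits: Iterable[ScanHit]) -> dict[str, ScanHit]:
    """Best hit per protein (some reports want protein-level scores)."""
    best: dict[str, ScanHit] = {}
    for h in hits:
        if h.protein_id not in best or h.decision_score > best[h.protein_id].decision_score:
            best[h.protein_id] = h
    return best
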