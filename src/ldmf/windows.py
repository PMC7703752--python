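"""Candidate-window extraction.

A candidate is a 10-residue core anchored on a leucine (L0, core spans
L0-relative positions -1..+8) plus its 20-residue upstream and downstream
flanks. Windows near the termini are padded with ``-`` so all windows
share one shape; pads occur only as a contiguous prefix of the upstream
flank (or the start of the core) and a contiguous suffix of the
downstream flank (or the end of the core).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Literal

from ldmf.io_formats import LdmfError, ProteinRecord, SecondaryStructureTrack

CORE_WIDTH = 10
FLANK_WIDTH = 20
PAD = "-"

EnumMode = Literal["anchored_L", "exhaustive"]


@dataclass(frozen=True)
class WindowInstance:
    """One 10-mer candidate core with flanks and optional SS annotation."""

    protein_id: str
    anchor: int
    core: str
    upstream: str
    downstream: str
    ss_core: str | None = None
    ss_upstream: str | None = None
    ss_downstream: str | None = None
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if len(self.core) != CORE_WIDTH:
            raise ValueError(f"core must be {CORE_WIDTH} residues")
        if len(self.upstream) != FLANK_WIDTH or len(self.downstream) != FLANK_WIDTH:
            raise ValueError(f"flanks must be {FLANK_WIDTH} residues")
        for ss in (self.ss_core, self.ss_upstream, self.ss_downstream):
            if ss is not None and set(ss) - set("HEC-"):
                raise ValueError(f"invalid SS letters in {ss!r}")

    @property
    def has_ss(self) -> bool:
        return self.ss_core is not None

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.anchor)


def _slice_padded(seq: str, start: int, stop: int) -> str:
    """Slice with '-' padding outside [0, len(seq))."""
    n = len(seq)
    left = min(stop, 0) - start if start < 0 else 0
    right = stop - max(start, n) if stop > n else 0
    return PAD * left + seq[max(start, 0) : min(max(stop, 0), n)] + PAD * right


def extract_window(
    protein: ProteinRecord, anchor: int, label: str = "unlabeled"
) -> WindowInstance:
    """Extract the core/flank window around L0 = ``protein.sequence[anchor]``."""
    seq = protein.sequence
    core_start = anchor - 1
    core_stop = anchor + CORE_WIDTH - 1
    return WindowInstance(
        protein_id=protein.id,
        anchor=anchor,
        core=_slice_padded(seq, core_start, core_stop),
        upstream=_slice_padded(seq, core_start - FLANK_WIDTH, core_start),
        downstream=_slice_padded(seq, core_stop, core_stop + FLANK_WIDTH),
        label=label,
    )


def enumerate_candidates(
    protein: ProteinRecord, mode: EnumMode = "anchored_L"
) -> Iterator[WindowInstance]:
    """Yield one window per admissible anchor.

    ``anchored_L`` anchors on every leucine (the canonical L0 constraint);
    ``exhaustive`` anchors on every position, so non-canonical cores (e.g.
    inverse-orientation motifs) can still be scored.
    """
    if mode not in ("anchored_L", "exhaustive"):
        raise ValueError(f"unknown enumeration mode {mode!r}")
    for i, residue in enumerate(protein.sequence):
        if mode == "anchored_L" and residue != "L":
            continue
        yield extract_window(protein, i)


def attach_ss(
    window: WindowInstance, track: SecondaryStructureTrack
) -> WindowInstance:
    """Return a copy of *window* carrying index-aligned SS slices.

    Padding mirrors the sequence padding exactly; attaching twice with the
    same track is idempotent.
    """
    if track.protein_id != window.protein_id:
        raise LdmfError(
            f"SS track for {track.protein_id!r} does not belong to window on "
            f"{window.protein_id!r}"
        )
    states = track.states
    core_start = window.anchor - 1
    core_stop = window.anchor + CORE_WIDTH - 1
    return replace(
        window,
        ss_core=_slice_padded(states, core_start, core_stop),
        ss_upstream=_slice_padded(states, core_start - FLANK_WIDTH, core_start),
        ss_downstream=_slice_padded(states, core_stop, core_stop + FLANK_WIDTH),
    )
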