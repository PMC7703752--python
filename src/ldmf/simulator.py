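"""Synthetic proteomes with ground-truth LD-motif implants and hard decoys.

The generator emulates the two site populations the detector must
separate: *implants* — consensus-derived LDXLLXXL 8-mers placed in a
helical secondary-structure context inside otherwise coil-like chains
(the signature of a real LD motif: a short helix in a disordered
region) — and *decoys* — 8-mers that match the same degenerate sequence
pattern but sit in a strand/coil context, emulating pattern-true
sequences buried in folded cores that make informative hard negatives.
Background residues are drawn i.i.d. from a SwissProt-like composition;
everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ldmf.io_formats import (
    LdmfError,
    ProteinRecord,
    SecondaryStructureTrack,
    write_fasta,
    write_ss_tracks,
)
from ldmf.windows import WindowInstance, attach_ss, extract_window

MOTIF_LEN = 8
#: degenerate slot classes of the canonical pattern; None = background draw
_SLOT_CLASSES: tuple[tuple[str, ...] | None, ...] = (
    ("L", "V"),
    ("D", "E"),
    None,
    ("L", "M"),
    ("L", "M"),
    None,
    None,
    ("L",),
)
#: margin kept between implanted sites and around termini
SITE_MARGIN = 25


@dataclass(frozen=True)
class SimulationConfig:
    n_proteins: int = 200
    length_range: tuple[int, int] = (200, 400)
    n_implants: int = 20
    n_decoys: int = 20
    #: per-slot probability of swapping to the alternate letter of the class
    epsilon: float = 0.1
    #: H run centred on the implanted core (>= core width 10)
    helix_context_length: int = 14
    background: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon < 0.5):
            raise ValueError("epsilon must be in [0, 0.5)")
        if self.helix_context_length < 10:
            raise ValueError("helix_context_length must cover the 10-mer core")


@dataclass(frozen=True)
class TruthSite:
    protein_id: str
    anchor: int  # 0-based L0 index of the implanted 8-mer
    core: str  # the 10-mer window -1..+8
    kind: str  # implant | decoy
    ss_context: str  # helical | strand_coil


@dataclass
class SimulationResult:
    proteins: list[ProteinRecord]
    tracks: dict[str, SecondaryStructureTrack]
    manifest: list[TruthSite]

    def manifest_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.protein_id, s.anchor, s.core, s.kind, s.ss_context)
                for s in self.manifest
            ],
            columns=["protein_id", "anchor", "core", "kind", "ss_context"],
        )

    def site_windows(self, kind: str | None = None) -> list[WindowInstance]:
        """Ground-truth windows with SS attached (implants labelled positive)."""
        by_id = {p.id: p for p in self.proteins}
        out = []
        for s in self.manifest:
            if kind is not None and s.kind != kind:
                continue
            w = extract_window(by_id[s.protein_id], s.anchor)
            w = replace(w, label="positive" if s.kind == "implant" else "negative")
            out.append(attach_ss(w, self.tracks[s.protein_id]))
        return out


def _draw_motif(rng: np.random.Generator, epsilon: float, letters: np.ndarray,
                probs: np.ndarray) -> str:
    out = []
    for slot in _SLOT_CLASSES:
        if slot is None:
            out.append(str(rng.choice(letters, p=probs)))
        elif len(slot) == 1:
            out.append(slot[0])
        else:
            out.append(slot[1] if rng.random() < epsilon else slot[0])
    return "".join(out)


def simulate(config: SimulationConfig = SimulationConfig()) -> SimulationResult:
    """Generate proteins, SS tracks and a truth manifest from *config*.

    Every implanted/decoy 8-mer matches the canonical degenerate pattern
    at its recorded anchor by construction; the two kinds differ only in
    their secondary-structure context.
    """
    rng = np.random.default_rng(config.seed)
    if config.background is None:
        from ldmf.resources import load_background_composition

        background = load_background_composition()
    else:
        background = dict(config.background)
    letters = np.array(sorted(background))
    probs = np.array([background[l] for l in letters])
    probs = probs / probs.sum()

    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_proteins)
    chains = [
        "".join(rng.choice(letters, p=probs, size=n)) for n in lengths
    ]

    # choose non-overlapping slots for all sites
    n_sites = config.n_implants + config.n_decoys
    slots: list[tuple[int, int]] = []  # (protein index, anchor)
    occupied: dict[int, list[int]] = {i: [] for i in range(config.n_proteins)}
    attempts = 0
    while len(slots) < n_sites:
        attempts += 1
        if attempts > 200 * n_sites:
            raise LdmfError(
                "cannot place all sites: too many sites for the configured "
                "protein number/lengths"
            )
        pi = int(rng.integers(config.n_proteins))
        n = int(lengths[pi])
        if n < 2 * SITE_MARGIN + MOTIF_LEN:
            continue
        anchor = int(rng.integers(SITE_MARGIN, n - SITE_MARGIN - MOTIF_LEN))
        if any(abs(anchor - a) < SITE_MARGIN for a in occupied[pi]):
            continue
        occupied[pi].append(anchor)
        slots.append((pi, anchor))

    kinds = ["implant"] * config.n_implants + ["decoy"] * config.n_decoys
    ss = [["C"] * int(n) for n in lengths]
    manifest: list[TruthSite] = []
    for (pi, anchor), kind in zip(slots, kinds):
        motif = _draw_motif(rng, config.epsilon, letters, probs)
        chain = chains[pi]
        chains[pi] = chain[:anchor] + motif + chain[anchor + MOTIF_LEN :]
        if kind == "implant":
            # H run centred on the 10-mer core
            extra = config.helix_context_length - 10
            start = anchor - 1 - extra // 2
            stop = start + config.helix_context_length
            state, context = "H", "helical"
        else:
            start, stop = anchor - 1, anchor + 9
            state, context = "E", "strand_coil"
        for i in range(max(start, 0), min(stop, len(ss[pi]))):
            ss[pi][i] = state
        manifest.append(
            TruthSite(
                protein_id=f"sim{pi:05d}",
                anchor=anchor,
                core=chains[pi][anchor - 1 : anchor + 9],
                kind=kind,
                ss_context=context,
            )
        )

    proteins = [
        ProteinRecord(id=f"sim{pi:05d}", sequence=chains[pi],
                      description="synthetic proteome chain")
        for pi in range(config.n_proteins)
    ]
    tracks = {
        p.id: SecondaryStructureTrack(protein_id=p.id, states="".join(ss[i]))
        for i, p in enumerate(proteins)
    }
    manifest.sort(key=lambda s: (s.protein_id, s.anchor))
    return SimulationResult(proteins=proteins, tracks=tracks, manifest=manifest)


def write_simulation(result: SimulationResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.proteins, outdir / "proteins.fasta")
    write_ss_tracks(
        [result.tracks[p.id] for p in result.proteins], outdir / "ss.plain3"
    )
    result.manifest_frame().to_csv(outdir / "manifest.tsv", sep="\t", index=False)
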