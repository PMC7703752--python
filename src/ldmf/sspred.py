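"""Built-in 3-state secondary-structure prediction.

A deliberately simple Chou-Fasman-style propensity predictor: each
residue is assigned the state (H/E/C) with the highest mean propensity
over a sliding window of half-width ``w`` (default 4). It exists so the
pipeline runs offline; per-residue prediction files from any external
predictor can be substituted via :func:`ldmf.io_formats.read_ss_track`
— downstream code only requires the ``ProteinRecord ->
SecondaryStructureTrack`` contract.

Ties break H > C > E: LD motifs are helical, so the helix-biased rule is
the conservative choice for this application.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ldmf.io_formats import CANONICAL_AA, ProteinRecord, SecondaryStructureTrack

#: tie-break priority (first wins on exact ties)
STATE_PRIORITY = ("H", "C", "E")


@dataclass(frozen=True)
class PropensityModel:
    helix: Mapping[str, float]
    strand: Mapping[str, float]
    coil: Mapping[str, float]
    window_half_width: int = 4

    def __post_init__(self) -> None:
        for name, table in (("helix", self.helix), ("strand", self.strand), ("coil", self.coil)):
            if set(table) != set(CANONICAL_AA):
                raise ValueError(f"{name} propensities must cover the 20 amino acids")
            if any(v <= 0 for v in table.values()):
                raise ValueError(f"{name} propensities must be strictly positive")


def default_propensity_model(window_half_width: int = 4) -> PropensityModel:
    """The bundled Chou-Fasman-style model."""
    from ldmf.resources import load_ss_propensities

    df = load_ss_propensities()
    return PropensityModel(
        helix=df["helix"].to_dict(),
        strand=df["strand"].to_dict(),
        coil=df["coil"].to_dict(),
        window_half_width=window_half_width,
    )


def _propensity_array(seq: str, table: Mapping[str, float]) -> np.ndarray:
    mean = sum(table.values()) / len(table)
    return np.array([table.get(c, mean) for c in seq])


def predict_ss(
    protein: ProteinRecord, model: PropensityModel | None = None
) -> SecondaryStructureTrack:
    """Per-residue argmax of sliding-window mean propensities.

    Deterministic and local: residue i's state depends only on residues
    within ``i +/- window_half_width``.
    """
    if model is None:
        model = default_propensity_model()
    seq = protein.sequence
    w = model.window_half_width
    n = len(seq)

    means = {}
    for state, table in (("H", model.helix), ("E", model.strand), ("C", model.coil)):
        arr = _propensity_array(seq, table)
        csum = np.concatenate(([0.0], np.cumsum(arr)))
        lo = np.maximum(np.arange(n) - w, 0)
        hi = np.minimum(np.arange(n) + w + 1, n)
        means[state] = (csum[hi] - csum[lo]) / (hi - lo)

    states = []
    for i in range(n):
        best = max(STATE_PRIORITY, key=lambda s: (means[s][i], -STATE_PRIORITY.index(s)))
        states.append(best)
    return SecondaryStructureTrack(protein_id=protein.id, states="".join(states))
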