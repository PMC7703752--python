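"""Regenerate the bundled synthetic positive-set fixture.

Produces ``src/ldmf/data/positive_set_synthetic.{fasta,tsv}``: a
synthetic stand-in for the initial LD-motif positive training set — 18
motif sites on 6 carrier proteins (4 each on four paxillin-family-like
carriers, 1 on a DLC1-like carrier, 1 on a RoXaN-like carrier).

The motif cores are fixed constants: where a source peptide sequence is
published (paxillin LD1/LD2/LD4, the leupaxin LD1 consensus, the
calpastatin and LPP assay peptides) the core is taken from it; the
remaining cores instantiate the canonical LDXLLXXL consensus with varied
wildcard residues. Two of the 18 are deliberately divergent (one
position-+4 Ile variant, one inverse-orientation motif), mirroring the
heterogeneity of experimentally confirmed LD motifs. Carrier scaffolds
are i.i.d. draws from a coil-biased composition — they are NOT real
protein sequences, only a disordered-like context for the implants.

Deterministic: rerunning reproduces the bundled files byte-for-byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

OUT_DIR = Path(__file__).resolve().parent.parent / "src" / "ldmf" / "data"
SEED = 20_260_918

# coil-biased filler composition (no L/M/V: the filler should carry no
# spurious motif anchors)
FILLER = {
    "G": 0.15, "S": 0.15, "P": 0.12, "N": 0.10, "D": 0.10, "T": 0.10,
    "Q": 0.08, "K": 0.08, "E": 0.05, "R": 0.05, "A": 0.02,
}

# carrier -> (length, [(anchor, core-10mer)])
DESIGN = {
    "PXN": (260, [(30, "DLDALLADLE"), (80, "ELDRLLLELN"),
                  (144, "ELDELMASLS"), (200, "SLDRLLQELE")]),
    "LPXN": (250, [(28, "ELDSLLQELE"), (85, "ALDELLDSLK"),
                   (150, "ELDALMSELR"), (210, "TLDSLLADLQ")]),
    "TGFB1I1": (245, [(35, "ELDDLMAQLS"), (90, "QLDGLLAELE"),
                      (148, "AVDELLHSLD"), (205, "ELESLLMRLQ")]),
    "PAXB": (240, [(30, "NLDSLLSDLE"), (88, "SLDELLNNLG"),
                   (145, "ELDKLMDSLS"), (202, "TVDDLLSTLE")]),
    "DLC1": (130, [(60, "ALDDLIDTLG")]),   # divergent: Ile at +4
    "ROXAN": (110, [(45, "SLTSILADLE")]),  # inverse-orientation motif
}


def main() -> None:
    rng = np.random.default_rng(SEED)
    letters = np.array(sorted(FILLER))
    probs = np.array([FILLER[l] for l in letters])
    probs = probs / probs.sum()

    fasta_lines = []
    tsv_lines = ["protein_id\tanchor\tcore\tlabel"]
    for pid, (length, sites) in DESIGN.items():
        chain = list("".join(rng.choice(letters, p=probs, size=length)))
        for anchor, core in sites:
            assert len(core) == 10
            chain[anchor - 1 : anchor + 9] = core
            tsv_lines.append(f"{pid}\t{anchor}\t{core}\tpositive")
        seq = "".join(chain)
        for anchor, core in sites:
            assert seq[anchor - 1 : anchor + 9] == core
        fasta_lines.append(f">{pid} synthetic stand-in carrier (not a real protein)")
        fasta_lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))

    (OUT_DIR / "positive_set_synthetic.fasta").write_text("\n".join(fasta_lines) + "\n")
    (OUT_DIR / "positive_set_synthetic.tsv").write_text("\n".join(tsv_lines) + "\n")
    print(f"wrote fixture to {OUT_DIR}")


if __name__ == "__main__":
    main()
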