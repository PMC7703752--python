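# ldmf — LD motif finder

`ldmf` detects **LD motifs** — leucine-aspartate short linear interaction
motifs with the canonical consensus `LDXLLXXL` — in protein sequences and
whole proteomes. LD motifs form short amphipathic helices inside disordered
regions of adaptor proteins (paxillin, leupaxin, Hic-5, DLC1, …) and dock
onto LD-motif binding domains such as the FAT domain of focal adhesion
kinase. The naive degenerate search pattern `(L,V)(D,E)X(L,M)(L,M)XXL` is
necessary but wildly unspecific (thousands of hits per proteome), so this
package frames detection as supervised classification of candidate windows.

It is aimed at computational biologists studying SLiM-mediated interaction
networks who need a trainable, inspectable motif detector that runs offline.

## Method

Each candidate is a 10-residue core anchored on the motif's first leucine
(L⁰; core spans L⁰-relative positions −1..+8) plus 20-residue flanks. A
candidate is encoded as a 36-dimensional vector (layout `ldmf-v1`):

* **6 PWM log-odds scores** — {sequence, 3-state secondary structure} ×
  {core, upstream flank, downstream flank}. PWMs are Laplace-smoothed
  (pseudocount 1) column-stochastic matrices built from the positive set
  only, scored as Σⱼ ln(p(aⱼ, j)/bg(aⱼ)) against a SwissProt-like
  background.
* **30 physicochemical values** — hydrophobicity (KYTJ820101), residue
  volume (GRAR740103) and net charge (KLEP840101) for each core position.

An RBF-kernel SVM (C = 1, γ = 1/36, class weights inversely proportional
to class frequency) is trained on z-standardized vectors. Training follows
a three-round active-learning protocol: round 1 uses random proteome
windows as negatives; round 2 adds *hard negatives* mined from a decoy
pool (pattern-true sites in the wrong structural context that the round-1
model ranks highly); round 3 adds experimentally validated hits to the
positive set. Evaluation is leave-one-out over the positive set with
negatives scored out-of-fold (10-fold).

Secondary structure comes from external predictions (PSIPRED `.ss2` or a
FASTA-like 3-state format) or, offline, from a built-in Chou–Fasman-style
propensity predictor. A synthetic-proteome generator with a ground-truth
manifest (helical implants vs strand-context decoys) makes every stage
testable without downloads.

## Worked example

Scan the bundled assay peptides with the degenerate pattern baseline:

```bash
$ ldmf pattern --fasta src/ldmf/data/printed_peptides.fasta --out out/
5 pattern match(es) in 20 sequence(s) -> out/pattern_hits.tsv
```

`pattern_hits.tsv` contains, among others, `LD2  4  LDRLLLEL` and
`LD4  8  LDELMASL` — the known paxillin LD2/LD4 motif cores at their L⁰
offsets — and no row for the scrambled control peptide.

Train and evaluate on a synthetic world with known ground truth:

```bash
$ ldmf simulate --seed 42 --n-proteins 60 --n-implants 8 --n-decoys 8 --out sim/
wrote 60 proteins, 16 truth sites -> sim/
$ awk -F'\t' 'NR==1{print "protein_id\tanchor\tcore\tlabel"}
    NR>1 && $4=="implant"{print $1"\t"$2"\t"$3"\tpositive"}' \
    sim/manifest.tsv > sim/sites.tsv
$ ldmf eval --fasta sim/proteins.fasta --sites sim/sites.tsv \
    --ss plain3:sim/ss.plain3 --n-negatives 300 --seed 1 --out eval/
LOOCV: sensitivity 1.0000, specificity 0.9967, accuracy 0.9968 -> eval/metrics.json
```

(`sites.tsv` is the implant rows of `sim/manifest.tsv` relabelled
`positive`. Sensitivity is the fraction of left-out motifs the retrained
model recovers — on this small clean world all 8; the one spurious
positive among 300 negative windows gives the 0.9967 specificity.)

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline end to end from the given seed — a synthetic
proteome scan with the degenerate pattern, two-round active-learning
training with held-out site recovery, and leave-one-out cross-validation
of the bundled 18-site positive fixture against ~10,000 proteome-drawn
negatives — logging the measured quantities to stderr and writing the
results JSON to `--out`.

## Layout

| path | contents |
| --- | --- |
| `src/ldmf/io_formats.py` | FASTA / ss2 / plain-3-state / TSV readers and writers |
| `src/ldmf/windows.py` | candidate enumeration, core/flank extraction, SS attachment |
| `src/ldmf/features.py` | PWMs, log-odds scoring, physicochemical profiles |
| `src/ldmf/sspred.py` | built-in propensity-based 3-state SS predictor |
| `src/ldmf/classifier.py` | SVM training, active learning, LOOCV, model bundles |
| `src/ldmf/scanner.py` | proteome scanning, pattern baselines, overlap suppression |
| `src/ldmf/simulator.py` | synthetic proteomes with truth manifests |
| `src/ldmf/cli.py` | `ldmf` command-line tool |
| `docs/methods.md` | model assumptions, defaults, numerical choices |
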