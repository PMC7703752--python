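# Methods

## Problem framing

LD motifs are ~8-residue SLiMs (consensus `LDXLLXXL`) that fold into an
amphipathic helix only in complex with an LD-motif binding domain. Sequence
pattern matching alone is hopeless as a detector: the degenerate pattern
`(L,V)(D,E)X(L,M)(L,M)XXL` fires thousands of times per proteome, mostly
inside folded cores where the sequence plays a structural role rather than
acting as an interaction element. Detection therefore combines three signal
sources over a candidate window — sequence composition, predicted secondary
structure of the motif and its surroundings, and the physicochemical
profile of the core — under a binary classifier.

A candidate window is a 10-mer core anchored on the motif's first leucine
(L⁰). The core covers L⁰-relative positions −1..+8: structural analyses
show the residues immediately before L⁰ and after L⁺⁷ can contact the
binding domain, so one residue is added on each side of the 8-mer. Flanks
of 20 residues on either side carry the structural-context signal (a real
LD motif is a short helix inside a disordered region). Windows at the
termini are padded with `-`, which is a first-class alphabet letter
throughout so terminal motifs remain scorable.

## Features (layout `ldmf-v1`, 36 dimensions)

1. **Six PWM log-odds scores.** {sequence, secondary structure} × {core,
   upstream, downstream}. Each PWM is built from the positive windows only,
   with Laplace pseudocount 1 over its alphabet (20 amino acids + pad, or
   H/E/C + pad). Scores are natural-log odds against a background:
   SwissProt-like composition for sequence, the empirical state frequencies
   of the training negatives for secondary structure. Probabilities are
   floored at 1e−9 before logs, so scores stay finite even with zero
   pseudocount. Unknown residues (X) are neither counted nor scored.
2. **Thirty physicochemical values.** Hydrophobicity (Kyte–Doolittle,
   KYTJ820101), residue volume (Grantham, GRAR740103) and net charge
   (KLEP840101) for each of the 10 core positions, per position rather than
   aggregated. X and pad map to the scale mean. The exact scales are
   configurable; these three are bundled defaults standing in for the
   unspecified AAindex entries of the original study.

Two numerical choices deserve emphasis:

* **Background shrinkage.** The secondary-structure background is shrunk
  toward uniform (λ = 0.25). Without this, a state that is merely *rare*
  among the negatives (e.g. strand in a mostly-coil training pool) makes
  every occurrence of that state look like strong motif evidence — an
  all-strand decoy core scored almost as high as a helical motif core on
  the helix PWM purely through the background denominator.
* **Jackknifed training features.** PWM-score features of each training
  positive are computed with that window *left out* of the PWM counts
  (negatives and deployment scoring always use the full positive-set
  PWMs). In-sample PWM scores are optimistically shifted — each window
  partly scores its own counts — so without the jackknife the SVM learns a
  "positive" region that unseen motifs never reach; held-out recall on the
  synthetic benchmark roughly doubles with this correction. The feature
  scaler is still fitted on deployment-consistent (full-PWM) features so
  that features which are constant at deployment cannot acquire phantom
  variance from the jackknife offset. The correction is skipped for sets
  of ≤ 2 positives and can be disabled in the training config.

## Classifier and training protocol

RBF-kernel SVM, C = 1, γ = 1/36, on z-standardized features, class weights
inversely proportional to class frequency (scikit-learn `balanced`). These
are deliberately plain defaults: with tens of positives there is nothing to
tune on, and the SVM depends only on its support vectors, which makes it
robust to the undefined negative-class distribution. All values are exposed
in `TrainConfig`.

Active learning runs three rounds:

1. **Random negatives.** Leucine-anchored windows drawn uniformly from the
   proteome, excluding known sites. Default 2,000.
2. **Hard negatives.** A decoy pool (in production: pattern-matching
   sequences from folded structures; in testing: the simulator's decoys) is
   scored by the round-1 model; members at or above the 0.9 score quantile
   join the negatives. The round-2 negative set is the union of the round-1
   negatives and the mined decoys — the harder set refines the boundary
   without forgetting what ordinary background looks like.
3. **Validated positives.** Externally confirmed hits are added to the
   positive set; the negative pool is carried over (minus any window
   promoted to positive).

Ortholog expansion of the positive set is intentionally out of scope
(homology search is an external tool); ortholog-derived positives enter as
ordinary motif-site TSV rows.

## Evaluation

Leave-one-out cross-validation over the positive set: each positive is held
out, everything (PWMs, scaler, SVM) is retrained, and the held-out window
is scored. Negatives enter the confusion matrix via 10-fold models trained
with all positives, so every negative is also scored by a model that never
saw it. A pure leave-one-sample-out scheme is available for small sets
(`loocv_scheme="loo_all"`). With negatives vastly outnumbering positives,
accuracy is dominated by true negatives; sensitivity is the informative
number.

## Secondary-structure prediction

The production path is external per-residue predictions (PSIPRED `.ss2` or
a FASTA-like 3-state file). For offline operation a Chou–Fasman-style
predictor is bundled: per-residue argmax of mean helix/strand/coil
propensities over a sliding window (half-width 4), ties broken H > C > E
(helix-biased, since the motifs of interest are helical). It is
deterministic, local, and deliberately crude — the classifier contract only
needs *some* 3-state track, and any callable `ProteinRecord →
SecondaryStructureTrack` can be substituted.

## Scanner

Proteome scanning enumerates leucine-anchored windows by default (every
10-mer in exhaustive mode, e.g. to score inverse-orientation candidates),
featurizes them under a trained bundle, and keeps windows with decision
score above the threshold (default 0, the SVM margin). Within a protein,
overlapping cores are greedily suppressed keeping the highest-scoring
window; the per-protein maximum is never discarded. Hits carry two
exploratory flags: the canonical degenerate pattern and an
inverse-orientation (class II) pattern `L..[ILM][ILM].[DE][LV]` — the
canonical pattern read C-to-N with the mid-helix hydrophobic class widened
to include Ile, which experimentally confirmed inverse motifs (LPP,
CCDC158) use at those slots. The inverse flag is reporting-only and never
feeds training.

## Synthetic data

The simulator emulates the two populations the detector must separate, not
real protein evolution:

* background chains drawn i.i.d. from a SwissProt-like composition
  (default 200 proteins of 200–400 residues);
* 20 **implants**: consensus-derived 8-mers (degenerate slots swapped to
  their alternate class letter with probability ε = 0.1, wildcards drawn
  from background) with a 14-residue helix context centred on the core,
  coil elsewhere — the signature of a real motif;
* 20 **decoys**: 8-mers from the same sequence generator placed in strand
  context — pattern-true/context-false sites emulating folded-core matches
  that make informative hard negatives.

Sites are placed ≥ 25 residues apart and away from termini; everything is
reproducible byte-for-byte from the seed. Secondary structure for
simulated proteins is *generated*, not predicted, so classifier tests
isolate the learning machinery from the built-in predictor (tests that
want the integrated path simply run `predict_ss` on the simulated chains).

What a green synthetic test does **not** establish: performance on real
proteomes, where composition is non-i.i.d. (coiled coils and Leu-rich
regions enrich the pattern ~20-fold over the i.i.d. expectation), flanks
carry correlated signal, and secondary-structure predictions are noisy.

## Bundled positive-set fixture

The initial positive set of the original study — 18 experimentally
confirmed motifs from 6 proteins (4–5 per paxillin-family protein, one
each from DLC1 and RoXaN) — cannot be redistributed as full UniProt
sequences here, so the package bundles a *synthetic stand-in* with the
same bookkeeping: 18 sites on 6 carrier chains. Cores are taken from
published peptide sequences where printed (paxillin LD1/LD2/LD4, the
leupaxin LD1 consensus, the calpastatin and LPP assay peptides) and
instantiate the canonical consensus otherwise; two of the 18 are
deliberately divergent (a +4 Ile variant and an inverse-orientation
motif), mirroring the heterogeneity of confirmed LD motifs. Carrier
scaffolds are coil-biased random filler, free of L/M/V so they introduce
no spurious anchors. Leave-one-out results on this fixture are a
plausibility check of the machinery at realistic class imbalance, not a
reproduction of the original training data.

## Known limitations

* The built-in SS predictor is far weaker than modern predictors; use
  external `.ss2` files for real scans.
* Flank PWMs carry little signal when positives are few and flanks
  diverse; they are retained for parity with the feature layout.
* The scanner's Python featurization handles hundreds of proteins
  comfortably but is not engineered for repeated whole-proteome scans.
* Motif width is fixed at 10; no gaps, no width search, no HMM.
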