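# Methods

## Input encoding

A protein of length L is represented as an L×30 real matrix. Columns
0–19 hold the PSI-BLAST position-specific log-odds scores in the ASCII
dialect's fixed residue order (A R N D C Q E G H I L K M F P S T W Y V),
squashed elementwise by the logistic function σ(x) = 1/(1+e^(−x)).
Columns 20–29 hold the 10 Kidera factors of the residue letter. The
Kidera table packaged in `submito._kidera` is the published one (Kidera
et al., J. Protein Chem. 4, 1985: ten near-orthogonal factors distilled
from 188 physico-chemical properties); each factor is zero-mean and
unit-variance across the 20 standard residues, which the test suite
verifies against the packaged constant.

Two choices here are conventions rather than forced:

* **Profile squashing.** Logistic squashing of raw log-odds is the
  standard way to feed PSSMs to a network; it is strictly monotone,
  bounds the channels in (0, 1), and maps a zero score to 0.5. The
  squash function is a parameter of `encode_protein` for anyone who
  prefers a different normalization.
* **Non-standard residues.** X, B, Z, U and O are accepted on input
  (flagged with a warning); they encode with the all-zero Kidera vector
  and whatever profile row the PSSM supplies. Zero is the neutral value
  for factors constructed to be zero-mean.

No length cap or padding is applied at encoding time; variable length is
the model's concern.

## Network

1D convolution with 256 filters of width 19, stride 1 and symmetric zero
padding of 9, so an L-row input produces an L×256 feature map (ReLU);
global max pooling and global average pooling applied in parallel over
the sequence axis and concatenated into a 512-vector; a dense ReLU layer
of 256 units; a 4-way softmax. The predicted compartment is the argmax,
with ties broken toward the lowest class index (a determinism contract —
ties are measure-zero in practice).

The network is implemented directly on NumPy with analytic gradients
(the convolution as an im2col matrix product), verified in the test
suite by central finite differences. Sequences are processed one at a
time at their native length, which keeps the "feature map has exactly L
rows" semantics without any padding-and-masking machinery; minibatches
only average gradients. At the problem sizes this package targets
(hundreds of proteins, lengths up to a few thousand) this is fast enough
that a deep-learning framework would buy nothing but a dependency.

### Training defaults and rationale

| parameter | default | why |
|---|---|---|
| loss | categorical cross-entropy | standard for softmax classifiers |
| class weights | inverse frequency, mean 1 | the compartments are heavily imbalanced in real data; weighting keeps the minority classes (intermembrane space above all) from being ignored |
| optimizer | Adam, lr 1e-3 | conventional for this architecture size |
| epochs | 100 | synthetic classes converge well before this; early stopping (patience 10 on validation loss, best weights restored) applies when a validation set is passed |
| batch size | 16 | gradient averaging only; no effect on the length semantics |
| initialization | He (ReLU layers), seeded | reproducibility: same seed ⇒ identical loss trace on the same platform |

Multi-localized proteins are outside the label space: the model is a
single-compartment classifier by construction.

## Evaluation

Per-compartment scoring binarizes the 4×4 confusion matrix one-vs-rest
and computes the Matthews correlation coefficient. When the denominator
vanishes (a class absent from truth or from predictions) the value is
defined as 0 — the conventional choice that keeps a per-class report
total. MCC is identically the Pearson correlation of the two indicator
vectors; the suite asserts agreement with that independent oracle to
1e-10.

Cross-validation uses stratified folds (each class split as evenly as
possible, seed-controlled shuffling via scikit-learn), and pooled
per-class MCC is computed on the sum of the per-fold confusion matrices.
A class with fewer members than folds is an error, with the remedy named.

## Mitochondrial screening

The 2-of-3 majority rule over boolean votes from three external
predictors. Exactly three votes are required; proteins with missing
votes are excluded and reported rather than imputed — imputation would
silently change the rule. Adapters for the tools' native output formats
are intentionally out of scope: the tools are web services/binaries, and
this package consumes their tabulated verdicts.

## Annotation transfer

* **Alignment**: exact Smith–Waterman under BLOSUM62 with the BLAST
  protein gap costs (a gap of length g costs 11 + g, i.e. Biopython's
  `open_gap_score=-12, extend_gap_score=-1`). An exact aligner replaces
  a heuristic search engine because inputs are desk-scale; the
  thresholds, not the engine, define the method.
* **Identity** = identities / alignment columns × 100 (gaps count as
  columns). **Coverage** = the alignment's span on the shorter sequence
  / that sequence's length × 100. "Fraction of the alignment" is
  ambiguous between query, subject and columns; the shorter-sequence
  span is the strictest symmetric reading, keeps coverage in [0, 100],
  and both thresholds are configurable.
* **Clustering**: an edge joins a pair iff identity > 40 (strict) and
  coverage ≥ 90 (inclusive) — the wording "more than" vs "at least"
  taken literally; components under single linkage form the clusters,
  everything else is a singleton. Clusters partition the input.
* **Enrichment**: for each GO term observed in a cluster, a one-sided
  Fisher exact test (hypergeometric upper tail P(X ≥ k)) of the term's
  frequency among cluster members against the annotation universe
  (proteins carrying ≥ 1 annotation in the background pool, plus the
  cluster members). One-sided because only over-representation licenses
  transfer. The Bonferroni divisor is the number of terms tested in that
  cluster, the natural per-cluster scope; significance is p ≤ 0.01/m.
  No minimum number of annotated members is imposed beyond k ≥ 1.
* **Transfer**: each significant term is assigned to every cluster
  member not already carrying it, with source `BAR` and an electronic
  evidence code. Transfer never removes or duplicates an existing
  annotation.
* **Merging**: per (protein, term, aspect) the best of three evidence
  tiers survives: `GOA_manual` > `GOA_IEA` > `BAR`. Finer ECO-code
  ordering inside the manual tier is out of scope.

## Synthetic data

The generators define the study conditions under which the toolkit is
validated:

* **Proteomes** (`generate_proteome`): background sequences uniform over
  the 20 residues, lengths uniform in 60–120, with one 11-mer consensus
  motif per compartment planted at a random position and point-mutated
  at rate 0.1. The signal is motif-shaped — not compositional — so the
  19-wide convolution filters are what must detect it; a dataset of
  60 proteins per class is the default training condition, 30 per class
  for held-out scoring.
* **Profiles** (`generate_pssm`): +7 log-odds on the observed residue,
  Gaussian-perturbed negatives (mean −2, sd = `pssm_noise`, default 1)
  elsewhere, integer-rounded — the shape, not the statistics, of an
  iterative-search PSSM. Profiles are written and re-read through the
  ASCII PSSM codec so the parser is exercised on every run.
* **GO worlds** (`generate_go_world`): 3 families of 8 point-mutants
  (5% per site) of random 120-residue founders over a 200-protein
  background; one planted term per family at frequency 0.9 inside /
  0.05 outside, 10 decoy terms at 0.2 everywhere. With these gaps the
  planted terms must pass the Bonferroni test and the decoys must not.

What the synthetic data does **not** emulate — and hence what passing
tests do not show about real data: real targeting peptides and membrane
anchors (compartment signals in nature are positional and compositional,
not exact motifs), realistic PSSM column correlations, homology
structure between compartments, multi-localized proteins, and GO's
ontology graph (terms here are independent labels; no ancestor
propagation). Held-out MCC of 1.0 on planted motifs is a capacity and
plumbing check, not a claim about biological accuracy.

## Numerical choices and degenerate inputs

* Logistic squashing is evaluated directly on integer log-odds; no
  overflow is possible at PSSM magnitudes.
* Softmax subtracts the max before exponentiation.
* A local alignment with no positive-scoring path yields a zero hit
  (identity 0, coverage 0) rather than an error.
* Hypergeometric p-values come from `scipy.stats.hypergeom.sf`, clipped
  to [0, 1]; the suite checks them against exact rational enumeration on
  all universes ≤ 30 to 1e-10.
* MCC with a zero denominator is 0 (above).
* Empty FASTA files parse to an empty list with a warning; duplicated
  ids, malformed GO ids, aspects outside {BP, MF}, unknown tools or
  sources, and duplicate (protein, tool) votes are hard errors.

## Pipeline problem sizes

The default end-to-end run (`submito-kit pipeline`) and the acceptance
script use the study conditions above: 240 training proteins, 120 test
proteins, 100 epochs (about two minutes of CPU), and the 224-sequence GO
world (about 25 000 pairwise alignments, under a minute). One global
seed fans out to per-stage seeds by fixed offsets so any stage can be
reproduced in isolation.

## Known limitations

* The predictor is validated on synthetic signals only; no pretrained
  weights for real proteomes ship with the package.
* The per-protein NumPy implementation trains serially; very large
  training sets (tens of thousands of proteins) would warrant a
  framework-backed backend behind the same interfaces.
* All-against-all alignment is quadratic; clustering beyond a few
  thousand sequences needs a prefilter.
* GO aspects are restricted to BP and MF, and terms are treated as
  independent — no true-path propagation over the ontology.
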