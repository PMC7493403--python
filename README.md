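# submito

A toolkit for sub-mitochondrial protein localization analysis. It is aimed
at computational biologists who need to (i) predict which of the four
mitochondrial compartments — outer membrane, inner membrane, intermembrane
space, matrix — a protein resides in, (ii) screen whole proteomes for
putative mitochondrial proteins by combining external localization
predictors, and (iii) extend sparse GO annotation by statistically
controlled transfer across clusters of similar sequences. Every stage is
exercisable end to end on synthetic data, so the full pipeline can be
validated without any external database.

## What it computes

**Compartment predictor.** A protein of length L is encoded as an L×30
matrix: 20 channels from its position-specific scoring matrix (PSSM,
PSI-BLAST ASCII dialect), squashed elementwise by the logistic
σ(x) = 1/(1+e^(−x)), plus the 10 Kidera physico-chemical factors of each
residue. A 1D convolutional network maps this input to compartment
probabilities:

    L×30 input
      → 1D convolution, 256 filters of width 19, stride 1,
        zero-padded so the feature map is L×256 (ReLU)
      → global max pooling ∥ global average pooling  (256 + 256 = 512)
      → dense layer, 256 hidden units (ReLU)
      → 4-way softmax; prediction = argmax

Performance is scored with the one-vs-rest Matthews correlation
coefficient per compartment,

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

under stratified k-fold cross-validation — the metric of choice when the
compartments are as imbalanced as they are in real proteomes.

**Mitochondrial screening.** Boolean mitochondrial calls from three
external tools (BUSCA, TargetP-2.0, MitoFates — consumed as tabulated
votes, never re-run) are combined by simple majority: a protein is called
mitochondrial iff at least 2 of the 3 tools agree.

**Annotation transfer.** Sequences are pairwise locally aligned
(Smith–Waterman, BLOSUM62, gap open 11 / extend 1) and joined by single
linkage whenever identity > 40% with coverage ≥ 90%. Within each cluster,
every observed GO term is tested for over-representation with a one-sided
Fisher exact test, Bonferroni-corrected per cluster at the 1% level;
significant terms are transferred to the unannotated members. Merging
annotation pools keeps, per (protein, term, aspect), the entry with the
best evidence tier: manually curated > electronically inferred >
transferred.

## Worked example

Train the predictor on a motif-planted synthetic proteome and score a
held-out set:

```python
from submito import (SyntheticSpec, generate_proteome, ModelConfig,
                     TrainConfig, build_model, train, predict)
from submito.synthetic_data import generate_profiles
from submito.encoding import encode_protein
from submito.evaluation import confusion, all_class_mcc
from submito.cnn_model import predict_many

def encode(spec, seed):
    labelled = generate_proteome(spec)
    records = [r for r, _ in labelled]
    profiles = generate_profiles(records, seed=seed)
    return [(encode_protein(r, profiles[r.id]), lab) for r, lab in labelled]

train_set = encode(SyntheticSpec(n_per_class=30, seed=0), 100)
test_set = encode(SyntheticSpec(n_per_class=10, seed=1), 200)

model = build_model(ModelConfig(seed=0))
model, history = train(model, train_set, TrainConfig(epochs=60, seed=0))
print(f"final training loss: {history[-1]:.4f}")

preds = predict_many(model, [e for e, _ in test_set])
cm = confusion(preds, [(e.protein_id, lab) for e, lab in test_set])
for label, mcc in all_class_mcc(cm).items():
    print(f"held-out MCC {label.name}: {mcc:.2f}")

one = predict(model, test_set[0][0])
print(one.protein_id, "->", one.label.name,
      [round(float(p), 3) for p in one.probabilities])
```

Output:

```
final training loss: 0.0004
held-out MCC outer_membrane: 1.00
held-out MCC inner_membrane: 1.00
held-out MCC intermembrane_space: 1.00
held-out MCC matrix: 1.00
outer_membrane_0000 -> outer_membrane [0.979, 0.011, 0.004, 0.006]
```

The training loss has collapsed on the separable synthetic classes, the
held-out MCC is 1.0 for all four compartments (the planted motifs are
fully recoverable by 19-wide filters), and the single prediction shows
the calibrated probability vector behind the argmax label.

The same stages are available from the shell:

```sh
submito-kit pipeline --workdir run1 --seed 1      # simulate → … → annotate
submito-kit screen   --workdir run1               # re-run one stage
```

Each stage writes its artifacts plus a manifest (input hashes, config
hash, stage seed) under the work directory.

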