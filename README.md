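# orf2pep

Two-stage prediction of functional peptides from prokaryotic and
metagenomic DNA: **(1)** find protein-coding open reading frames with a
multi-feature-fusion CNN + Transformer-encoder classifier and greedy
overlap resolution, **(2)** translate the retained genes and classify the
peptides as anticancer/antimicrobial (ACP/AMP) candidates with a
dual-channel CNN/BiLSTM model, then profile their physicochemical
properties.

It is written for computational biologists who want an offline,
end-to-end, fully reproducible pipeline: every stage trains and tests on
synthetic data generated by the package itself, so no database downloads
or pretrained weights are required.

## The models

**Gene stage.** Candidate ORFs (starts ATG/CTG/GTG/TTG, stops
TAA/TAG/TGA, ≥ 60 bp, six frames, metagenome-style completeness classes)
are standardized to 700 bp and encoded as

X = [X_ORF, X_MC, X_DC, X_TIS, X_ORFL, X_GC, X_baseC],

the concatenation of the flattened one-hot matrix (700×4), monocodon
usage (64), dicodon usage (4096), a translation-initiation-site PWM
log-odds score, normalized ORF length, GC content and base composition —
6,967 values.  The classifier is

conv(64,k3) → pool(2) → conv(200,k3) → pool(2) → dropout → flatten →
fc(→4096) → Transformer encoder (8 heads) → fc(4096→128) → dropout(0.2)
→ fc(128→1) → sigmoid,

trained with binary cross-entropy (Adam, lr 10⁻³, batch 32, minority
oversampling), with a 10-bucket GC-content model library for
pretrain/fine-tune workflows.  Overlapping predictions are resolved
greedily: keep the highest-probability candidate, discard anything
overlapping it by more than 60 bp.

**Peptide stage.** Peptides are tokenized over a 26-token vocabulary
(20 residues, X, and [PAD]/[UNK]/[CLS]/[SEP]/[MASK]) and embedded by a
pluggable provider (trainable lookup by default; any external protein
language model via a one-function contract).  Two channels — a
conv(256→128→64, k3) stack with masked average pooling, and a BiLSTM
whose forward/backward final states are concatenated — feed a
batch-normalized three-layer MLP with a sigmoid output (BCE, Adafactor,
early stopping; one model per task).  Predicted candidates are profiled
with eight physicochemical properties (GRAVY, molecular weight,
aromaticity, instability index, pI, net charge at pH 7, Boman index,
Trp content).

Both neural stages run on a compact numpy layer library with
reverse-mode autodiff included in the package (`orf2pep.nn`); every
gradient is finite-difference-verified in the test suite.  See
`docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```bash
python examples/02_train_gene_model.py
```

```
1750 candidates, 113 coding
epoch  1  loss 0.9060  train acc 0.689
epoch  4  loss 0.4563  train acc 0.783
epoch  7  loss 0.2501  train acc 0.894
epoch 10  loss 0.0129  train acc 1.000
held-out balanced accuracy: 0.904
mean p(coding):   true genes 0.892  spurious ORFs 0.079
```

A 30 kb synthetic genome with 25 codon-biased genes yields 1,750
candidate ORFs in all-starts mode, 113 of them coding; after ten epochs
the classifier assigns held-out true genes a mean coding probability of
0.89 against 0.08 for spurious ORFs — the codon-usage contrast the fused
features are designed to expose (thirty epochs, as in
`scripts/acceptance.py`, push balanced accuracy above 0.95).  The
other scripts in `examples/` cover scanning (`01`), peptide
classification (`03`), physicochemical profiling (`04`) and the full
genome→peptide chain (`05`).

The same pipeline is available as a CLI (`orf2pep simulate-genome`,
`scan`, `featurize`, `train-gene`, `predict-genes`, `translate`,
`train-pep`, `predict-pep`, `physchem`, `evaluate`), writing standard
FASTA/GFF3/BED/TSV; the whole chain is byte-reproducible for a fixed
`--seed`.

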