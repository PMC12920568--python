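"""Full pipeline: genome -> gene calls -> peptides -> ACP scores -> profile.

Runs both stages on synthetic data: trains the gene model on one genome,
predicts genes with greedy overlap resolution, translates the retained
calls, classifies the translated peptides with a peptide model trained on
a simulated ACP-style set, and profiles the predicted positives.
"""

import numpy as np

from orf2pep.feature_encoder import FeatureEncoder
from orf2pep.gene_model import (GeneModelConfig, evaluate_calls, greedy_resolve,
                                predict_orfs, train_gene_model)
from orf2pep.metrics import precision, sensitivity
from orf2pep.orf_scanner import scan_orfs
from orf2pep.peptide_model import (PeptideModelConfig, predict_peptides,
                                   train_peptide_model)
from orf2pep.physchem import profile_peptides
from orf2pep.seqio import PeptideRecord, translate_orf
from orf2pep.synthetic_data import (GenomeSimSpec, PeptideSimSpec,
                                    make_orf_dataset, simulate_genome,
                                    simulate_peptides)

# --- stage 1: gene prediction --------------------------------------------
record, truth = simulate_genome(GenomeSimSpec(length=25_000, n_genes=20, seed=3))
candidates, labels = make_orf_dataset(scan_orfs(record), truth)
encoder = FeatureEncoder().fit_tis(
    [c for c, l in zip(candidates, labels) if l == 1], [record.sequence])
X = encoder.encode_matrix(candidates)
gene_model = train_gene_model(X, labels, GeneModelConfig.desk(seed=3, max_epochs=8))

scored = predict_orfs(gene_model, candidates, X)
calls = greedy_resolve(scored, overlap_threshold=60, min_prob=0.5)
counts = evaluate_calls(calls, truth, all_candidates=candidates)
print(f"gene calls: {len(calls)}  Sn {sensitivity(counts):.2f}  "
      f"precision {precision(counts):.2f}")

# --- stage 2: translate and classify -------------------------------------
peptides = [PeptideRecord(id=f"pep{i}", sequence=translate_orf(c.source_orf.nt_seq))
            for i, c in enumerate(calls)]
print(f"translated {len(peptides)} peptides, "
      f"lengths {min(p.length for p in peptides)}-{max(p.length for p in peptides)} aa")

train_recs, train_labels = simulate_peptides(PeptideSimSpec(n_pos=300, n_neg=300, seed=702))
pep_model = train_peptide_model(train_recs, train_labels, "ACP",
                                PeptideModelConfig.desk(seed=702, max_epochs=8))
scores = predict_peptides(pep_model, peptides)
positives = [s for s in scores if s.label == "positive"]
print(f"predicted ACP candidates: {len(positives)}/{len(scores)}")

# --- stage 3: physicochemical profile of the candidates -------------------
if positives:
    chosen = [p for p in peptides
              if p.id in {s.peptide_id for s in positives} and "X" not in p.sequence]
    matrix = profile_peptides(chosen[:5])
    print("profile of first predicted candidates (raw values):")
    print(matrix.raw.round(2).to_string())
# Translated genes are random-composition peptides here, so few if any
# should cross the ACP threshold -- the interesting output is the joint
# mechanics of calling, translating, scoring and profiling in one pass.
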