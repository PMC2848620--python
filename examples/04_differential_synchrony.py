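"""Find genes that gain or lose cross-region synchrony in the case group.

Simulates control and case cohorts (14 subjects each) sharing a gene
universe in which 60 genes are designed to lose synchrony (rho 0.9 -> 0)
and 120 to gain it (rho 0 -> 0.9), runs the full differential pipeline
(selection at |r| >= 0.7 in at least one group, percentile-bootstrap p for
the shift, Benjamini-Hochberg FDR, gain/loss banding), and compares the
calls against the generator's ground truth.
"""

import numpy as np

from genesync import AnalysisConfig, run_differential_pipeline
from genesync.simulate import SimConfig, generate_paired_cohort

sim = SimConfig(
    n_genes=5000,
    n_subjects_per_group=14,
    n_gain_genes=120,
    n_loss_genes=60,
    rng_seed=11,
)
datasets, truth = generate_paired_cohort(sim)
config = AnalysisConfig(n_bootstrap=2000, fdr_q=0.2, rng_seed=11)
result = run_differential_pipeline(datasets["control"], datasets["mdd"], config)

print(f"gene universe: {result.n_genes_tested}; "
      f"selected at |r| >= {config.selection_cutoff}: {len(result.gene_ids)}")
print("counts over the FDR grid:")
print(result.fdr_grid_counts.to_string(index=False))

id_to_class = dict(zip(truth.table["gene_id"], truth.table["gene_class"]))
for label in ("gain", "loss"):
    called = result.gene_ids[result.label == label]
    correct = sum(id_to_class[g] == label for g in called)
    designed = (truth.table["gene_class"] == label).sum()
    print(f"{label}: called {len(called)}, of which {correct} are designed "
          f"{label} genes (out of {designed} designed)")
# At 20% FDR the pipeline recovers most designed rewiring events; calls
# that are not designed genes are either stable genes caught by noise or
# designed genes of the other class near the band edges.
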