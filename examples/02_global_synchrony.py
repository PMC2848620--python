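"""Is cross-region gene synchrony real, or an artifact of pairing?

Generates the control-like preset cohort (14 subjects, 10,000 genes,
median true cross-region correlation 0.32), computes every gene's observed
cross-region Pearson r, then destroys the within-subject pairing with 100
derangement scrambles to build the null. A right-shifted observed
distribution against a null centered near zero is the signature of
subject-specific coordination.
"""

import numpy as np

from genesync import (
    AnalysisConfig,
    emulate_control_cohort,
    genewise_synchrony,
    global_shift_test,
    median_shift_permutation_p,
    permutation_null,
)

dataset, truth = emulate_control_cohort(seed=1)
config = AnalysisConfig(n_bootstrap=100, n_permutations=100, rng_seed=1)

observed = genewise_synchrony(dataset)
null = permutation_null(dataset, config)
p_ranksum = global_shift_test(observed, null)
p_median = median_shift_permutation_p(observed, null)

print(f"genes: {dataset.n_genes}, subjects: {dataset.n_subjects}")
print(f"true median rho (generator): {np.median(truth.rho('control')):.3f}")
print(f"observed median r:           {np.median(observed):.3f}")
print(f"scrambled-linkage null median r: {np.median(null.pooled):.3f}")
print(f"global shift p (rank-sum, observed > null): {p_ranksum:.3g}")
print(f"median-r permutation p (subject-level, floor 1/101): {p_median:.4f}")
# The observed median sits near the generator's 0.32 while the null sits
# near 0; the rank-sum p underflows to 0 at this scale, and the
# subject-level permutation p hits its floor — both say the shift is real.
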