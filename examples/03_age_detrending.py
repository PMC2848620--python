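"""Separate intrinsic synchrony from age-driven correlation.

Half the genes here correlate across regions only because both regions
drift with subject age (shared slopes, true rho = 0); the other half carry
intrinsic rho = 0.5 with no age trend. Detrending age inside every
bootstrap resample should erase the former and spare the latter.
"""

import numpy as np

from genesync import AnalysisConfig, age_contribution_report
from genesync.simulate import RhoDistribution, SimConfig, generate_paired_cohort

sim = SimConfig(
    n_genes=1000,
    n_subjects_per_group=30,
    n_age_driven=500,
    age_driven_slope=0.05,
    rho_distribution=RhoDistribution(family="constant", value=0.5),
    groups=("control",),
    rng_seed=7,
)
datasets, truth = generate_paired_cohort(sim)
report = age_contribution_report(
    datasets["control"], AnalysisConfig(n_bootstrap=500, rng_seed=7)
)

aged = truth.genes_of_class("age_driven")
stable = truth.genes_of_class("stable")
print("                          raw median r   detrended median r")
print(f"age-driven genes (rho=0):     {np.median(report.r_raw[aged]):.3f}"
      f"            {np.median(report.r_detrended[aged]):.3f}")
print(f"intrinsic genes (rho=0.5):    {np.median(report.r_raw[stable]):.3f}"
      f"            {np.median(report.r_detrended[stable]):.3f}")
print(f"max |corr(residual, age)| after detrending: "
      f"{np.abs(report.age_corr_a_detrended).max():.2e}")
print(f"across-gene corr(raw, detrended) synchrony: "
      f"{report.corr_raw_vs_detrended:.3f}")
# Age-driven synchrony collapses to ~0 under per-resample detrending while
# intrinsic synchrony is untouched; residuals are exactly age-orthogonal.
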