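"""Calibration of the resampling null on a cohort with no genetic effect.

When phenotype labels are independent of genotype, the observed pathway and
its matched-size dummy pathways are exchangeable, so p(DS) should be uniform
and about 5% of pathways should fall below 0.05.
"""

import numpy as np

from poda.evaluation import null_calibration

cal = null_calibration(
    seed=5, B=200, alpha=0.05,
    n_samples=200, n_snps=2000, n_genes=400, n_pathways=40,
)
p = np.array(list(cal.p_ds.values()))
print(f"pathways analyzed: {len(p)}")
print(f"fraction with p(DS) < 0.05: {cal.fraction_below_alpha:.3f} (expect ~0.05)")
print(f"p(DS) quartiles: {np.percentile(p, [25, 50, 75]).round(3)} (expect ~[0.25 0.50 0.75])")
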