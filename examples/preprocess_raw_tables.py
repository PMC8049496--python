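"""From raw omics tables to the model's binary inputs.

Builds small in-memory stand-ins for the three raw tables (non-silent SNV
calls, GISTIC copy-number codes, expression Z scores plus raw counts) and
runs the preprocessing rules: |code| == 2 CNV binarization, SNV/CNV OR
combination, the median-count power filter, |Z| > 1.96 DEG calls, and the
multitask-lasso SGA filter.
"""

import numpy as np
import pandas as pd

from orn.preprocess import (
    binarize_cnv, binarize_zscores, combine_events, filter_low_expression, lasso_filter,
)

rng = np.random.default_rng(0)
samples = [f"TCGA-{i:02d}" for i in range(40)]

snv = pd.DataFrame(rng.integers(0, 2, (40, 4)), index=samples,
                   columns=["TP53", "IDH1", "EGFR", "PTEN"])
cnv = pd.DataFrame(rng.integers(-2, 3, (40, 3)), index=samples,
                   columns=["EGFR", "CDKN2A", "MYC"])
counts = pd.DataFrame(rng.poisson(40, (40, 5)), index=samples,
                      columns=["g1", "g2", "g3", "g4", "g5"])
counts["g5"] = rng.poisson(2, 40)  # weakly expressed gene
zs = pd.DataFrame(rng.normal(0, 1.5, (40, 5)), index=samples, columns=counts.columns)
zs["g1"] += 2.5 * snv["TP53"]  # TP53 mutations shift g1 expression

events = combine_events(snv, binarize_cnv(cnv))
print(f"event matrix: {events.n_samples} samples x {events.n_genes} genes "
      f"(union of SNV and high-level CNV genes)")

kept = filter_low_expression(counts)
print(f"median-count filter kept {kept} (g5 dropped: median below 10)")
deg = binarize_zscores(zs[kept])
print(f"DEG matrix density {deg.values.mean():.3f} (|Z| > 1.96 calls)")

mut_df = pd.DataFrame(events.values, index=events.sample_ids, columns=events.gene_ids)
deg_df = pd.DataFrame(deg.values, index=deg.sample_ids, columns=deg.gene_ids)
retained = lasso_filter(mut_df, deg_df, reg_strength=0.02)
print(f"multitask lasso retained SGA genes: {retained} "
      f"(genes with any predictive weight on the DEG matrix)")
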