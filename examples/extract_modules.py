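"""Turn a fitted model into discrete pathway modules and patient groups.

After fitting, each latent pathway is read out as (a) its upstream module
— the SGA genes whose U weight exceeds 0.5, (b) its regulon — the top 5%
of genes by Z weight, and (c) a binary patient group from thresholded
pathway abnormality probabilities, ready for external survival analysis.
"""

import orn
from orn.extract import binarize_pas, build_modules, export_modules

truth = orn.generate(
    orn.SimConfig(n_samples=300, n_sga=200, n_deg=200, n_pathways=3,
                  mut_density=0.04, u_density=0.03, z_density=0.1, seed=2)
)
res = orn.fit(truth.mut, truth.expr, orn.FitConfig(n_pathways=3, seed=3))

modules = build_modules(res.u, res.z)
for mod in modules:
    print(f"pathway {mod.pathway_index}: {len(mod.upstream_genes)} upstream SGAs, "
          f"{len(mod.regulon_genes)} regulon genes")
    print(f"  upstream: {sorted(mod.upstream_genes)[:8]}")

pas = binarize_pas(res.path)
print("patients with each pathway called abnormal:", pas.sum(axis=0).tolist())

export_modules(modules, "modules.gmt", "gmt")
print("wrote modules.gmt (one gene set per line: name, description, members)")
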