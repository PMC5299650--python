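"""Downstream cohort summaries: recurrence, gene status and pathways.

After individualized calling, the cohort is summarised three ways:
per-site recurrence frequencies (which aberrations appear in >90% of
tumors), the promoter-gene hypermethylation rule, and per-sample pathway
over-representation of the hypermethylated genes.
"""

import numpy as np
import pandas as pd

from rmocomp import (SimulationConfig, aberration_frequency,
                     build_stable_pairs, call_cohort, count_pair_orderings,
                     gene_methylation_status, pathway_enrichment,
                     simulate_normal_cohort, simulate_tumor_cohort)

config = SimulationConfig(n_sites=300, n_normals=80, n_tumors=30,
                          dm_fraction=0.1, delta=0.3, recurrence=0.95,
                          seed=2)
normals = simulate_normal_cohort(config)
tumors, truth = simulate_tumor_cohort(config)
background = build_stable_pairs(count_pair_orderings(normals))
calls = call_cohort(tumors, background,
                    restrict_to=truth.registry["site_id"])

freq, top = aberration_frequency(calls, n_samples=config.n_tumors,
                                 min_frequency=0.9)
print(f"{len(top)} CpG sites aberrant in >90% of the {config.n_tumors} "
      f"tumors:")
print(top.head(8).to_string(index=False))

# a synthetic promoter annotation: three CpG sites per gene
sites = background.site_ids
annotation = pd.DataFrame({
    "site_id": sites,
    "gene_symbol": [f"GENE{i // 3:03d}" for i in range(len(sites))],
    "promoter_flag": True,
    "platforms": "27K,450K",
})

sample = calls[calls["sample_id"] == "T000"]
genes = gene_methylation_status(sample, annotation)
hyper_genes = genes.loc[genes["status"] == "hypermethylated", "gene_symbol"]
print(f"\nsample T000: {len(hyper_genes)} hypermethylated genes "
      f"(>=1 promoter CpG hyper, none hypo)")

# synthetic pathway collection over the gene universe
universe = sorted(annotation["gene_symbol"].unique())
rng = np.random.default_rng(0)
pathways = {f"PW{j:02d}": set(rng.choice(universe, 12, replace=False))
            for j in range(15)}
pathways["PW_target"] = set(hyper_genes[:8]) | set(universe[:4])
enrich = pathway_enrichment(hyper_genes, pathways, universe,
                            fdr_threshold=0.05, sample_id="T000")
hits = enrich[enrich["significant"]]
print(f"{len(hits)} pathway(s) enriched at FDR < 0.05:")
print(hits[["pathway_id", "overlap", "pathway_size", "p", "fdr"]]
      .to_string(index=False))
# The planted pathway built from this sample's hypermethylated genes is
# recovered; random pathways stay at chance.
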