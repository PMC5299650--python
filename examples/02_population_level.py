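"""Population-level DM detection replicated across independent datasets.

Two replicate case/control datasets are drawn from one disease model; DM
CpG sites are detected in each with the Welch t-test + BH, and the sites
consistently detected with the same direction in both become the
population-level DM set — the restriction set for individualized calling.
"""

from dataclasses import replace

from rmocomp import (SimulationConfig, consistent_overlap,
                     simulate_normal_cohort, simulate_tumor_cohort, ttest_dm)

base = SimulationConfig(n_sites=500, n_normals=80, n_tumors=30,
                        dm_fraction=0.1, delta=0.3, recurrence=0.9, seed=1)

dm_lists = []
for rep in (1, 2):
    cfg = replace(base, replicate=rep)
    cancer, _ = simulate_tumor_cohort(cfg)
    normal = simulate_normal_cohort(cfg)
    dm = ttest_dm(cancer, normal, fdr_threshold=0.05)
    significant = dm[dm["significant"]]
    dm_lists.append(significant)
    print(f"dataset {rep}: {len(significant)} DM sites at FDR < 0.05")

sites, concordance = consistent_overlap(*dm_lists)
print(f"\n{concordance.k} sites shared; {concordance.s} with the same "
      f"direction (score {concordance.score:.4f}, "
      f"binomial tail p = {concordance.p:.3g})")
print(f"{len(sites)} consistently detected population-level DM sites")
# A score of 1.0 means every site found in both datasets agrees on
# hyper vs hypo — the reproducibility signature of genuine DM sites.
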