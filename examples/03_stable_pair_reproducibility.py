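"""Cross-cohort reproducibility of the stable-ordering background.

Stable pairs are built independently from two normal cohorts of the same
tissue model (emulating two platforms or laboratories); the comparison
reports how much of the shorter list is contained in the longer one and
how often the shared pairs agree in direction.
"""

from dataclasses import replace

from rmocomp import (SimulationConfig, build_stable_pairs,
                     compare_stable_pair_sets, count_pair_orderings,
                     simulate_normal_cohort)

base = SimulationConfig(n_sites=400, n_normals=80, n_tumors=0,
                        dm_fraction=0.0, seed=1)

backgrounds = []
for rep in (0, 1):
    cohort = simulate_normal_cohort(replace(base, replicate=rep))
    bg = build_stable_pairs(count_pair_orderings(cohort), theta=0.99)
    backgrounds.append(bg)
    print(f"cohort {rep}: {bg.n_pairs} stable pairs "
          f"from {cohort.n_samples} normals")

cmp = compare_stable_pair_sets(*backgrounds)
conc = cmp["concordance"]
print(f"\ncontainment of shorter list in longer: "
      f"{100 * cmp['containment_shorter_in_longer']:.2f}%")
print(f"direction concordance on {conc.k} shared pairs: "
      f"{100 * conc.score:.2f}% (binomial tail p = {conc.p:.3g})")
# Near-total containment and ~100% direction agreement is what makes a
# background predetermined in one cohort transferable to new samples.
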