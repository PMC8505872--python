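"""Simulate the two-species study design and inspect what it contains.

Generates negative-binomial counts for C. palustris leaf primordia under
five conditions plus mature leaves, C. terrestris primordia under two
conditions, and the tetraploid<->diploid ortholog map, with candidate-gene
signatures planted at known positions.
"""

from heterophylly import simulate_experiment

study = simulate_experiment(n_genes=1000, n_ct_genes=400, seed=7)

print("C. palustris samples:", len(study.cp_counts.samples))
print(study.cp_counts.metadata.groupby(["stage", "condition"]).size())
print("\nC. terrestris samples:", len(study.ct_counts.samples))

links = study.orthology.links
print("\northology:", links["relation"].value_counts().to_dict(),
      "| orphan tetraploid genes:", len(study.orthology.orphans))

print("\nplanted truth categories:")
print(study.truth["category"].value_counts())
# SHARED4 / SHARED3_NOT_UNI genes are the candidates the cascade should
# recover; CT_CONSISTENT / CT_UNEXPRESSED genes should be excluded again by
# the cross-species comparison.
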