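"""From a lesion-vs-normal DMP set to direction-labelled gene lists and
gene-set over-representation.

Genes whose transcription-start-site probes are hypermethylated in the
lesion are read as inhibited; hypomethylated TSS probes mark activation.
Enrichment is a one-sided hypergeometric test against the universe of all
genes with a TSS probe on the array.
"""

import numpy as np

import methylscape as ms

cfg = ms.SyntheticConfig(
    n_probes=6000,
    groups=[ms.GroupSpec("normal", 10), ms.GroupSpec("lesion", 10)],
    planted_dmps={("normal", "lesion"): (400, 0.35)},
    noise_sd=0.1,
    seed=6,
)
beta, _, sheet, annotation, _ = ms.generate_cohort(cfg)
groups = sheet.groups()

stats = ms.moderated_t(beta, groups["normal"], groups["lesion"],
                       "normal", "lesion")
dmps = ms.call_dmps(stats)
lists = ms.dmps_to_gene_lists(dmps, annotation, lesion_is_group_b=True)
print(f"activated genes (hypomethylated TSS in lesion): {len(lists.activated)}")
print(f"inhibited genes (hypermethylated TSS in lesion): {len(lists.inhibited)}")
print(f"universe (genes with >= 1 TSS probe): {len(lists.universe)}")
print(f"genes with conflicting probe directions: {len(lists.conflicting)}")

# a gene-set collection in which set ENRICHED is stacked with inhibited genes
rng = np.random.default_rng(0)
inhibited = sorted(lists.inhibited)
background = sorted(lists.universe - lists.inhibited)
collection = ms.GeneSetCollection(sets={
    "ENRICHED": frozenset(inhibited[:15] + background[:5]),
    "RANDOM": frozenset(rng.choice(background, 20, replace=False)),
})
table = ms.hypergeometric_enrich(lists.inhibited, lists.universe, collection,
                                 direction="inhibited")
print(table[["gene_set", "overlap", "set_size", "p", "q"]].to_string(index=False))
# the stacked set should come out with a far smaller p than the random one
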