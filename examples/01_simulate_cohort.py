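"""Generate a small EPIC-like cohort with planted structure and inspect it.

Three diagnosis groups of 10 samples each; groups A and B are planted with
the same methylation signature (siblings), C has its own, and an extra 50
probes are shifted between A and C.  The ground truth records exactly which
probes differ between which groups.
"""

import methylscape as ms

cfg = ms.SyntheticConfig(
    n_probes=4000,
    groups=[
        ms.GroupSpec("A", 10, signature_probes=100, signature_delta=0.35),
        ms.GroupSpec("B", 10, share_signature_with="A"),
        ms.GroupSpec("C", 10, signature_probes=100, signature_delta=0.35),
    ],
    planted_dmps={("A", "C"): (50, 0.35)},
    noise_sd=0.3,
    bad_samples=[("A_01", 0.2)],
    seed=1,
)
beta, detp, sheet, annotation, truth = ms.generate_cohort(cfg)

print(f"beta matrix: {beta.data.shape[0]} probes x {beta.data.shape[1]} samples")
print(f"beta range: [{beta.values.min():.3f}, {beta.values.max():.3f}]")
for pair, probes in truth.dmp_probes_per_pair.items():
    print(f"true differential probes {pair[0]} vs {pair[1]}: {len(probes)}")
frac = (detp.data["A_01"] > 0.01).mean()
print(f"detection-p failure fraction of planted bad sample A_01: {frac:.3f}")
# A vs B is 0 because B copies A's signature; A vs C combines both groups'
# signatures (200 probes) plus the 50 pair-planted probes.
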