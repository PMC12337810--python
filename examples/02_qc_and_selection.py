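"""Sample QC, M-value transform, probe filtering, and top-SD CpG selection.

A sample failing detection p > 0.01 at more than 10% of probes is excluded
(the cohort below plants one at 20%).  The landscape feature space is then
the most variable CpGs by across-sample standard deviation of beta.
"""

import methylscape as ms

cfg = ms.SyntheticConfig(
    n_probes=4000,
    groups=[ms.GroupSpec(g, 10, signature_probes=100, signature_delta=0.35)
            for g in "ABC"],
    noise_sd=0.3,
    bad_samples=[("A_01", 0.2)],
    seed=2,
)
beta, detp, sheet, annotation, _ = ms.generate_cohort(cfg)

report = ms.sample_qc(detp, p_threshold=0.01, max_fail_fraction=0.10)
print(f"excluded samples: {list(report.excluded)}")
print(f"their failing fractions: "
      f"{[round(report.fail_fraction[s], 3) for s in report.excluded]}")

kept = beta.select_samples([s for s in beta.sample_ids if s not in report.excluded])
filtered = ms.filter_probes(kept, annotation, policy=("sex_chromosomes",))
print(f"probes after dropping sex chromosomes: {len(filtered.probe_ids)} "
      f"(of {len(beta.probe_ids)})")

m_values = ms.beta_to_m(filtered)
print(f"M-value of beta 0.8 is 2 by definition; matrix M range: "
      f"[{m_values.values.min():.2f}, {m_values.values.max():.2f}]")

subset = ms.select_top_sd(filtered, k=1000)
print(f"selected {len(subset)} probes; SD of the 1st / 1000th: "
      f"{subset.sd.iloc[0]:.3f} / {subset.sd.iloc[-1]:.3f}")
# planted signature probes dominate the top of the SD ranking
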