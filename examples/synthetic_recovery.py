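"""Generate a synthetic FAERS bundle with injected signals and recover them.

Two PTs are injected at a report-level odds ratio of 10 for the target drug;
the remaining vocabulary PTs are null. The recovery report shows that the
pipeline (dedup -> cohort -> four statistics -> all-four gate) flags exactly
the injected PTs and that the estimated RORs cover the true odds ratio.
"""

from pedsignal import SyntheticConfig, generate_bundle, recover_parameters

config = SyntheticConfig(
    n_reports=30_000,
    p_target_drug=0.05,
    signal_map={"Cardiac arrest": 10.0, "Laryngospasm": 10.0},
    duplicate_rate=0.10,
    seed=21,
)
bundle, truth = generate_bundle(config)
report = recover_parameters(bundle, truth, config)

print(f"reports generated: {truth.n_reports} (+{truth.n_duplicates} duplicate versions)")
print(f"post-dedup count matches ground truth: {report.dedup_ok}")
print()
print("injected PTs (true odds ratio 10):")
print(report.per_injected.to_string(index=False))
print()
flagged_nulls = int(report.per_null["signal"].sum())
print(f"null PTs falsely flagged: {flagged_nulls} / {len(report.per_null)}")
print()
print("'signal' is the conjunction of the four positivity rules (ROR CI low > 1;")
print("PRR >= 2 with chi2 >= 4; IC025 > 0; EBGM05 > 2) at a minimum of 3 cases;")
print("'covers_truth' says the Wald 95% CI of the estimated ROR contains 10.")
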