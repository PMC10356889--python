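"""Quantify automated-scoring errors and correct an automated count.

Automated MN scoring both invents micronuclei (false positives) and misses
real ones (false negatives), with error rates that grow with dose. This
example summarises the packaged per-dose error-rate table and applies a
manual-mode correction to a toy automated histogram.
"""

from cbmndose import (
    InspectionRecord,
    MNDistribution,
    build_error_model,
    correct_counts,
    load_fixture,
    summarize_error_table,
)

rates = load_fixture("table2_error_rates")
summary = summarize_error_table(rates)
for key, label in [
    ("fp_bn_pct", "false-positive BN"),
    ("fp_mn_pct", "false-positive MN"),
    ("fn_mn_pct", "false-negative MN"),
]:
    s = summary[key]
    print(
        f"{label:>18}: mean {s['mean']:.2f}%  "
        f"range {s['range'][0]:.2f}-{s['range'][1]:.2f}%"
    )

model = build_error_model(rates)
print(f"\ninterpolated rates at 3.5 Gy: {model.rates_at(3.5)}")

auto = MNDistribution(dose=4.0, n_bn=1000, counts=(800, 160, 35, 5))
record = InspectionRecord(
    dose=4.0, n_bn_auto=1000, n_fp_bn=22, n_fp_mn=15, n_fn_mn=108, n_mn_auto=auto.n_mn
)
fixed = correct_counts(auto, record, mode="manual")
print(
    f"\nautomated: {auto.n_bn} BN cells, {auto.n_mn} MN"
    f"\ncorrected: {fixed.n_bn} BN cells, {fixed.n_mn} MN"
    "\n(rejected 22 spurious BN cells, removed 15 false MN, recovered 108 missed MN)"
)
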