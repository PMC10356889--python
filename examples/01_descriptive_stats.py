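"""Per-dose summary of the packaged pooled CBMN calibration table.

Prints MN frequency (mean micronuclei per binucleated cell), the dispersion
index (variance/mean; 1 under Poisson counting) and the Papworth u score
(standard-normal scale; |u| > 1.96 flags significant overdispersion) for
each of the nine dose points.
"""

from cbmndose import load_fixture, summarize_dataset

dataset = load_fixture("table1_fully_automated")
summary = summarize_dataset(dataset)
print(summary.round({"mn_frequency": 3, "dispersion_index": 2, "u_statistic": 1}))
print(
    "\nMN frequency rises ~11-fold from 0 to 4 Gy; dispersion indices of"
    "\n1.03-1.12 show counts are near-Poisson with mild overdispersion."
)
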