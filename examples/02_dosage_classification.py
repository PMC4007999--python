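"""Classify marker dosage from segregation counts.

Single-dose (SD) markers segregate 1:1 present:absent regardless of
ploidy; at ploidy 8, double-dose markers segregate 55:15 and
triple-dose 65:5 under random chromosomal pairing.  Classification is
by chi-square at alpha = 0.05, keeping moderately distorted markers as
skewed SD while excluding likely double-dose markers.
"""

from polylink import SimulationConfig, classify_dosage, generate_population, score_matrix

for counts in [(113, 114), (178, 49), (130, 97)]:
    call = classify_dosage(*counts, ploidy=8)
    print(
        f"present/absent {counts}: class={call.dosage_class:10s} "
        f"chi2(1:1)={call.chi2_1to1:6.2f} chi2(DD)={call.chi2_dd:6.2f} "
        f"skew_log2={call.skew_log2:+.3f}"
    )

cross = generate_population(SimulationConfig(seed=2))
report = score_matrix(cross.matrix, ploidy=8)
print("\nwhole-matrix classes:", report["dosage_class"].value_counts().to_dict())
truth = cross.truth["dosage"]
sd = truth.index[truth == 1]
ok = report.loc[sd, "dosage_class"].isin(["SD", "SD_skewed"]).mean()
print(f"true SD recovered as SD/SD_skewed: {100 * ok:.1f}%")
# the three worked examples show a clean SD, a clear DD, and a
# moderately distorted marker retained as skewed SD
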