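"""Clinical biomarker cohorts: group comparisons and correlations.

Simulates the default four-group cohort (healthy, COVID-19, SLE, mCRC)
and reproduces the analysis pattern of the clinical arm: Mann-Whitney
group comparisons of cirDNA/NE/MPO and per-group Pearson correlation
of cirDNA with the NET enzymes.
"""

from fragkin.cohort_stats import compare_groups, correlation_matrix
from fragkin.synthetic.cohort_sim import default_cohort_specs, simulate_cohort

table = simulate_cohort(default_cohort_specs(), seed=1)
print(f"cohort: {len(table)} subjects in {table['group'].nunique()} groups")

for group in ("COVID-19", "SLE", "mCRC"):
    c = compare_groups(table, "cir_nDNA", group, "HI")
    print(f"cir_nDNA {group:9s} median {c.median_a:6.1f} vs HI {c.median_b:5.2f} ng/mL, "
          f"U={c.u_statistic:.0f}, p={c.p_value:.2e} {c.stars}")

for group in ("HI", "SLE"):
    res = correlation_matrix(table, ["cir_nDNA", "NE", "MPO"], group=group, log_scale=True)
    print(f"{group}: r(cirDNA, NE) = {res.r.loc['cir_nDNA', 'NE']:.2f}, "
          f"r(cirDNA, MPO) = {res.r.loc['cir_nDNA', 'MPO']:.2f}")
# Disease groups show elevated markers (stars per the usual p-value
# thresholds) and positive cirDNA-enzyme correlations, while the healthy
# group shows none: the signature of NET-driven cirDNA release.
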