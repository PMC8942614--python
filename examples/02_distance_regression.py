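"""Testing whether a covariate relates to pairwise network distances.

Simulates scenario 1 at 60% signal (Treatment and IQ shape the signal
block; Age and Sex do not), regresses the pairwise Euclidean degree
distance on pairwise covariate differences, and tests the Treatment
coefficient with all four procedures.
"""

import netdist as nd

cov = nd.simulate_covariates(60, seed=1)
degrees = nd.simulate_degree_matrix(nd.layout(1), cov, s_p=0.6, seed=2)
y, metric, _ = nd.condensed_values(degrees, "euclidean")

table = nd.CovariateTable(
    cov, continuous=("AGE", "IQ"), categorical=("SEX", "TRT"), coi="TRT"
)
X = nd.build_design(table)                      # intercept + |diff| / 1{neq} columns
X_ile = nd.build_design(table, include_ile=True)  # one fixed effect per subject

print(f"{metric} distance ~ |Age_i-Age_j| + 1(Sex_i!=Sex_j) + |IQ_i-IQ_j| + 1(Trt_i!=Trt_j)")
print(f"n = {X.n_pairs} pairs from {len(cov)} subjects\n")
print("method                     statistic      p-value")
for name, res in [
    ("standard F", nd.f_test(y, X, "TRT")),
    ("F with subject effects", nd.f_test_ile(y, X_ile, "TRT")),
    ("dyadic FGLS", nd.fgls_test(y, X, "TRT")),
    ("Freedman-Lane (B=999)", nd.freedman_lane_test(y, X, "TRT", 999, seed=3)),
]:
    print(f"{name:<25}  {res.statistic:9.2f}  {res.p_value:11.4g}")

print(
    "\nAll four should reject (Treatment drives the signal block). The\n"
    "standard F test is shown for reference only: with a covariate that has\n"
    "no effect it over-rejects, because pairs sharing a subject are\n"
    "correlated; the other three account for that dependence."
)
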