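"""Permutation MDMR as an external comparator.

MDMR works on the square participant distance matrix and a participant-level
design (raw covariate values, not pairwise differences). It is run here on
the same simulated data as the pairwise regression for comparison. MDMR uses
raw distances; the log transform of the KS statistic is a regression-side
device only.
"""

import netdist as nd

cov = nd.simulate_covariates(60, seed=1)
degrees = nd.simulate_degree_matrix(nd.layout(1), cov, s_p=0.6, seed=2)

table = nd.CovariateTable(
    cov, continuous=("AGE", "IQ"), categorical=("SEX", "TRT"), coi="TRT"
)
Xp, names = nd.participant_design(table)

print("metric     MDMR pseudo-F   MDMR p    pairwise-ILE p")
for metric in ("ks", "jaccard", "euclidean"):
    if metric == "jaccard":
        import numpy as np

        feats = np.vstack([nd.key_nodes(r, 0.2).values for r in degrees])
    else:
        feats = degrees
    raw, _, _ = nd.condensed_values(feats, metric, log=False)
    D = nd.to_square(raw)
    res = nd.mdmr_permutation_test(D, Xp, "TRT", n_permutations=999, seed=4, columns=names)

    # the pairwise regression route on the same features
    y, _, _ = nd.condensed_values(feats, metric)
    X_ile = nd.build_design(table, include_ile=True)
    p_ile = nd.f_test_ile(y, X_ile, "TRT").p_value
    print(f"{metric:<9}  {res.statistic:13.2f}  {res.p_value:7.4f}  {p_ile:14.4g}")

print(
    "\nMDMR and the pairwise regression agree on strongly-driven metrics\n"
    "(Euclidean, Jaccard); the KS route is where the regression framework\n"
    "has power that MDMR lacks, since Gower centering of a distance between\n"
    "*distributions* discards most of the usable signal."
)
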