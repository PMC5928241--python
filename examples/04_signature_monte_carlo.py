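"""Test whether a CpG signature separates tumor from normal samples.

Simulates 18 matched tumor/normal pairs (20,000 probes; an 800-probe
signature where tumors shift by 0.3 beta, plus patient-level variation),
clusters samples on the signature (Manhattan distance, complete linkage,
k=2) and compares the cluster/tissue chi-square p against 1,000 random
probe sets of the same size.
"""

import pandas as pd

from hzemeth import simulate
from hzemeth.signature import monte_carlo_signature_test

beta, labels, signature = simulate.generate_tumor_normal(
    n_probes=20_000, n_pairs=18, signature_size=800, delta=0.3, noise_sd=0.02, seed=42
)

result = monte_carlo_signature_test(beta, labels, signature, n_resamples=1000, seed=43)

clusters = pd.Series(result.cluster_labels, index=beta.columns)
agreement = pd.crosstab(clusters, labels)
print("cluster x tissue table on the signature probes:")
print(agreement.to_string())
print(f"observed chi-square p = {result.observed_p:.3g} "
      f"(perfect 18/18 separation gives ~2e-9)")
print(f"Monte-Carlo p = {result.mc_p:.4g} over M = {result.n_resamples} random probe sets")
print(f"null resampling p-values: min {result.null_min:.3g}, "
      f"median {result.null_median:.3g}, max {result.null_max:.3g}")
print("random probe sets cluster samples by patient, not tissue, so none "
      "matches the signature's separation: mc_p sits at its 1/(M+1) floor")
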