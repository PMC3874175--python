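"""Exponential vs hypo-exponential models of gene in-degree.

Per-region TF counts follow an exponential law (MLE rate = n / total).
The per-gene sum of promoter and first-intron counts should then follow
the hypo-exponential distribution with the two fitted rates — a better
fit than a single exponential refitted to the sums.
"""

import numpy as np

from intronreg.degree import (
    compare_degree_models,
    exponential_rate_from_totals,
    hypoexp_mean,
)

# worked example from printed screen totals: 827 interactions, 120 promoters
lam = exponential_rate_from_totals(n_regions=120, total_interactions=827)
print(f"promoter rate from screen totals: lambda_P = {lam:.3f} "
      f"(mean {1 / lam:.2f} interactions per promoter)")

rng = np.random.default_rng(6)
prom = np.floor(rng.exponential(1 / 0.145, 2000) + 0.5)
intr = np.floor(rng.exponential(1 / 0.3, 2000) + 0.5)
out = compare_degree_models(prom, intr)
print(f"fitted rates: lambda_P = {out.lambda_promoter:.3f}, "
      f"lambda_I = {out.lambda_intron:.3f}")
print(f"predicted combined mean: "
      f"{hypoexp_mean([out.lambda_promoter, out.lambda_intron]):.2f}; "
      f"observed: {np.mean(prom + intr):.2f}")
print(f"log-likelihood  hypo-exponential: {out.loglik_hypoexp:.1f}  "
      f"single exponential: {out.loglik_exponential:.1f}")
print(f"KS distance     hypo-exponential: {out.ks_hypoexp:.4f}  "
      f"single exponential: {out.ks_exponential:.4f}")
print(f"hypo-exponential preferred: {out.hypoexp_preferred}")
print("\nThe higher log-likelihood and smaller KS distance of the "
      "hypo-exponential show the combined in-degree is the sum of two "
      "exponential components, not a single exponential.")
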