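"""The three SNP-weighting schemes on a small worked example.

Weights are relative variance shares (mean one): the beta-density MAF scheme
reshapes heritability across the allele-frequency spectrum, the window
scheme concentrates variance where a prior fit found large squared effects,
and the combined scheme multiplies the two factors.
"""

import numpy as np

import snpblup as sb

maf = np.array([0.1, 0.2, 0.5])
alpha_hat = np.array([1.0, 2.0, 3.0])  # effects from a prior identity-weight fit

flat = sb.maf_weights(maf, a=1, b=1)
het = sb.maf_weights(maf, a=2, b=2)  # contribution ~ 2p(1-p)
win = sb.window_weights(alpha_hat, S=0)
comb = sb.combined_weights(maf, 2, 2, alpha_hat, S=0)

print("MAF:", maf)
print(f"a=b=1 (unweighted):     {flat.w}")
print(f"a=b=2 (~2p(1-p)):       {het.w}")
print(f"window S=0 (alpha^2):   {win.w.round(4)}")
print(f"combined a=b=2, S=0:    {comb.w.round(4)}")
print("every scheme has mean weight", flat.w.mean(), het.w.mean(), win.w.mean(), comb.w.mean())
# Each weight is that SNP's share of genetic variance relative to the average SNP.
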