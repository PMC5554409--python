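"""Hub bias: why the global-equilibrium adjustment matters.

On a scale-free network with a response that is independent of the
expression data (null scenario), a ranking that omits the global
equilibrium subtraction piles network hubs at the top regardless of the
phenotype. The adjusted ranking shows no such enrichment. Overlap is
between the robust top-500 genes and the 200 highest-degree nodes, with an
upper-tail hypergeometric p-value.
"""

import progeni as pg
from progeni.robust import BootstrapConfig, robust_rank

network = pg.generate_network(n_genes=2000, seed=0)
X, response, _ = pg.generate_dataset(network, n_samples=120, scenario="null", seed=0)
Xn = pg.normalize_expression(X, log2_first=False)
config = BootstrapConfig(n_repeats=20, sample_fraction=0.8, seed=1)

for method, label in (("progeni", "with hub adjustment   "),
                      ("progeni_nh", "without hub adjustment")):
    ranked = robust_rank(network, Xn, response, config, method=method)
    overlap, p = pg.hub_bias(ranked, network, n_top=500, n_hubs=200)
    print(f"{label} ({method:>10s}): overlap {overlap:>3d}/200, p = {p:.2e}")

print()
print("Chance overlap is 500*200/2000 = 50. The unadjusted ranking is almost")
print("entirely hubs; the adjusted one is indistinguishable from (or below) chance.")
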