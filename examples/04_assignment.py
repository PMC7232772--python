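"""Leave-one-out home-likelihood population assignment.

Each individual is scored against every group's allele frequencies (its own
genotype removed from its home group first); assignment is to the
highest-likelihood group. On moderately differentiated demes self-assignment
should be near-perfect.
"""

import numpy as np

from ciscopop import instantiate_individuals, leave_one_out_assign
from ciscopop.sim import _balding_nichols

rng = np.random.default_rng(5)
pbar = rng.uniform(0.2, 0.8, 3000)
freqs = np.stack([_balding_nichols(pbar, 0.05, 3000, rng) for _ in range(3)])
gm = instantiate_individuals(freqs, 40, seed=rng).to_genotype_matrix()

res = leave_one_out_assign(gm)
print("self-assignment rate per group (%):")
print(res.self_assignment.round(1).to_string())
print("\nconfusion matrix (rows = home group, columns = assigned):")
print(res.confusion.to_string())
print("\nat FST ~0.05 with thousands of SNPs, assignment is essentially "
      "error-free — the regime the empirical RAD data sit in.")
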