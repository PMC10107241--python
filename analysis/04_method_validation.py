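"""Validate the statistical machinery on sites with known ground truth.

Three checks at reduced problem sizes (the full-size versions run in the
test suite and scripts/acceptance.py): type-I error of the CV permutation
test on open-membership sites, its power plus module recovery on strongly
structured sites, and uniformity of the swap chain on an exactly
enumerable matrix class.
"""

from itertools import product

import numpy as np
from scipy.stats import chisquare
from sklearn.metrics import adjusted_rand_score

import flocknet as fn

SEED = 42


def main() -> None:
    rej = 0
    n_sites = 40
    for i in range(n_sites):
        rng = np.random.default_rng([SEED, 1, i])
        fm = fn.generate_site(fn.SyntheticConfig(
            n_species=15, n_flocks=30, affinity=1.0), rng=rng)
        obs = fn.network_cv(fn.build_network(fm))
        ens = fn.null_metric_distribution(fm, ["cv"], n_perm=300, rng=rng)
        rej += fn.upper_tail_pvalue(obs, ens.null_values["cv"]) < 0.05
    print(f"open membership (alpha=1): CV test rejects {rej}/{n_sites} "
          f"sites at the 5% level (nominal: {0.05 * n_sites:.0f})")

    rej, aris = 0, []
    for i in range(n_sites):
        rng = np.random.default_rng([SEED, 2, i])
        cfg = fn.SyntheticConfig(n_species=15, n_flocks=40, affinity=8.0,
                                 n_modules=2)
        fm = fn.generate_site(cfg, rng=rng)
        net = fn.build_network(fm)
        ens = fn.null_metric_distribution(fm, ["cv"], n_perm=300, rng=rng)
        rej += fn.upper_tail_pvalue(fn.network_cv(net),
                                    ens.null_values["cv"]) < 0.05
        part, _ = fn.greedy_modularity(net)
        aris.append(adjusted_rand_score(fn.true_modules(cfg, fm), part.labels))
    print(f"strong structure (alpha=8): CV test rejects {rej}/{n_sites}; "
          f"median adjusted Rand vs true modules {np.median(aris):.2f}")

    mats = [np.array(b, dtype=np.int8).reshape(4, 4)
            for b in product((0, 1), repeat=16)]
    mats = [m for m in mats if (m.sum(0) == 2).all() and (m.sum(1) == 2).all()]
    idx = {m.tobytes(): i for i, m in enumerate(mats)}
    fm = fn.FlockMatrix("u", tuple("abcd"), tuple("wxyz"), mats[0])
    counts = np.zeros(len(mats))
    # thin by 10: the chi-square test wants independent draws
    for k, state in enumerate(fn.permutation_chain(
            fm, 100_000, np.random.default_rng([SEED, 3]))):
        if k % 10 == 0:
            counts[idx[state.tobytes()]] += 1
    p = chisquare(counts).pvalue
    print(f"swap chain on the 90-matrix fixed-margin class: all visited = "
          f"{bool((counts > 0).all())}, uniformity chi2 p = {p:.3f}")


if __name__ == "__main__":
    main()
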