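"""Independent oracles for the test suite.

These deliberately avoid the package's computational paths: quadrature
instead of incomplete-gamma bin means, scipy.linalg.expm instead of the
symmetrized eigendecomposition, and explicit enumeration of internal-node
states instead of pruning.
"""

import itertools

import numpy as np
from scipy import integrate
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist


def quadrature_bin_means(alpha: float, k: int) -> np.ndarray:
    """Conditional means of a unit-mean gamma on its K equiprobable quantile
    bins, by adaptive quadrature of x * pdf(x)."""
    dist = gamma_dist(a=alpha, scale=1.0 / alpha)
    edges = dist.ppf(np.arange(k + 1) / k)
    edges[-1] = np.inf
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _err = integrate.quad(lambda x: x * dist.pdf(x), lo, hi,
                                   limit=200)
        means.append(val * k)  # divide by bin mass 1/K
    return np.asarray(means)


def brute_force_log_likelihood(aln, tree, model, branch_scale=1.0):
    """Total log-likelihood by explicit summation over all internal-node
    codon assignments and joint rate categories.

    Only usable for a handful of taxa; transition matrices come from
    scipy.linalg.expm.
    """
    from ratebound.genetics import build_generator

    flat = tree.flatten(aln.taxa)
    syn, nonsyn, w = model.joint_categories()
    pi = model.params.codon_freqs
    n_states = pi.size
    internal = [n for n in range(flat.n_nodes) if flat.children[n]]
    root = flat.n_nodes - 1
    edges = [(nid, child, blen) for nid in internal
             for child, blen in flat.children[nid]]

    total = 0.0
    for h in range(aln.n_sites):
        site_lik = 0.0
        for c in range(w.size):
            q = build_generator(model.params, syn[c], nonsyn[c],
                                model.nonsyn_scale)
            p_mats = {child: expm(q * blen * branch_scale)
                      for _nid, child, blen in edges}
            cat_lik = 0.0
            for assign in itertools.product(range(n_states),
                                            repeat=len(internal)):
                state = dict(zip(internal, assign))
                for nid in range(flat.n_nodes):
                    if not flat.children[nid]:
                        state[nid] = aln.codons[flat.leaf_taxon_row[nid], h]
                prob = pi[state[root]]
                for nid, child, _blen in edges:
                    s_child = state[child]
                    if s_child < 0:  # ambiguous leaf: sum over all states=1
                        continue
                    prob *= p_mats[child][state[nid], s_child]
                cat_lik += prob
            site_lik += w[c] * cat_lik
        total += np.log(site_lik)
    return total
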