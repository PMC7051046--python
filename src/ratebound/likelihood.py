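"""Felsenstein-pruning likelihood for the dual-rate codon mixture.

Each site carries an independent synonymous rate and nonsynonymous rate; the
site likelihood is a mixture over the product of the two discrete rate
distributions (``K_syn x K_nonsyn`` joint categories).  The engine caches
site patterns and the flattened tree, vectorizes the pruning recursion over
joint categories and patterns, and rescales partial likelihoods at internal
nodes so deep trees do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import CodonAlignment, PhyloTree
from .genetics import N_CODONS, CodonModelParams
from .ratedist import DiscreteRateDistribution

__all__ = ["DualRateModel", "PruningEngine", "log_likelihood",
           "site_log_likelihoods_by_category", "LikelihoodError"]


class LikelihoodError(RuntimeError):
    pass


@dataclass(frozen=True)
class DualRateModel:
    """Codon model plus independent synonymous/nonsynonymous rate mixtures.

    The joint mixture has ``syn_K * nonsyn_K`` components with product
    weights; ``nonsyn_scale`` is the global omega-like multiplier applied to
    every nonsynonymous category rate.
    """

    params: CodonModelParams
    syn_dist: DiscreteRateDistribution
    nonsyn_dist: DiscreteRateDistribution
    nonsyn_scale: float = 1.0

    def __post_init__(self):
        if not (self.nonsyn_scale >= 0):
            raise ValueError("nonsyn_scale must be non-negative")

    def joint_categories(self):
        """(syn_rates, nonsyn_rates, weights) arrays over the joint mixture,
        synonymous index varying slowest."""
        s = np.asarray(self.syn_dist.rates)
        n = np.asarray(self.nonsyn_dist.rates)
        ws = np.asarray(self.syn_dist.weights)
        wn = np.asarray(self.nonsyn_dist.weights)
        syn = np.repeat(s, n.size)
        nonsyn = np.tile(n, s.size)
        w = np.repeat(ws, n.size) * np.tile(wn, s.size)
        return syn, nonsyn, w


class PruningEngine:
    """Reusable pruning workspace for one (alignment, tree) pair."""

    def __init__(self, alignment: CodonAlignment, tree: PhyloTree):
        self.alignment = alignment
        self.tree = tree
        self.flat = tree.flatten(alignment.taxa)
        self.patterns, self.pattern_counts, self.site_to_pattern = (
            alignment.site_patterns()
        )
        self.n_patterns = self.patterns.shape[1]

    def _transition_matrices(self, model: DualRateModel, branch_scale: float):
        """P[edge above child-node] per joint category: dict node_id ->
        (ncat, 61, 61)."""
        syn, nonsyn, w = model.joint_categories()
        ncat = syn.size
        pi = model.params.codon_freqs
        s_mat, n_mat = model.params.base_matrices()
        # all joint-category generators in one stacked eigendecomposition
        q = (syn[:, None, None] * s_mat
             + (nonsyn * model.nonsyn_scale)[:, None, None] * n_mat)
        rows = q.sum(axis=2)
        idx = np.arange(N_CODONS)
        q[:, idx, idx] -= rows
        sqrt_pi = np.sqrt(pi)
        b = q * (sqrt_pi[None, :, None] / sqrt_pi[None, None, :])
        b = 0.5 * (b + np.swapaxes(b, 1, 2))
        lams, v = np.linalg.eigh(b)
        lefts = v / sqrt_pi[None, :, None]
        rights = np.swapaxes(v, 1, 2) * sqrt_pi[None, None, :]
        # one batched matmul over (edge, category)
        edge_children, edge_lens = [], []
        for nid, children in enumerate(self.flat.children):
            for child, blen in children:
                edge_children.append(child)
                edge_lens.append(blen)
        t = np.asarray(edge_lens) * branch_scale
        scale = np.exp(t[:, None, None] * lams[None, :, :])  # (ne, ncat, 61)
        tmp = np.empty_like(lefts)
        p_above = {}
        for e, child in enumerate(edge_children):
            np.multiply(lefts, scale[e][:, None, :], out=tmp)
            p = np.matmul(tmp, rights)
            np.clip(p, 0.0, None, out=p)
            p_above[child] = p
        return p_above, w, pi, ncat

    def pattern_log_likelihoods_by_category(
        self, model: DualRateModel, branch_scale: float = 1.0
    ):
        """Per-pattern, per-joint-category log-likelihoods.

        Returns ``(logl, weights)`` with ``logl`` of shape
        (n_patterns, ncat); ``logsumexp(logl + log weights, axis=1)`` is the
        per-pattern total.
        """
        if branch_scale < 0:
            raise ValueError("branch_scale must be non-negative")
        p_above, w, pi, ncat = self._transition_matrices(model, branch_scale)
        npat = self.n_patterns
        flat = self.flat
        log_scale = np.zeros((ncat, npat))
        messages: dict = {}
        internal_count = 0
        for nid, children in enumerate(flat.children):
            if not children:  # leaf: message computed by the parent below
                continue
            partial = None
            for child, _blen in children:
                p = p_above[child]
                if not flat.children[child]:  # child is a leaf
                    states = self.patterns[flat.leaf_taxon_row[child]]
                    known = states >= 0
                    if known.all():
                        msg = p[:, :, states]
                    else:
                        msg = np.ones((ncat, N_CODONS, npat))
                        if known.any():
                            msg[:, :, known] = p[:, :, states[known]]
                else:
                    msg = np.matmul(p, messages.pop(child))
                if partial is None:
                    partial = msg
                else:
                    partial *= msg
            internal_count += 1
            is_root = nid == flat.n_nodes - 1
            # periodic rescaling keeps deep trees from underflowing without
            # paying the max/divide on every node of a small tree
            if is_root or internal_count % 8 == 0:
                m = partial.max(axis=1)
                safe = np.where(m > 0, m, 1.0)
                partial /= safe[:, None, :]
                with np.errstate(divide="ignore"):
                    log_scale += np.where(m > 0, np.log(safe), -np.inf)
            messages[nid] = partial
        root = flat.n_nodes - 1
        if not flat.children[root]:
            raise LikelihoodError("tree must have at least one internal node")
        root_partial = messages.pop(root)
        site_lik = np.einsum("x,cxp->cp", pi, root_partial)
        with np.errstate(divide="ignore"):
            logl = np.log(site_lik) + log_scale
        return logl.T, w

    def site_log_likelihoods_by_category(
        self, model: DualRateModel, branch_scale: float = 1.0
    ):
        """(n_sites, ncat) per-site per-joint-category log-likelihoods."""
        logl, w = self.pattern_log_likelihoods_by_category(model, branch_scale)
        return logl[self.site_to_pattern], w

    def log_likelihood(self, model: DualRateModel, branch_scale: float = 1.0) -> float:
        logl, w = self.pattern_log_likelihoods_by_category(model, branch_scale)
        per_pattern = logsumexp(logl + np.log(w)[None, :], axis=1)
        bad = ~np.isfinite(per_pattern)
        if bad.any():
            sites = np.nonzero(np.isin(self.site_to_pattern, np.nonzero(bad)[0]))[0]
            raise LikelihoodError(
                f"non-finite site log-likelihood at site(s) {sites.tolist()[:10]}"
            )
        return float(per_pattern @ self.pattern_counts)


def log_likelihood(
    aln: CodonAlignment, tree: PhyloTree, model: DualRateModel,
    branch_scale: float = 1.0,
) -> float:
    """Total log-likelihood of the alignment under the dual-rate mixture."""
    return PruningEngine(aln, tree).log_likelihood(model, branch_scale)


def site_log_likelihoods_by_category(
    aln: CodonAlignment, tree: PhyloTree, model: DualRateModel,
    branch_scale: float = 1.0,
):
    """Per-site per-joint-category log-likelihood matrix and joint weights."""
    return PruningEngine(aln, tree).site_log_likelihoods_by_category(
        model, branch_scale
    )
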