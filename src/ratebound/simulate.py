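"""Forward simulation of codon alignments with per-site dual rates.

Each site draws an independent (synonymous, nonsynonymous) rate pair from
continuous unit-mean gammas, a fixed discrete distribution, or a constant;
the root codon is drawn from the stationary frequencies and states evolve
down the tree through the per-site generator.  The simulator returns the
true site rates alongside the data so estimator bias can be measured
directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CodonAlignment, PhyloTree
from .genetics import CODONS, CodonModelParams, build_generator, reversible_eigen
from .likelihood import DualRateModel
from .ratedist import DiscreteRateDistribution

__all__ = ["RateLaw", "SimulationSpec", "sample_site_rates",
           "simulate_alignment", "make_collection", "random_yule_tree"]


@dataclass(frozen=True)
class RateLaw:
    """A law for per-site rate multipliers: constant 1, unit-mean gamma, or
    a fixed discrete distribution."""

    kind: str
    alpha: float | None = None
    dist: DiscreteRateDistribution | None = None

    @classmethod
    def constant(cls) -> "RateLaw":
        return cls("constant")

    @classmethod
    def gamma(cls, alpha: float) -> "RateLaw":
        if not (alpha > 0):
            raise ValueError(f"gamma shape must be positive, got {alpha}")
        return cls("gamma", alpha=float(alpha))

    @classmethod
    def discrete(cls, dist: DiscreteRateDistribution) -> "RateLaw":
        return cls("discrete", dist=dist)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 0:
            raise ValueError("n must be non-negative")
        if self.kind == "constant":
            return np.ones(n)
        if self.kind == "gamma":
            # unit mean: shape alpha, scale 1/alpha
            return rng.gamma(self.alpha, 1.0 / self.alpha, size=n)
        if self.kind == "discrete":
            idx = rng.choice(self.dist.k, size=n, p=self.dist.weights)
            return np.asarray(self.dist.rates)[idx]
        raise ValueError(f"unknown rate law kind {self.kind!r}")

    def analytic_cv(self) -> float:
        if self.kind == "constant":
            return 0.0
        if self.kind == "gamma":
            return 1.0 / np.sqrt(self.alpha)
        return self.dist.cv

    def to_json_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.alpha is not None:
            d["alpha"] = self.alpha
        if self.dist is not None:
            d["dist"] = self.dist.to_json_dict()
        return d

    @classmethod
    def from_json_dict(cls, obj: dict) -> "RateLaw":
        if obj["kind"] == "discrete":
            return cls.discrete(DiscreteRateDistribution.from_json_dict(obj["dist"]))
        if obj["kind"] == "gamma":
            return cls.gamma(obj["alpha"])
        return cls.constant()


def sample_site_rates(
    syn_law: RateLaw, nonsyn_law: RateLaw, n_sites: int, seed
) -> np.ndarray:
    """Independent per-site (syn_rate, nonsyn_rate) pairs, shape (n, 2)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    syn = syn_law.sample(n_sites, rng)
    nonsyn = nonsyn_law.sample(n_sites, rng)
    return np.column_stack([syn, nonsyn]) if n_sites else np.empty((0, 2))


def random_yule_tree(
    n_taxa: int, rng: np.random.Generator, branch_length_mean: float = 0.1
) -> PhyloTree:
    """Random topology by uniform sequential joins (Yule/coalescent labelled
    shape) with i.i.d. exponential branch lengths."""
    if n_taxa < 2:
        raise ValueError("random trees need at least 2 taxa")
    nodes = [f"t{i + 1}" for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.exponential(branch_length_mean, size=2)
        nodes.append(f"({a}:{la:.10g},{b}:{lb:.10g})")
    la, lb = rng.exponential(branch_length_mean, size=2)
    newick = f"({nodes[0]}:{la:.10g},{nodes[1]}:{lb:.10g});"
    return PhyloTree.from_newick(newick)


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to regenerate one synthetic dataset, bit for bit."""

    n_sites: int
    seed: int
    newick: str | None = None
    n_taxa: int | None = None
    branch_length_mean: float = 0.1
    kappa: float = 2.0
    position_freqs: tuple | None = None  # (3, 4) nested tuples, or None = flat
    syn_law: RateLaw = field(default_factory=RateLaw.constant)
    nonsyn_law: RateLaw = field(default_factory=RateLaw.constant)
    nonsyn_scale: float = 1.0

    def __post_init__(self):
        if self.n_sites < 0:
            raise ValueError("n_sites must be non-negative")
        if self.newick is None and (self.n_taxa is None or self.n_taxa < 2):
            raise ValueError("give a newick string or n_taxa >= 2")

    def codon_model_params(self) -> CodonModelParams:
        pf = None if self.position_freqs is None else np.asarray(self.position_freqs)
        return CodonModelParams(kappa=self.kappa, position_freqs=pf)

    def to_json_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "seed": self.seed,
            "newick": self.newick,
            "n_taxa": self.n_taxa,
            "branch_length_mean": self.branch_length_mean,
            "kappa": self.kappa,
            "position_freqs": self.position_freqs,
            "syn_law": self.syn_law.to_json_dict(),
            "nonsyn_law": self.nonsyn_law.to_json_dict(),
            "nonsyn_scale": self.nonsyn_scale,
        }

    @classmethod
    def from_json_dict(cls, obj: dict) -> "SimulationSpec":
        obj = dict(obj)
        obj["syn_law"] = RateLaw.from_json_dict(obj["syn_law"])
        obj["nonsyn_law"] = RateLaw.from_json_dict(obj["nonsyn_law"])
        if obj.get("position_freqs") is not None:
            obj["position_freqs"] = tuple(tuple(r) for r in obj["position_freqs"])
        return cls(**obj)


def simulate_alignment(spec: SimulationSpec):
    """Evolve one alignment; returns (alignment, tree, truth table).

    The truth table is a DataFrame with one row per site holding the true
    synonymous and nonsynonymous rate multipliers.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.newick is not None:
        tree = PhyloTree.from_newick(spec.newick)
    else:
        tree = random_yule_tree(spec.n_taxa, rng, spec.branch_length_mean)
    params = spec.codon_model_params()
    pi = params.codon_freqs
    rates = sample_site_rates(spec.syn_law, spec.nonsyn_law, spec.n_sites, rng)

    taxa = tree.leaf_labels
    flat = tree.flatten(taxa)
    n_states = len(CODONS)
    seqs = np.empty((len(taxa), spec.n_sites), dtype=np.int16)
    # preorder: parents before children (reverse of the postorder flattening)
    order = range(flat.n_nodes - 1, -1, -1)
    edges = {child: (nid, blen)
             for nid, ch in enumerate(flat.children) for child, blen in ch}
    for h in range(spec.n_sites):
        s, n = rates[h]
        q = build_generator(params, s, n, spec.nonsyn_scale)
        lam, left, right = reversible_eigen(q, pi)
        state = {flat.n_nodes - 1: rng.choice(n_states, p=pi)}
        for nid in order:
            if nid == flat.n_nodes - 1:
                continue
            parent, blen = edges[nid]
            row = (left[state[parent]] * np.exp(lam * blen)) @ right
            np.clip(row, 0.0, None, out=row)
            row /= row.sum()
            state[nid] = rng.choice(n_states, p=row)
            if not flat.children[nid]:
                seqs[flat.leaf_taxon_row[nid], h] = state[nid]
    aln = CodonAlignment(tuple(taxa), seqs)
    truth = pd.DataFrame(
        {"site": np.arange(1, spec.n_sites + 1),
         "syn_rate": rates[:, 0], "nonsyn_rate": rates[:, 1]}
    )
    return aln, tree, truth


def make_collection(
    spec_template: SimulationSpec,
    n_alignments: int,
    master_seed: int,
    out_dir=None,
):
    """Simulate a reproducible collection of datasets.

    Per-alignment seeds derive deterministically from ``master_seed``.  If
    ``out_dir`` is given, each replicate is written as FASTA + Newick +
    truth TSV with a JSON manifest.
    """
    if n_alignments < 1:
        raise ValueError("n_alignments must be >= 1")
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(master_seed).spawn(n_alignments)
    ]
    datasets = []
    manifest = {"master_seed": master_seed, "n_alignments": n_alignments,
                "template": spec_template.to_json_dict(), "replicates": []}
    for i, seed in enumerate(child_seeds):
        spec = SimulationSpec.from_json_dict(
            {**spec_template.to_json_dict(), "seed": seed}
        )
        aln, tree, truth = simulate_alignment(spec)
        name = f"rep{i + 1:03d}"
        datasets.append((name, aln, tree, truth))
        entry = {"name": name, "seed": seed,
                 "true_cv_syn": float(truth.syn_rate.std(ddof=0) / truth.syn_rate.mean())
                 if spec.n_sites else float("nan"),
                 "true_cv_nonsyn": float(truth.nonsyn_rate.std(ddof=0) / truth.nonsyn_rate.mean())
                 if spec.n_sites else float("nan")}
        manifest["replicates"].append(entry)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            aln.write_fasta(out / f"{name}.fasta")
            tree.write_newick(out / f"{name}.nwk")
            truth.to_csv(out / f"{name}.truth.tsv", sep="\t", index=False)
    if out_dir is not None:
        with open(Path(out_dir) / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return datasets, manifest
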