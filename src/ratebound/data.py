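"""Codon alignments and phylogenetic trees: containers and file I/O.

Alignments are held as integer matrices over the 61 sense codons (``-1``
marks a gapped or ambiguous codon); stop codons are a hard read error.
Trees are dendropy trees with required branch lengths, flattened into plain
arrays for the likelihood engine.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import CODON_INDEX, CODONS, STOP_CODONS

__all__ = ["CodonAlignment", "PhyloTree", "StopCodonError"]


class StopCodonError(ValueError):
    """A stop codon was encountered in a sequence being read."""


def _encode_sequence(name: str, seq: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(
            f"sequence {name!r} has length {len(seq)}, not a multiple of 3"
        )
    out = np.empty(len(seq) // 3, dtype=np.int16)
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            raise StopCodonError(
                f"stop codon {codon} in sequence {name!r} at codon position {i // 3 + 1}"
            )
        out[i // 3] = CODON_INDEX.get(codon, -1)
    return out


@dataclass(frozen=True)
class CodonAlignment:
    """Taxa-by-codon-site matrix over the sense codons (-1 = ambiguous/gap)."""

    taxa: tuple[str, ...]
    codons: np.ndarray  # (n_taxa, n_sites) int16

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon names must be unique")
        c = np.asarray(self.codons, dtype=np.int16)
        if c.ndim != 2 or c.shape[0] != len(self.taxa):
            raise ValueError("codons must be a (n_taxa, n_sites) matrix")
        if c.size and (c.max() >= len(CODONS) or c.min() < -1):
            raise ValueError("codon states must be sense-codon indices or -1")
        object.__setattr__(self, "codons", c)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    @classmethod
    def from_sequences(cls, named_seqs) -> "CodonAlignment":
        """Build from an iterable of ``(name, nucleotide_string)`` pairs."""
        names, rows = [], []
        for name, seq in named_seqs:
            names.append(str(name))
            rows.append(_encode_sequence(name, str(seq)))
        if rows and len({r.size for r in rows}) != 1:
            raise ValueError("sequences have unequal codon lengths")
        mat = np.vstack(rows) if rows else np.empty((0, 0), dtype=np.int16)
        return cls(tuple(names), mat)

    @classmethod
    def read_fasta(cls, path) -> "CodonAlignment":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no sequences found in {path}")
        return cls.from_sequences(records)

    @classmethod
    def read_phylip(cls, path) -> "CodonAlignment":
        """Relaxed sequential PHYLIP: header line, then ``name sequence``
        records (whitespace-separated, sequences may wrap across lines)."""
        with open(path) as fh:
            tokens = fh.read().split()
        if len(tokens) < 2:
            raise ValueError(f"{path} is not a PHYLIP file")
        n_taxa, n_chars = int(tokens[0]), int(tokens[1])
        pairs, i = [], 2
        for _ in range(n_taxa):
            if i >= len(tokens):
                raise ValueError(f"{path}: fewer taxa than the header promises")
            name = tokens[i]
            i += 1
            chunks = []
            length = 0
            while length < n_chars:
                if i >= len(tokens):
                    raise ValueError(f"{path}: sequence for {name!r} is truncated")
                chunks.append(tokens[i])
                length += len(tokens[i])
                i += 1
            seq = "".join(chunks)
            if len(seq) != n_chars:
                raise ValueError(f"{path}: sequence for {name!r} has length {len(seq)}")
            pairs.append((name, seq))
        return cls.from_sequences(pairs)

    def codon_string(self, taxon_index: int) -> str:
        return "".join(
            CODONS[s] if s >= 0 else "---" for s in self.codons[taxon_index]
        )

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.codon_string(i)), id=name, description="")
            for i, name in enumerate(self.taxa)
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n_taxa} {3 * self.n_sites}\n")
            for i, name in enumerate(self.taxa):
                fh.write(f"{name}  {self.codon_string(i)}\n")

    def position_nucleotide_counts(self) -> np.ndarray:
        """(3, 4) counts of A, C, G, T at each codon position (F3x4 input)."""
        counts = np.zeros((3, 4), dtype=float)
        flat = self.codons[self.codons >= 0]
        for s in flat:
            codon = CODONS[s]
            for p in range(3):
                counts[p, "ACGT".index(codon[p])] += 1
        return counts

    def site_patterns(self):
        """Unique site columns and their multiplicities.

        Returns ``(patterns, counts, site_to_pattern)`` with ``patterns`` of
        shape (n_taxa, n_patterns).
        """
        if self.n_sites == 0:
            return (np.empty((self.n_taxa, 0), dtype=np.int16),
                    np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        patterns, inverse, counts = np.unique(
            self.codons, axis=1, return_inverse=True, return_counts=True
        )
        return patterns, counts, inverse.ravel()


@dataclass(frozen=True)
class FlatTree:
    """Postorder array form of a rooted tree for the pruning engine.

    Nodes are numbered so that every child precedes its parent; the root is
    the last node.  ``children[i]`` lists ``(child_node, branch_length)``;
    leaves carry the row index of their taxon in the alignment order.
    """

    n_nodes: int
    children: tuple  # per node: tuple of (child_id, branch_length)
    leaf_taxon_row: dict  # node_id -> alignment row
    branch_lengths: np.ndarray  # length of the edge above each non-root node


class PhyloTree:
    """A rooted-or-unrooted tree with branch lengths, backed by dendropy."""

    def __init__(self, dendropy_tree: dendropy.Tree):
        self._tree = dendropy_tree
        labels = self.leaf_labels
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        for edge in dendropy_tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                raise ValueError("all branches must have lengths")
            if edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    @classmethod
    def read_newick(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".17g"
        ).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(lf.taxon.label for lf in self._tree.leaf_node_iter())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def total_length(self) -> float:
        return sum(
            e.length for e in self._tree.preorder_edge_iter()
            if e.tail_node is not None and e.length is not None
        )

    def rerooted_at_edge(self, edge_index: int, fraction: float = 0.5) -> "PhyloTree":
        """A copy rerooted part-way along the ``edge_index``-th internal or
        terminal edge (preorder order); used for pulley-principle checks."""
        t = self._tree.clone(depth=1)
        edges = [e for e in t.preorder_edge_iter() if e.tail_node is not None]
        edge = edges[edge_index]
        t.reroot_at_edge(edge, length1=edge.length * fraction,
                         length2=edge.length * (1 - fraction),
                         update_bipartitions=False)
        return PhyloTree(t)

    def flatten(self, taxa_order) -> FlatTree:
        """Number nodes in postorder against a given alignment taxon order."""
        row_of = {name: i for i, name in enumerate(taxa_order)}
        missing = [l for l in self.leaf_labels if l not in row_of]
        extra = [n for n in row_of if n not in set(self.leaf_labels)]
        if missing or extra:
            raise ValueError(
                "tree/alignment taxa mismatch: "
                f"tree-only={missing}, alignment-only={extra}"
            )
        ids: dict = {}
        children: list = []
        leaf_rows: dict = {}
        blens: list = []
        for node in self._tree.postorder_node_iter():
            nid = len(children)
            ids[node] = nid
            if node.is_leaf():
                children.append(())
                leaf_rows[nid] = row_of[node.taxon.label]
            else:
                children.append(
                    tuple((ids[ch], float(ch.edge.length)) for ch in node.child_nodes())
                )
            blens.append(
                float(node.edge.length)
                if node.parent_node is not None and node.edge.length is not None
                else 0.0
            )
        return FlatTree(
            n_nodes=len(children),
            children=tuple(children),
            leaf_taxon_row=leaf_rows,
            branch_lengths=np.asarray(blens),
        )
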