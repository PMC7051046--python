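"""Universal genetic code constants and the MG94-style codon generator.

The state space is the 61 sense codons of the universal code.  Substitutions
between codons differing at exactly one nucleotide position are classified
as synonymous or nonsynonymous and as transitions or transversions; the
generator entry for such a change is::

    q(x -> y) = rate_class_multiplier * exchangeability(a, b) * pi_target

where ``pi_target`` is the frequency of the replacement nucleotide at the
affected codon position (MG94 / F3x4 convention) and the class multiplier is
the site's synonymous rate for synonymous changes or its nonsynonymous rate
times the global omega-like scale for nonsynonymous ones.  The model is
time-reversible with stationary codon frequencies proportional to the
product of position-specific nucleotide frequencies.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

_standard = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_standard.stop_codons))
CODONS = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if a + b + c not in _standard.stop_codons
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AMINO_ACIDS = tuple(_standard.forward_table[c] for c in CODONS)
N_CODONS = len(CODONS)  # 61

# purine/pyrimidine pairs
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _single_step_pairs():
    """All ordered codon pairs differing at exactly one position."""
    rows, cols, pos, from_n, to_n, is_ts, is_syn = [], [], [], [], [], [], []
    for i, x in enumerate(CODONS):
        for j, y in enumerate(CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if x[p] != y[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            rows.append(i)
            cols.append(j)
            pos.append(p)
            from_n.append(NUC_INDEX[x[p]])
            to_n.append(NUC_INDEX[y[p]])
            is_ts.append((x[p], y[p]) in _TRANSITIONS)
            is_syn.append(AMINO_ACIDS[i] == AMINO_ACIDS[j])
    return tuple(np.asarray(a) for a in (rows, cols, pos, from_n, to_n, is_ts, is_syn))

(PAIR_ROWS, PAIR_COLS, PAIR_POS, PAIR_FROM, PAIR_TO,
 PAIR_IS_TRANSITION, PAIR_IS_SYNONYMOUS) = _single_step_pairs()


class CodonModelParams:
    """Nucleotide exchangeabilities and equilibrium frequencies.

    Parameters
    ----------
    kappa : float
        Transition/transversion rate ratio (HKY).  Ignored if
        ``exchangeabilities`` is given.
    position_freqs : (3, 4) array, optional
        Position-specific nucleotide frequencies (F3x4).  Defaults to flat,
        which yields uniform codon frequencies over the 61 sense codons.
    exchangeabilities : (4, 4) symmetric array, optional
        General reversible nucleotide exchangeabilities; overrides ``kappa``.
    """

    def __init__(self, kappa: float = 2.0, position_freqs=None, exchangeabilities=None):
        if exchangeabilities is not None:
            ex = np.asarray(exchangeabilities, dtype=float)
            if ex.shape != (4, 4) or not np.allclose(ex, ex.T):
                raise ValueError("exchangeabilities must be a symmetric 4x4 matrix")
            self.exchangeabilities = ex
            self.kappa = None
        else:
            if not (kappa > 0):
                raise ValueError(f"kappa must be positive, got {kappa}")
            ex = np.ones((4, 4))
            for a, b in _TRANSITIONS:
                ex[NUC_INDEX[a], NUC_INDEX[b]] = kappa
            np.fill_diagonal(ex, 0.0)
            self.exchangeabilities = ex
            self.kappa = float(kappa)
        if position_freqs is None:
            pf = np.full((3, 4), 0.25)
        else:
            pf = np.asarray(position_freqs, dtype=float)
            if pf.shape != (3, 4):
                raise ValueError("position_freqs must have shape (3, 4)")
            if np.any(pf <= 0):
                raise ValueError("position frequencies must be strictly positive")
            pf = pf / pf.sum(axis=1, keepdims=True)
        self.position_freqs = pf
        # stationary codon frequencies: product over positions, renormalized
        # over the sense codons (F3x4)
        pi = np.array(
            [np.prod([pf[p, NUC_INDEX[c[p]]] for p in range(3)]) for c in CODONS]
        )
        self.codon_freqs = pi / pi.sum()
        self._base_matrices = None

    @classmethod
    def from_alignment(cls, alignment, kappa: float = 2.0, pseudocount: float = 1.0):
        """F3x4 empirical frequencies from a codon alignment.

        A small pseudocount keeps all frequencies positive (required for a
        valid reversible generator on the full sense-codon state space).
        """
        counts = alignment.position_nucleotide_counts() + pseudocount
        return cls(kappa=kappa, position_freqs=counts)

    def base_matrices(self):
        """Synonymous and nonsynonymous generator parts, jointly normalized.

        Returns ``(S, N)`` with zero diagonals such that the neutral
        generator ``S + N`` (unit synonymous and nonsynonymous rates,
        omega = 1) has expected rate 1 under the stationary frequencies;
        branch lengths are then expected substitutions per codon site on
        that neutral scale.
        """
        if self._base_matrices is None:
            vals = (
                self.exchangeabilities[PAIR_FROM, PAIR_TO]
                * self.position_freqs[PAIR_POS, PAIR_TO]
            )
            s = np.zeros((N_CODONS, N_CODONS))
            n = np.zeros((N_CODONS, N_CODONS))
            syn = PAIR_IS_SYNONYMOUS
            s[PAIR_ROWS[syn], PAIR_COLS[syn]] = vals[syn]
            n[PAIR_ROWS[~syn], PAIR_COLS[~syn]] = vals[~syn]
            pi = self.codon_freqs
            c = float(pi @ (s.sum(axis=1) + n.sum(axis=1)))
            self._base_matrices = (s / c, n / c)
        return self._base_matrices


def build_generator(
    params: CodonModelParams,
    syn_rate: float,
    nonsyn_rate: float,
    nonsyn_scale: float = 1.0,
) -> np.ndarray:
    """61x61 rate matrix for one (synonymous, nonsynonymous) rate pair.

    Rows sum to zero; the matrix is reversible with respect to
    ``params.codon_freqs``.
    """
    if syn_rate < 0 or nonsyn_rate < 0 or nonsyn_scale < 0:
        raise ValueError("rates and nonsyn_scale must be non-negative")
    s, n = params.base_matrices()
    q = syn_rate * s + (nonsyn_rate * nonsyn_scale) * n
    np.fill_diagonal(q, 0.0)
    q[np.diag_indices_from(q)] = -q.sum(axis=1)
    return q


def reversible_eigen(q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a reversible generator via symmetrization.

    Returns ``(eigenvalues, left, right)`` with
    ``expm(t q) = left @ diag(exp(eigenvalues * t)) @ right``.
    """
    sqrt_pi = np.sqrt(pi)
    b = q * (sqrt_pi[:, None] / sqrt_pi[None, :])
    b = 0.5 * (b + b.T)  # symmetrize away rounding noise
    lam, v = np.linalg.eigh(b)
    left = v / sqrt_pi[:, None]
    right = v.T * sqrt_pi[None, :]
    return lam, left, right


def transition_matrix(eig, t: float) -> np.ndarray:
    """Row-stochastic ``P(t) = expm(t Q)`` from a reversible eigensystem."""
    lam, left, right = eig
    p = (left * np.exp(lam * t)) @ right
    np.clip(p, 0.0, None, out=p)
    return p
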