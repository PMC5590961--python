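"""Shared codon-level tables: standard genetic code, NG86 site/pathway
counts, and the GY94 codon rate matrix.

Everything here is derived once, at import time, from Biopython's standard
codon table, and consumed by both the forward simulator and the Ks
estimators.  Sense codons are indexed 0..60 in lexicographic order.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

NT = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in _TABLE.forward_table if set(c) <= set(NT))
)
N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)

_PURINES = {"A", "G"}


def is_transition(x: str, y: str) -> bool:
    """A<->G or C<->T single-nucleotide exchange."""
    return x != y and ((x in _PURINES) == (y in _PURINES))


def _single_nt_neighbours(codon: str):
    for pos in range(3):
        for nt in NT:
            if nt != codon[pos]:
                yield pos, codon[:pos] + nt + codon[pos + 1 :]


def _site_counts() -> np.ndarray:
    """NG86 synonymous-site fractions per sense codon.

    Each codon position counts as one site, split into synonymous and
    nonsynonymous fractions by the proportion of its single-nucleotide
    changes (to sense codons only; changes to stops shrink the
    denominator) that preserve the amino acid.
    """
    s = np.zeros(N_CODONS)
    for i, codon in enumerate(SENSE_CODONS):
        aa = CODON_AA[i]
        for pos in range(3):
            syn = 0
            valid = 0
            for nt in NT:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if alt in STOP_CODONS:
                    continue
                valid += 1
                if _TABLE.forward_table[alt] == aa:
                    syn += 1
            if valid:
                s[i] += syn / valid
    return s


SYN_SITES: np.ndarray = _site_counts()  # shape (61,)


def _pathway_diffs() -> tuple[np.ndarray, np.ndarray]:
    """NG86 synonymous/nonsynonymous difference counts for all codon pairs.

    All minimal mutational pathways between the two codons are enumerated;
    pathways passing through a stop codon are discarded (unless every
    pathway does, in which case all are kept) and the per-step synonymous /
    nonsynonymous classification is averaged over the surviving pathways
    with equal weight.
    """
    sd = np.zeros((N_CODONS, N_CODONS))
    nd = np.zeros((N_CODONS, N_CODONS))
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i == j:
                continue
            pos_diff = [p for p in range(3) if a[p] != b[p]]
            paths = []
            for order in permutations(pos_diff):
                cur = a
                steps = []
                through_stop = False
                for p in order:
                    nxt = cur[:p] + b[p] + cur[p + 1 :]
                    if nxt in STOP_CODONS:
                        through_stop = True
                        steps.append((cur, nxt))
                    else:
                        steps.append((cur, nxt))
                    cur = nxt
                paths.append((through_stop, steps))
            usable = [st for ok, st in paths if not ok] or [st for _, st in paths]
            s_tot = n_tot = 0.0
            for steps in usable:
                for x, y in steps:
                    if (
                        x not in STOP_CODONS
                        and y not in STOP_CODONS
                        and _TABLE.forward_table[x] == _TABLE.forward_table[y]
                    ):
                        s_tot += 1
                    else:
                        n_tot += 1
            sd[i, j] = s_tot / len(usable)
            nd[i, j] = n_tot / len(usable)
    return sd, nd


SYN_DIFFS, NONSYN_DIFFS = _pathway_diffs()  # shape (61, 61)

# Boolean masks over single-nucleotide codon neighbours.
_NEIGHBOUR = np.zeros((N_CODONS, N_CODONS), dtype=bool)
_TS = np.zeros((N_CODONS, N_CODONS), dtype=bool)
_SYN = np.zeros((N_CODONS, N_CODONS), dtype=bool)
for _i, _a in enumerate(SENSE_CODONS):
    for _pos, _alt in _single_nt_neighbours(_a):
        _j = CODON_INDEX.get(_alt)
        if _j is None:  # stop codon
            continue
        _NEIGHBOUR[_i, _j] = True
        _TS[_i, _j] = is_transition(_a[_pos], _alt[_pos])
        _SYN[_i, _j] = CODON_AA[_i] == CODON_AA[_j]


def gy94_rate_matrix(
    kappa: float, omega: float, freqs: np.ndarray | None = None
) -> np.ndarray:
    """GY94 codon rate matrix (61x61), rows summing to zero.

    Off-diagonal rate i->j is nonzero only for single-nucleotide
    neighbours: proportional to the target codon frequency, multiplied by
    ``kappa`` for transitions and by ``omega`` for amino-acid-changing
    substitutions.  Rates to and from stop codons are zero by construction
    (stops are not states).  The matrix is *not* normalised here; callers
    scale time explicitly.
    """
    if freqs is None:
        freqs = np.full(N_CODONS, 1.0 / N_CODONS)
    q = np.where(_NEIGHBOUR, freqs[None, :], 0.0)
    q = np.where(_TS, q * kappa, q)
    q = np.where(~_SYN & _NEIGHBOUR, q * omega, q)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def synonymous_flux(q: np.ndarray, freqs: np.ndarray | None = None) -> float:
    """Expected synonymous substitutions per codon per unit time under q."""
    if freqs is None:
        freqs = np.full(N_CODONS, 1.0 / N_CODONS)
    return float((freqs[:, None] * np.where(_SYN, q, 0.0)).sum())


def total_flux(q: np.ndarray, freqs: np.ndarray | None = None) -> float:
    """Expected substitutions per codon per unit time under q."""
    if freqs is None:
        freqs = np.full(N_CODONS, 1.0 / N_CODONS)
    off = q - np.diag(np.diag(q))
    return float((freqs[:, None] * off).sum())
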