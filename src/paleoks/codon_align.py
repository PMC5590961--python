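"""Protein-guided codon alignment of gene families.

Pairwise global alignment (Needleman-Wunsch-Gotoh, BLOSUM62, affine gaps
11/1, end gaps penalised), a single-pass progressive multiple alignment
over an NJ guide tree for larger families, and back-translation of the
protein alignment to codons.  Simulated families are gap-light, so a
single progressive pass (no iterative refinement) is sufficient: Ks
estimation needs homologous columns, not optimal alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .seqio import CodingSequence
from .simgraph import SCORE_MATRIX, _make_aligner, _sanitise, encode_peptide

GAP_CODON = "---"


@dataclass(frozen=True)
class PairwiseProteinAlignment:
    """Two gapped peptide rows of equal length plus the optimal score."""

    a: str
    b: str
    score: float


@dataclass(frozen=True)
class ProteinMSA:
    """A multiple protein alignment: equal-length gapped rows keyed by id."""

    rows: dict[str, str]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.rows)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))


@dataclass(frozen=True)
class CodonAlignment:
    """Codon rows (lists of sense codons or ``---``) keyed by gene id."""

    rows: dict[str, list[str]]

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(self.rows)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def degapped(self, gene_id: str) -> str:
        return "".join(c for c in self.rows[gene_id] if c != GAP_CODON)


def global_protein_align(pep_a: str, pep_b: str, gap_open: int = 11,
                         gap_extend: int = 1) -> PairwiseProteinAlignment:
    """Optimal global alignment with affine gaps; end gaps are penalised."""
    if not pep_a or not pep_b:
        raise ValueError("peptides must be non-empty")
    aligner = _make_aligner(gap_open, gap_extend, local=False)
    alignment = aligner.align(_sanitise(pep_a), _sanitise(pep_b))[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    # Restore any non-standard residues masked for scoring.
    ga = _restore(ga, pep_a)
    gb = _restore(gb, pep_b)
    return PairwiseProteinAlignment(a=ga, b=gb, score=float(alignment.score))


def _restore(gapped: str, original: str) -> str:
    out = []
    it = iter(original)
    for c in gapped:
        out.append("-" if c == "-" else next(it))
    return "".join(out)


def _poisson_distance(aln: PairwiseProteinAlignment) -> float:
    """Poisson-corrected p-distance over gap-free columns."""
    same = diff = 0
    for x, y in zip(aln.a, aln.b):
        if x == "-" or y == "-":
            continue
        if x == y:
            same += 1
        else:
            diff += 1
    total = same + diff
    p = diff / total if total else 0.0
    return -math.log(max(1.0 - p, 1e-6))


def _profile(rows: list[str]) -> np.ndarray:
    """Per-column residue frequency profile (21 residue classes, gaps
    excluded from the frequency mass)."""
    ncol = len(rows[0])
    prof = np.zeros((ncol, 21))
    for row in rows:
        enc = encode_peptide(row.replace("-", "X"))
        for j, ch in enumerate(row):
            if ch != "-":
                prof[j, enc[j]] += 1
    return prof


def _profile_align(rows_a: list[str], rows_b: list[str], gap_open: float,
                   gap_extend: float) -> tuple[list[str], list[str]]:
    """Affine-gap profile-profile NW with mean-of-pairs column scores.

    Traceback ties resolve match > gap-in-b (advance A only) > gap-in-a,
    making the result deterministic.
    """
    pa, pb = _profile(rows_a), _profile(rows_b)
    na, nb = pa.shape[0], pb.shape[0]
    counts_a, counts_b = pa.sum(axis=1), pb.sum(axis=1)
    # Mean-of-pairs substitution score between columns.
    smat = (pa @ SCORE_MATRIX @ pb.T)
    denom = np.outer(counts_a, counts_b)
    denom[denom == 0] = 1.0
    smat /= denom
    open_cost = gap_open + gap_extend
    neg = -1e18
    m = np.full((na + 1, nb + 1), neg)
    ix = np.full((na + 1, nb + 1), neg)  # gap in B (A advances)
    iy = np.full((na + 1, nb + 1), neg)  # gap in A (B advances)
    m[0, 0] = 0.0
    for i in range(1, na + 1):
        ix[i, 0] = -open_cost - gap_extend * (i - 1)
    for j in range(1, nb + 1):
        iy[0, j] = -open_cost - gap_extend * (j - 1)
    for i in range(1, na + 1):
        mi1 = m[i - 1]
        ixi1 = ix[i - 1]
        iyi1 = iy[i - 1]
        for j in range(1, nb + 1):
            best_prev = max(mi1[j - 1], ixi1[j - 1], iyi1[j - 1])
            m[i, j] = best_prev + smat[i - 1, j - 1]
            ix[i, j] = max(mi1[j] - open_cost, ixi1[j] - gap_extend,
                           iyi1[j] - open_cost)
            iy[i, j] = max(m[i, j - 1] - open_cost, iy[i, j - 1] - gap_extend,
                           ix[i, j - 1] - open_cost)
    # Traceback.
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = na, nb
    state = int(np.argmax([m[i, j], ix[i, j], iy[i, j]]))
    while i > 0 or j > 0:
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        if state == 0:
            prevs = (m[i - 1, j - 1], ix[i - 1, j - 1], iy[i - 1, j - 1])
            out_a.append("col")
            out_b.append("col")
            i, j = i - 1, j - 1
            state = int(np.argmax(prevs))
        elif state == 1:
            came_m = m[i - 1, j] - open_cost
            came_ix = ix[i - 1, j] - gap_extend
            came_iy = iy[i - 1, j] - open_cost
            out_a.append("col")
            out_b.append("gap")
            i -= 1
            state = int(np.argmax([came_m, came_ix, came_iy]))
        else:
            came_m = m[i, j - 1] - open_cost
            came_iy = iy[i, j - 1] - gap_extend
            came_ix = ix[i, j - 1] - open_cost
            out_a.append("gap")
            out_b.append("col")
            j -= 1
            state = int(np.argmax([came_m, came_ix, came_iy]))
    out_a.reverse()
    out_b.reverse()
    new_a = _expand(rows_a, out_a)
    new_b = _expand(rows_b, out_b)
    return new_a, new_b


def _expand(rows: list[str], ops: list[str]) -> list[str]:
    out = ["" for _ in rows]
    col = 0
    for op in ops:
        if op == "col":
            for k, row in enumerate(rows):
                out[k] += row[col]
            col += 1
        else:
            for k in range(len(rows)):
                out[k] += "-"
    return out


def progressive_msa(peptides: Mapping[str, str], gap_open: int = 11,
                    gap_extend: int = 1) -> ProteinMSA:
    """Progressive multiple alignment over an NJ guide tree.

    The guide tree is neighbour joining on Poisson-corrected p-distances
    from all pairwise global alignments; profiles are merged postorder
    with mean-of-pairs profile NW.  Two sequences reduce to the plain
    pairwise global alignment; one sequence is returned unchanged.
    """
    ids = sorted(peptides)
    if not ids:
        raise ValueError("no peptides given")
    if len(ids) == 1:
        return ProteinMSA(rows={ids[0]: peptides[ids[0]]})
    if len(ids) == 2:
        aln = global_protein_align(peptides[ids[0]], peptides[ids[1]],
                                   gap_open, gap_extend)
        return ProteinMSA(rows={ids[0]: aln.a, ids[1]: aln.b})
    from .distribution import nj_tree  # deferred: avoids a module cycle

    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_protein_align(peptides[ids[i]], peptides[ids[j]],
                                       gap_open, gap_extend)
            dist[i, j] = dist[j, i] = _poisson_distance(aln)
    tree = nj_tree(dist, ids)

    def merge(node) -> tuple[list[str], list[str]]:
        if node.is_tip():
            return [node.name], [peptides[node.name]]
        child_results = [merge(c) for c in node.children]
        ids_acc, rows_acc = child_results[0]
        for ids_next, rows_next in child_results[1:]:
            rows_acc, rows_next = _profile_align(rows_acc, rows_next,
                                                 float(gap_open),
                                                 float(gap_extend))
            rows_acc = rows_acc + rows_next
            ids_acc = ids_acc + ids_next
        return ids_acc, rows_acc

    order, rows = merge(tree)
    return ProteinMSA(rows={gid: row for gid, row in
                            sorted(zip(order, rows))})


def backtranslate(msa: ProteinMSA,
                  cds_lookup: Mapping[str, CodingSequence]) -> CodonAlignment:
    """Replace each residue with its source codon; gaps become ``---``."""
    rows: dict[str, list[str]] = {}
    for gid, pep_row in msa.rows.items():
        cds = cds_lookup[gid]
        expected = pep_row.replace("-", "")
        if expected != cds.pep:
            raise ValueError(
                f"peptide row of {gid} does not match the translation of its CDS")
        codons: list[str] = []
        pos = 0
        for ch in pep_row:
            if ch == "-":
                codons.append(GAP_CODON)
            else:
                codons.append(cds.nt[3 * pos:3 * pos + 3])
                pos += 1
        rows[gid] = codons
    return CodonAlignment(rows=rows)


def pairwise_codon_view(alignment: CodonAlignment, id_a: str,
                        id_b: str) -> list[tuple[str, str]]:
    """Gap-free codon pairs between two rows (columns with a gap in
    either row are dropped)."""
    row_a, row_b = alignment.rows[id_a], alignment.rows[id_b]
    return [
        (ca, cb)
        for ca, cb in zip(row_a, row_b)
        if ca != GAP_CODON and cb != GAP_CODON
    ]


def align_family_codons(members: Sequence[CodingSequence], gap_open: int = 11,
                        gap_extend: int = 1) -> CodonAlignment:
    """Protein MSA of a family followed by back-translation."""
    peptides = {m.id: m.pep for m in members}
    msa = progressive_msa(peptides, gap_open, gap_extend)
    return backtranslate(msa, {m.id: m for m in members})
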