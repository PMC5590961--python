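"""All-against-all local protein alignment and the similarity graph.

Exact Smith-Waterman-Gotoh with BLOSUM62 and affine gaps (open 11,
extend 1: a length-k gap costs 11 + k).  The all-vs-all scan computes
optimal local scores with a numba kernel; pairs whose Karlin-Altschul
E-value passes the cutoff get a full traceback (Biopython's exact
PairwiseAligner) for identity, length and span statistics.  Passing hits
are assembled into a weighted undirected similarity graph, the substrate
for Markov clustering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from numba import njit

from .seqio import CodingSequence, PipelineConfig

logger = logging.getLogger("paleoks")

# Gapped Karlin-Altschul constants for BLOSUM62 / 11 / 1.
LAMBDA = 0.267
KA_K = 0.041

_STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"
_NONSTD_SCORE = -4.0


def _build_score_matrix() -> np.ndarray:
    """21x21 matrix: BLOSUM62 for the 20 standard residues, -4 for any
    non-standard residue against everything (BLOSUM62's minimum)."""
    b62 = substitution_matrices.load("BLOSUM62")
    m = np.full((21, 21), _NONSTD_SCORE)
    for i, x in enumerate(_STANDARD_AA):
        for j, y in enumerate(_STANDARD_AA):
            m[i, j] = b62[x, y]
    return m


SCORE_MATRIX = _build_score_matrix()
_AA_INDEX = np.full(128, 20, dtype=np.int64)
for _i, _c in enumerate(_STANDARD_AA):
    _AA_INDEX[ord(_c)] = _i


def encode_peptide(pep: str) -> np.ndarray:
    """Map residues to matrix indices; non-standard letters share index 20."""
    arr = np.frombuffer(pep.encode("ascii"), dtype=np.uint8)
    return _AA_INDEX[arr]


@njit(cache=False)
def _sw_score(a, b, mat, gap_open, gap_extend):  # pragma: no cover - jit
    n, m = a.size, b.size
    h_row = np.zeros(m + 1)
    e_row = np.full(m + 1, -1e18)
    best = 0.0
    open_cost = gap_open + gap_extend
    for i in range(n):
        f = -1e18
        diag = 0.0
        ai = a[i]
        for j in range(1, m + 1):
            up = h_row[j]
            e = e_row[j] - gap_extend
            eo = up - open_cost
            if eo > e:
                e = eo
            e_row[j] = e
            h = diag + mat[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            diag = up
            h_row[j] = h
            if h > best:
                best = h
            f -= gap_extend
            fo = h - open_cost
            if fo > f:
                f = fo
    return best


@dataclass
class AlignmentHit:
    """One directed local-alignment result forming a similarity-graph edge."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    percent_identity: float
    aln_len: int
    query_span: tuple[int, int]  # half-open, 0-based
    subject_span: tuple[int, int]
    mismatches: int = 0
    gap_opens: int = 0


def karlin_altschul_evalue(raw_score: float, len_query: int,
                           len_db_total: int) -> tuple[float, float]:
    """Bit score and E-value from a raw score: E = K * m * n * exp(-lambda*S).

    Uses the gapped BLOSUM62/11/1 constants with raw (uncorrected)
    lengths; monotone decreasing in the score, linear in m * n.
    """
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    if len_query < 1 or len_db_total < 1:
        raise ValueError("lengths must be >= 1")
    bit = (LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)
    e = KA_K * len_query * len_db_total * math.exp(-LAMBDA * raw_score)
    return bit, e


def _make_aligner(gap_open: int, gap_extend: int, local: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    alphabet = _STANDARD_AA + "X"
    mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for i, x in enumerate(alphabet):
        for j, y in enumerate(alphabet):
            mat[x, y] = SCORE_MATRIX[min(i, 20), min(j, 20)]
    aligner.substitution_matrix = mat
    aligner.mode = "local" if local else "global"
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def _sanitise(pep: str) -> str:
    return "".join(c if c in _STANDARD_AA else "X" for c in pep)


def _alignment_stats(alignment) -> tuple[int, int, int, int,
                                         tuple[int, int], tuple[int, int]]:
    counts = alignment.counts()
    aln_len = counts.gaps + counts.identities + counts.mismatches
    qa, sa = alignment.aligned
    q_span = (int(qa[0][0]), int(qa[-1][1]))
    s_span = (int(sa[0][0]), int(sa[-1][1]))
    gap_opens = 0
    for blocks in (qa, sa):
        for k in range(1, len(blocks)):
            if blocks[k][0] != blocks[k - 1][1]:
                gap_opens += 1
    return counts.identities, counts.mismatches, aln_len, gap_opens, q_span, s_span


def local_align(pep_a: str, pep_b: str, gap_open: int = 11,
                gap_extend: int = 1) -> AlignmentHit | None:
    """Optimal Smith-Waterman-Gotoh local alignment of two peptides.

    Returns ``None`` when no residue pair scores positive (empty local
    alignment).  ``e_value`` is left as NaN: it depends on the database
    size and is filled in by :func:`all_vs_all`.
    """
    if not pep_a or not pep_b:
        raise ValueError("peptides must be non-empty")
    aligner = _make_aligner(gap_open, gap_extend, local=True)
    sa, sb = _sanitise(pep_a), _sanitise(pep_b)
    score = aligner.score(sa, sb)
    if score <= 0:
        return None
    alignment = aligner.align(sa, sb)[0]
    identities, mismatches, aln_len, gap_opens, q_span, s_span = _alignment_stats(alignment)
    bit, _ = karlin_altschul_evalue(score, len(pep_a), len(pep_b))
    return AlignmentHit(
        query_id="query",
        subject_id="subject",
        raw_score=int(round(score)),
        bit_score=bit,
        e_value=math.nan,
        percent_identity=100.0 * identities / aln_len,
        aln_len=aln_len,
        query_span=q_span,
        subject_span=s_span,
        mismatches=mismatches,
        gap_opens=gap_opens,
    )


def all_vs_all(queries: Sequence[CodingSequence], config: PipelineConfig,
               subjects: Sequence[CodingSequence] | None = None
               ) -> list[AlignmentHit]:
    """Directed local-alignment hits passing the E-value cutoff.

    With one sequence set, every ordered pair (a, b), a != b, is searched
    against the set itself (self-hits excluded).  With two sets, hits in
    both directions (A vs database B and B vs database A) are returned.
    Each unordered pair is scored once (the optimal local score is
    symmetric); tracebacks are computed only for pairs that can pass the
    cutoff, which keeps the scan exact but fast.
    """
    cross = subjects is not None
    set_a = list(queries)
    set_b = list(subjects) if cross else set_a
    if not cross and len(set_a) < 2:
        raise ValueError("all-vs-all requires >= 2 sequences")
    enc_a = [encode_peptide(s.pep) for s in set_a]
    enc_b = [encode_peptide(s.pep) for s in set_b] if cross else enc_a
    db_len_b = sum(len(s.pep) for s in set_b)  # database for a -> b queries
    db_len_a = sum(len(s.pep) for s in set_a)
    aligner = _make_aligner(config.gap_open, config.gap_extend, local=True)
    hits: list[AlignmentHit] = []
    pairs: Iterable[tuple[int, int]]
    if cross:
        pairs = ((i, j) for i in range(len(set_a)) for j in range(len(set_b)))
    else:
        pairs = ((i, j) for i in range(len(set_a)) for j in range(i + 1, len(set_a)))
    go, ge = float(config.gap_open), float(config.gap_extend)
    for i, j in pairs:
        score = _sw_score(enc_a[i], enc_b[j], SCORE_MATRIX, go, ge)
        if score <= 0:
            continue
        a, b = set_a[i], set_b[j]
        _, e_ab = karlin_altschul_evalue(score, len(a.pep), db_len_b)
        _, e_ba = karlin_altschul_evalue(score, len(b.pep), db_len_a)
        if min(e_ab, e_ba) > config.evalue_cutoff:
            continue
        alignment = aligner.align(_sanitise(a.pep), _sanitise(b.pep))[0]
        identities, mismatches, aln_len, gap_opens, q_span, s_span = \
            _alignment_stats(alignment)
        pid = 100.0 * identities / aln_len
        raw = int(round(alignment.score))
        for (qid, sid, e, qs, ss) in (
            (a.id, b.id, e_ab, q_span, s_span),
            (b.id, a.id, e_ba, s_span, q_span),
        ):
            if e > config.evalue_cutoff:
                continue
            bit, _ = karlin_altschul_evalue(raw, len(a.pep if qid == a.id else b.pep),
                                            db_len_b if qid == a.id else db_len_a)
            hits.append(AlignmentHit(
                query_id=qid, subject_id=sid, raw_score=raw, bit_score=bit,
                e_value=e, percent_identity=pid, aln_len=aln_len,
                query_span=qs, subject_span=ss,
                mismatches=mismatches, gap_opens=gap_opens,
            ))
    logger.info("all-vs-all: %d directed hits at E <= %g",
                len(hits), config.evalue_cutoff)
    return hits


MAX_EDGE_WEIGHT = 200.0


def build_similarity_graph(hits: Iterable[AlignmentHit],
                           all_ids: Iterable[str] | None = None) -> nx.Graph:
    """Weighted undirected graph over genes from directed hits.

    Edge weight is min(200, -log10 E), averaged over the available
    directions (E = 0 maps to 200).  ``all_ids`` adds isolated nodes for
    genes without hits so downstream clustering sees singletons.
    """
    directed: dict[tuple[str, str], float] = {}
    for h in hits:
        w = MAX_EDGE_WEIGHT if h.e_value == 0 else min(
            MAX_EDGE_WEIGHT, -math.log10(h.e_value))
        key = (h.query_id, h.subject_id)
        directed[key] = max(directed.get(key, -math.inf), w)
    graph = nx.Graph()
    if all_ids is not None:
        graph.add_nodes_from(all_ids)
    undirected: dict[tuple[str, str], list[float]] = {}
    for (q, s), w in directed.items():
        undirected.setdefault(tuple(sorted((q, s))), []).append(w)
    for (u, v), ws in undirected.items():
        graph.add_edge(u, v, weight=sum(ws) / len(ws))
    return graph


def write_hits_tsv(hits: Sequence[AlignmentHit], path) -> None:
    """12-column tabular hit table (1-based inclusive coordinates)."""
    from .seqio import write_tsv

    rows = [
        {
            "query": h.query_id,
            "subject": h.subject_id,
            "pident": h.percent_identity,
            "length": h.aln_len,
            "mismatch": h.mismatches,
            "gapopen": h.gap_opens,
            "qstart": h.query_span[0] + 1,
            "qend": h.query_span[1],
            "sstart": h.subject_span[0] + 1,
            "send": h.subject_span[1],
            "evalue": h.e_value,
            "bitscore": h.bit_score,
        }
        for h in hits
    ]
    write_tsv(rows, path, columns=["query", "subject", "pident", "length",
                                   "mismatch", "gapopen", "qstart", "qend",
                                   "sstart", "send", "evalue", "bitscore"])
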