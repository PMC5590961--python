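"""One-to-one ortholog identification and the ortholog Ks distribution.

Reciprocal best hits between two proteomes (best by bit score, ties by
E-value then subject id), filtered to at least 30% identity over at
least 150 aligned amino acids.  Each retained pair dates the speciation
once, so the ortholog distribution is unweighted — no redundancy
correction is needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ks import KsEstimate, estimate_ks_ng86
from .seqio import CodingSequence, PipelineConfig
from .simgraph import AlignmentHit

logger = logging.getLogger("paleoks")


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit gene pair with its alignment statistics."""

    gene_a: str
    gene_b: str
    bit_score: float
    percent_identity: float
    aln_len: int
    ks: KsEstimate | None = None


def _best_hits(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Best hit per query: highest bit score, then lowest E-value, then
    lexicographically smallest subject id."""
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key_new = (-h.bit_score, h.e_value, h.subject_id)
        key_cur = (-cur.bit_score, cur.e_value, cur.subject_id)
        if key_new < key_cur:
            best[h.query_id] = h
    return best


def reciprocal_best_hits(hits_a_to_b: Iterable[AlignmentHit],
                         hits_b_to_a: Iterable[AlignmentHit]
                         ) -> list[OrthologPair]:
    """Mutual best-hit pairs; one-to-one by construction."""
    best_ab = _best_hits(hits_a_to_b)
    best_ba = _best_hits(hits_b_to_a)
    pairs: list[OrthologPair] = []
    for qa, hit in sorted(best_ab.items()):
        back = best_ba.get(hit.subject_id)
        if back is not None and back.subject_id == qa:
            pairs.append(OrthologPair(
                gene_a=qa,
                gene_b=hit.subject_id,
                bit_score=hit.bit_score,
                percent_identity=hit.percent_identity,
                aln_len=hit.aln_len,
            ))
    logger.info("reciprocal best hits: %d pairs", len(pairs))
    return pairs


def filter_ortholog_pairs(pairs: Sequence[OrthologPair],
                          min_identity: float = 30.0,
                          min_len: int = 150) -> list[OrthologPair]:
    """Keep pairs with identity >= min_identity over >= min_len aligned
    columns (both thresholds inclusive)."""
    kept: list[OrthologPair] = []
    n_id = n_len = 0
    for p in pairs:
        if p.percent_identity < min_identity:
            n_id += 1
        elif p.aln_len < min_len:
            n_len += 1
        else:
            kept.append(p)
    logger.info("ortholog filter: kept %d, rejected %d (identity) + %d (length)",
                len(kept), n_id, n_len)
    return kept


def ortholog_ks_distribution(pairs: Sequence[OrthologPair],
                             cds_a: Mapping[str, CodingSequence],
                             cds_b: Mapping[str, CodingSequence],
                             config: PipelineConfig | None = None
                             ) -> tuple[list[OrthologPair], pd.DataFrame]:
    """NG86 Ks per ortholog pair from direct pairwise codon alignment.

    Returns the pairs with Ks attached and an unweighted distribution
    table; saturated pairs keep their +inf sentinel and are excluded from
    densities by the same rules as the paranome.
    """
    from .codon_align import backtranslate, global_protein_align, \
        pairwise_codon_view, ProteinMSA

    config = config or PipelineConfig()
    out: list[OrthologPair] = []
    rows: list[dict] = []
    for p in pairs:
        a, b = cds_a[p.gene_a], cds_b[p.gene_b]
        aln = global_protein_align(a.pep, b.pep, config.gap_open,
                                   config.gap_extend)
        msa = ProteinMSA(rows={a.id: aln.a, b.id: aln.b})
        codon_aln = backtranslate(msa, {a.id: a, b.id: b})
        codon_pairs = pairwise_codon_view(codon_aln, a.id, b.id)
        if not codon_pairs:
            continue
        est = estimate_ks_ng86(codon_pairs, a.id, b.id)
        out.append(OrthologPair(**{**p.__dict__, "ks": est}))
        rows.append({
            "gene_a": p.gene_a,
            "gene_b": p.gene_b,
            "ks": est.ks,
            "weight": 1.0,
            "identity": p.percent_identity,
            "aln_len": p.aln_len,
            "bit_score": p.bit_score,
        })
    table = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "ks", "weight", "identity",
                       "aln_len", "bit_score"])
    return out, table


def ortholog_density_entries(table: pd.DataFrame, min_ks: float = 0.05,
                             ks_max: float = 5.0) -> pd.DataFrame:
    """Entries usable for the ortholog density (same exclusions as the
    paranome: finite, min_ks <= Ks <= ks_max)."""
    if table.empty:
        return table
    ks = table["ks"].to_numpy(float)
    mask = np.isfinite(ks) & (ks >= min_ks) & (ks <= ks_max)
    return table[mask]


def write_ortholog_tsv(pairs: Sequence[OrthologPair], path) -> None:
    from .seqio import write_tsv

    rows = [
        {
            "gene_a": p.gene_a,
            "gene_b": p.gene_b,
            "identity": p.percent_identity,
            "aln_len": p.aln_len,
            "bit_score": p.bit_score,
            "ks": math.nan if p.ks is None else p.ks.ks,
        }
        for p in pairs
    ]
    write_tsv(rows, path, columns=["gene_a", "gene_b", "identity", "aln_len",
                                   "bit_score", "ks"])
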