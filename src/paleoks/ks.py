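"""Pairwise synonymous-distance (Ks) estimation.

Default estimator is NG86: per-codon synonymous-site fractions, pathway-
averaged difference counts and a Jukes-Cantor multiple-hit correction.
A pairwise maximum-likelihood estimator under a GY94 codon model with
F3x4 frequencies is available as an alternative; the downstream
distribution analysis is estimator-agnostic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from ._codons import (
    CODON_INDEX,
    N_CODONS,
    NONSYN_DIFFS,
    SENSE_CODONS,
    SYN_DIFFS,
    SYN_SITES,
    gy94_rate_matrix,
    synonymous_flux,
    total_flux,
)

logger = logging.getLogger("paleoks")

MIN_RELIABLE_CODONS = 10


@dataclass(frozen=True)
class KsEstimate:
    """One pairwise synonymous-distance measurement.

    ``ks``/``ka`` are substitutions per synonymous/nonsynonymous site;
    ``syn_sites + nonsyn_sites == 3 * codons_used`` always.  ``saturated``
    marks pS >= 3/4 where the Jukes-Cantor log is undefined (ks is then
    +inf and the pair is excluded from age distributions downstream).
    """

    gene_a: str
    gene_b: str
    ks: float
    ka: float
    syn_sites: float
    nonsyn_sites: float
    codons_used: int
    method: str = "NG86"
    saturated: bool = False
    unreliable: bool = False
    kappa: float | None = None  # fitted transition/transversion ratio (ML only)

    @property
    def omega(self) -> float:
        if self.ks == 0 or not math.isfinite(self.ks):
            return math.nan
        return self.ka / self.ks


def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site fractions of one sense codon.

    Each of the three positions contributes one site, split by the
    fraction of its sense-codon single-nucleotide changes that are
    synonymous (changes to stops are excluded from the denominator).
    """
    idx = CODON_INDEX.get(codon)
    if idx is None:
        raise ValueError(f"not a sense codon: {codon!r}")
    s = float(SYN_SITES[idx])
    return s, 3.0 - s


def ng86_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences of a codon pair."""
    ia, ib = CODON_INDEX.get(codon_a), CODON_INDEX.get(codon_b)
    if ia is None or ib is None:
        raise ValueError(f"not sense codons: {codon_a!r}, {codon_b!r}")
    return float(SYN_DIFFS[ia, ib]), float(NONSYN_DIFFS[ia, ib])


def _codon_indices(codon_pairs: Sequence[tuple[str, str]]) -> tuple[np.ndarray, np.ndarray]:
    try:
        ia = np.array([CODON_INDEX[a] for a, _ in codon_pairs])
        ib = np.array([CODON_INDEX[b] for _, b in codon_pairs])
    except KeyError as exc:
        raise ValueError(f"not a sense codon: {exc.args[0]!r}") from None
    return ia, ib


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return math.inf, True
    return -0.75 * math.log1p(-(4.0 / 3.0) * p), False


def estimate_ks_ng86(codon_pairs: Sequence[tuple[str, str]],
                     gene_a: str = "a", gene_b: str = "b") -> KsEstimate:
    """NG86 Ks/Ka from a gap-free list of aligned codon pairs."""
    if not codon_pairs:
        raise ValueError("empty codon pair list")
    ia, ib = _codon_indices(codon_pairs)
    s_sites = float((SYN_SITES[ia] + SYN_SITES[ib]).sum() / 2.0)
    n_sites = 3.0 * len(codon_pairs) - s_sites
    sd = float(SYN_DIFFS[ia, ib].sum())
    nd = float(NONSYN_DIFFS[ia, ib].sum())
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks, sat_s = _jc_correct(ps)
    ka, _ = _jc_correct(pn)
    return KsEstimate(
        gene_a=gene_a,
        gene_b=gene_b,
        ks=ks,
        ka=ka,
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
        codons_used=len(codon_pairs),
        method="NG86",
        saturated=sat_s,
        unreliable=len(codon_pairs) < MIN_RELIABLE_CODONS,
    )


def _f3x4_freqs(ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies."""
    counts = np.zeros((3, 4))
    nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for idx_arr in (ia, ib):
        for i in idx_arr:
            for pos, nt in enumerate(SENSE_CODONS[i]):
                counts[pos, nt_index[nt]] += 1
    pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freqs[0, nt_index[c[0]]]
            * pos_freqs[1, nt_index[c[1]]]
            * pos_freqs[2, nt_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    total = pi.sum()
    if total <= 0:
        return np.full(N_CODONS, 1.0 / N_CODONS)
    return pi / total


def _transition_matrix(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """exp(Qt) for a reversible Q via the pi^(1/2) symmetrisation."""
    d = np.sqrt(np.clip(pi, 1e-300, None))
    sym = (q * d[:, None]) / d[None, :]
    sym = (sym + sym.T) / 2.0
    w, v = np.linalg.eigh(sym)
    p = (v * np.exp(w * t)) @ v.T
    p = p / d[:, None] * d[None, :]
    return np.clip(p, 1e-300, None)


def gy94_pair_loglik(codon_pairs: Sequence[tuple[str, str]], t: float,
                     kappa: float, omega: float,
                     pi: np.ndarray | None = None) -> float:
    """Log-likelihood of two sequences separated by branch length ``t``
    (expected substitutions per codon) under GY94 with frequencies ``pi``
    (F3x4 from the pair when omitted)."""
    ia, ib = _codon_indices(codon_pairs)
    if pi is None:
        pi = _f3x4_freqs(ia, ib)
    q = gy94_rate_matrix(kappa, omega, pi)
    scale = total_flux(q, pi)
    if scale <= 0:
        return -math.inf
    p = _transition_matrix(q / scale, pi, t)
    return float(np.sum(np.log(pi[ia] * p[ia, ib])))


def estimate_ks_ml(codon_pairs: Sequence[tuple[str, str]],
                   gene_a: str = "a", gene_b: str = "b",
                   kappa_init: float = 2.0,
                   omega_init: float = 0.5) -> KsEstimate:
    """Pairwise ML Ks under GY94 with F3x4 frequencies.

    Optimises (t, kappa, omega) on the two-sequence likelihood, then
    decomposes t into dS and dN using the fitted matrix's synonymous flux
    and the mutational-opportunity site proportions (the neutral, omega=1
    version of the fitted matrix).  Falls back to NG86 with a logged
    warning if the optimiser fails.
    """
    if len(codon_pairs) < 30:
        raise ValueError("ML estimation requires >= 30 codon pairs")
    ia, ib = _codon_indices(codon_pairs)
    pi = _f3x4_freqs(ia, ib)

    def neg_loglik(params: np.ndarray) -> float:
        t, kappa, omega = np.exp(params)
        return -gy94_pair_loglik(codon_pairs, t, kappa, omega, pi)

    x0 = np.log([max(0.05, np.mean(ia != ib)), kappa_init, omega_init])
    res = minimize(
        neg_loglik,
        x0,
        method="L-BFGS-B",
        bounds=[(math.log(1e-6), math.log(50.0)),
                (math.log(0.1), math.log(20.0)),
                (math.log(1e-3), math.log(10.0))],
    )
    if not res.success:
        logger.warning("ML Ks failed for (%s, %s): %s — falling back to NG86",
                       gene_a, gene_b, res.message)
        ng = estimate_ks_ng86(codon_pairs, gene_a, gene_b)
        return KsEstimate(**{**ng.__dict__, "method": "NG86-fallback"})
    t, kappa, omega = np.exp(res.x)
    q = gy94_rate_matrix(kappa, omega, pi)
    scale = total_flux(q, pi)
    q_norm = q / scale
    # Mutational opportunity: site proportions under the neutral matrix.
    q_neutral = gy94_rate_matrix(kappa, 1.0, pi)
    prop_s = synonymous_flux(q_neutral, pi) / total_flux(q_neutral, pi)
    s_sites = 3.0 * len(codon_pairs) * prop_s
    n_sites = 3.0 * len(codon_pairs) - s_sites
    syn_subs_per_codon = t * synonymous_flux(q_norm, pi)
    nonsyn_subs_per_codon = t * (total_flux(q_norm, pi) - synonymous_flux(q_norm, pi))
    ks = syn_subs_per_codon * len(codon_pairs) / s_sites
    ka = nonsyn_subs_per_codon * len(codon_pairs) / n_sites
    return KsEstimate(
        gene_a=gene_a,
        gene_b=gene_b,
        ks=ks,
        ka=ka,
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
        codons_used=len(codon_pairs),
        method="ML",
        saturated=False,
        unreliable=len(codon_pairs) < MIN_RELIABLE_CODONS,
        kappa=float(kappa),
    )


def codon_pairs_from_cds(nt_a: str, nt_b: str) -> list[tuple[str, str]]:
    """Split two equal-length in-frame CDS into aligned codon pairs."""
    if len(nt_a) != len(nt_b) or len(nt_a) % 3:
        raise ValueError("sequences must be equal-length and in frame")
    return [(nt_a[i:i + 3], nt_b[i:i + 3]) for i in range(0, len(nt_a), 3)]
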