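"""Synthetic transcriptomes with known duplication histories.

Families are grown on ultrametric gene genealogies (a molecular clock with
divergence split evenly across branches): an optional whole-genome
duplication at a chosen Ks, a Poisson background of small-scale
duplications at uniform ages, and optionally a two-species split younger
than the WGD.  Sequences evolve along the genealogy under a GY94-style
codon substitution process with uniform codon frequencies; branch lengths
are scaled so the expected number of synonymous substitutions per
(NG86-counted) synonymous site equals the branch's Ks.

The estimators downstream make none of the simulator's assumptions; the
truth table records every within-family pair with its true path Ks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._codons import SENSE_CODONS, SYN_SITES, gy94_rate_matrix, synonymous_flux
from .seqio import CodingSequence

TRUTH_COLUMNS = ("gene_a", "gene_b", "true_ks", "event_class", "family_id")

WGD, SSD, SPECIATION = "WGD", "SSD", "SPECIATION"


@dataclass
class SimulationConfig:
    """Scenario parameters for the synthetic transcriptome generator.

    ``wgd_ks`` is the synonymous divergence of the planted whole-genome
    duplication (default 0.8, the regime where an ancient WGD is still a
    distinct peak); ``wgd_retention`` the fraction of genes keeping their
    WGD duplicate; ``ssd_rate`` the expected number of small-scale
    duplicate copies per base gene, with ages uniform on ``ssd_ks_range``;
    ``speciation_ks``, when set, places a two-species split younger than
    the WGD.  ``omega`` and ``kappa`` are the GY94 selection and
    transition/transversion ratios used for sequence evolution.
    """

    n_base_genes: int = 300
    gene_len_codons: int = 300
    wgd_ks: float = 0.8
    wgd_retention: float = 0.6
    ssd_rate: float = 0.3
    ssd_ks_range: tuple[float, float] = (0.05, 3.0)
    speciation_ks: float | None = None
    omega: float = 0.2
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.wgd_retention <= 1:
            raise ValueError("wgd_retention must be in [0, 1]")
        if self.wgd_ks <= 0:
            raise ValueError("wgd_ks must be > 0")
        if self.speciation_ks is not None and not 0 < self.speciation_ks < self.wgd_ks:
            raise ValueError("speciation_ks must satisfy 0 < speciation_ks < wgd_ks")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.n_base_genes < 1 or self.gene_len_codons < 3:
            raise ValueError("n_base_genes >= 1 and gene_len_codons >= 3 required")
        lo, hi = self.ssd_ks_range
        if not 0 <= lo < hi:
            raise ValueError("ssd_ks_range must be an increasing non-negative interval")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        section = data.get("simulation", data)
        known = {f.name for f in fields(cls)}
        kwargs = {k: v for k, v in section.items() if k in known}
        if "ssd_ks_range" in kwargs:
            kwargs["ssd_ks_range"] = tuple(kwargs["ssd_ks_range"])
        return cls(**kwargs)


def random_cds(length_codons: int, rng: np.random.Generator) -> CodingSequence:
    """A CDS of codons drawn uniformly from the 61 sense codons."""
    if length_codons < 3:
        raise ValueError("length_codons must be >= 3")
    idx = rng.integers(0, len(SENSE_CODONS), size=length_codons)
    return _cds_from_indices("random", idx)


def _cds_from_indices(gene_id: str, idx: np.ndarray) -> CodingSequence:
    nt = "".join(SENSE_CODONS[i] for i in idx)
    return CodingSequence.from_nt(gene_id, nt)


@lru_cache(maxsize=8)
def _evolution_operator(kappa: float, omega: float):
    """Eigendecomposition of the (symmetric, uniform-frequency) GY94 matrix
    plus the time scale converting branch Ks into chronological time."""
    q = gy94_rate_matrix(kappa, omega)
    w, v = np.linalg.eigh(q)  # q is symmetric under uniform frequencies
    syn_rate = synonymous_flux(q)  # syn substitutions / codon / unit time
    syn_sites = float(SYN_SITES.mean())  # NG86 syn sites / codon at uniform
    return w, v, syn_sites / syn_rate


def _evolve_indices(idx: np.ndarray, branch_ks: float, omega: float,
                    kappa: float, rng: np.random.Generator) -> np.ndarray:
    if branch_ks == 0:
        return idx.copy()
    w, v, ks_to_time = _evolution_operator(kappa, omega)
    p = (v * np.exp(w * branch_ks * ks_to_time)) @ v.T
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=1, keepdims=True)
    cum = np.cumsum(p, axis=1)
    u = rng.random(idx.size)
    return (cum[idx] > u[:, None]).argmax(axis=1)


def evolve_to_ks(cds: CodingSequence, target_ks: float, omega: float = 0.2,
                 kappa: float = 2.0,
                 rng: np.random.Generator | None = None) -> CodingSequence:
    """Evolve a CDS so the expected synonymous divergence from its parent
    equals ``target_ks`` synonymous substitutions per synonymous site."""
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    idx = np.array([_CODON_TO_INDEX[cds.nt[i:i + 3]]
                    for i in range(0, len(cds.nt), 3)])
    return _cds_from_indices(cds.id, _evolve_indices(idx, target_ks, omega, kappa, rng))


_CODON_TO_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


# ---------------------------------------------------------------------------
# Ultrametric family genealogies
# ---------------------------------------------------------------------------

class _Node:
    """Internal genealogy node; leaves have height 0 and a gene id."""

    __slots__ = ("height", "event", "children", "gene_id", "species")

    def __init__(self, height: float, event: str | None = None,
                 gene_id: str | None = None, species: str | None = None):
        self.height = height
        self.event = event
        self.children: list[_Node] = []
        self.gene_id = gene_id
        self.species = species

    def leaves(self) -> list["_Node"]:
        if not self.children:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]


def _insert_event(root: _Node, height: float, event: str,
                  rng: np.random.Generator) -> _Node:
    """Duplicate one lineage alive at ``height``; returns the new root."""
    if height >= root.height:
        # Older than every existing node: new node on the root stem.
        node = _Node(height, event)
        node.children = [root, _Node(0.0, gene_id="?", species=root.species)]
        return node
    # Collect edges (parent, child) crossing the height.
    edges: list[tuple[_Node, int]] = []

    def walk(parent: _Node):
        for k, child in enumerate(parent.children):
            if child.height < height <= parent.height:
                edges.append((parent, k))
            if child.children:
                walk(child)

    walk(root)
    parent, k = edges[rng.integers(0, len(edges))]
    old = parent.children[k]
    node = _Node(height, event, species=old.species)
    node.children = [old, _Node(0.0, gene_id="?", species=old.species)]
    parent.children[k] = node
    return root


def _pairwise_truth(root: _Node, family_id: str) -> list[dict]:
    """Every leaf pair with its path Ks (= 2 x MRCA height) and the MRCA's
    event class."""
    rows: list[dict] = []

    def walk(node: _Node):
        for child in node.children:
            walk(child)
        if len(node.children) >= 2:
            for c1, c2 in itertools.combinations(node.children, 2):
                for la in c1.leaves():
                    for lb in c2.leaves():
                        a, b = sorted((la.gene_id, lb.gene_id))
                        rows.append({
                            "gene_a": a,
                            "gene_b": b,
                            "true_ks": 2.0 * node.height,
                            "event_class": node.event,
                            "family_id": family_id,
                        })

    walk(root)
    return rows


def _evolve_tree(root: _Node, base_idx: np.ndarray, omega: float, kappa: float,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Evolve codon-index arrays down the genealogy; branch Ks = height drop."""
    out: dict[str, np.ndarray] = {}

    def walk(node: _Node, idx: np.ndarray):
        if not node.children:
            out[node.gene_id] = idx
            return
        for child in node.children:
            walk(child, _evolve_indices(idx, node.height - child.height,
                                        omega, kappa, rng))

    walk(root, base_idx)
    return out


def _build_family(cfg: SimulationConfig, rng: np.random.Generator,
                  speciation: bool) -> _Node:
    """Genealogy for one base gene under the configured scenario."""
    pre_split: list[tuple[float, str]] = []
    post_split: list[tuple[float, str]] = []
    if rng.random() < cfg.wgd_retention:
        pre_split.append((cfg.wgd_ks / 2.0, WGD))
    lo, hi = cfg.ssd_ks_range
    if cfg.ssd_rate > 0 and hi > lo:
        # One SSD pool per species history; duplications older than the
        # split are shared between the species, younger ones are
        # species-specific.
        n_ssd = rng.poisson(cfg.ssd_rate * (2 if speciation else 1))
        for _ in range(n_ssd):
            height = rng.uniform(lo, hi) / 2.0
            if speciation and height < cfg.speciation_ks / 2.0:
                post_split.append((height, SSD))
            else:
                pre_split.append((height, SSD))
    root = _Node(0.0, gene_id="?")
    for height, event in sorted(pre_split, reverse=True):
        root = _insert_event(root, height, event, rng)
    if speciation:
        root = _speciate(root, cfg.speciation_ks / 2.0)
        for height, event in sorted(post_split, reverse=True):
            root = _insert_event(root, height, event, rng)
    return root


def _speciate(node: _Node, height: float) -> _Node:
    """Fork every lineage alive at ``height`` into an A and a B copy."""
    if node.height <= height:
        sp = _Node(height, SPECIATION)
        a, b = _clone(node), _clone(node)
        _tag(a, "A")
        _tag(b, "B")
        sp.children = [a, b]
        return sp
    node.children = [_speciate(c, height) for c in node.children]
    return node


def _clone(node: _Node) -> _Node:
    new = _Node(node.height, node.event, node.gene_id, node.species)
    new.children = [_clone(c) for c in node.children]
    return new


def _tag(node: _Node, species: str) -> None:
    node.species = species
    for c in node.children:
        _tag(c, species)


def _name_leaves(root: _Node, family_id: str) -> None:
    for i, leaf in enumerate(root.leaves()):
        prefix = f"{leaf.species}." if leaf.species else ""
        leaf.gene_id = f"{prefix}{family_id}.{i}"


def simulate_paranome(cfg: SimulationConfig
                      ) -> tuple[list[CodingSequence], pd.DataFrame]:
    """One species' transcriptome with a planted WGD and SSD background.

    Returns the gene set and a truth table of every within-family pair
    (gene_a, gene_b, true_ks, event_class, family_id).
    """
    rng = np.random.default_rng(cfg.seed)
    genes: list[CodingSequence] = []
    truth_rows: list[dict] = []
    for g in range(cfg.n_base_genes):
        family_id = f"fam{g:04d}"
        root = _build_family(cfg, rng, speciation=False)
        _name_leaves(root, family_id)
        base_idx = rng.integers(0, len(SENSE_CODONS), size=cfg.gene_len_codons)
        seqs = _evolve_tree(root, base_idx, cfg.omega, cfg.kappa, rng)
        for gid, idx in sorted(seqs.items()):
            genes.append(_cds_from_indices(gid, idx))
        truth_rows.extend(_pairwise_truth(root, family_id))
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return genes, truth.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def simulate_species_pair(cfg: SimulationConfig
                          ) -> tuple[list[CodingSequence], list[CodingSequence],
                                     pd.DataFrame]:
    """Two species sharing an ancestral WGD, split at ``speciation_ks``.

    WGD pairs (class WGD) appear within each species at ``wgd_ks``;
    one-to-one ortholog pairs (class SPECIATION) diverge at
    ``speciation_ks``; cross-species pairs tracing back to the WGD carry
    class WGD at ``wgd_ks``.  Small-scale duplications are added per
    species below the split.
    """
    if cfg.speciation_ks is None:
        raise ValueError("speciation_ks must be set for a two-species scenario")
    rng = np.random.default_rng(cfg.seed)
    species_a: list[CodingSequence] = []
    species_b: list[CodingSequence] = []
    truth_rows: list[dict] = []
    for g in range(cfg.n_base_genes):
        family_id = f"fam{g:04d}"
        root = _build_family(cfg, rng, speciation=True)
        _name_leaves(root, family_id)
        base_idx = rng.integers(0, len(SENSE_CODONS), size=cfg.gene_len_codons)
        seqs = _evolve_tree(root, base_idx, cfg.omega, cfg.kappa, rng)
        for leaf in sorted(root.leaves(), key=lambda lf: lf.gene_id):
            cds = _cds_from_indices(leaf.gene_id, seqs[leaf.gene_id])
            (species_a if leaf.species == "A" else species_b).append(cds)
        truth_rows.extend(_pairwise_truth(root, family_id))
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return species_a, species_b, truth.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
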