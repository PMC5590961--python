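"""The node-weighted Ks age distribution and its peaks.

A gene family of n members yields n(n-1)/2 pairwise Ks estimates but only
n-1 duplication events, so raw pairwise distributions over-count large
families.  The correction: split families into subfamilies whose pairwise
Ks stays below a saturation bound (default 5), build a rooted tree per
subfamily, and let each internal (duplication) node add its m cross-clade
Ks estimates to the distribution with weight 1/m each, so every event
contributes exactly unit mass.  The weighted multiset is smoothed with a
weighted Gaussian KDE and peaks are called against the background level.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .ks import KsEstimate, estimate_ks_ng86
from .seqio import CodingSequence, PipelineConfig

logger = logging.getLogger("paleoks")

ENTRY_COLUMNS = ("gene_a", "gene_b", "ks", "weight", "subfamily_id",
                 "node_id", "family_id")


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Subfamily:
    """A maximal single-linkage component of a family at Ks <= ks_max."""

    subfamily_id: str
    family_id: str
    member_ids: tuple[str, ...]
    estimates: dict[tuple[str, str], KsEstimate] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.member_ids)


def split_subfamilies(family_id: str, member_ids: Sequence[str],
                      estimates: Mapping[tuple[str, str], KsEstimate],
                      ks_max: float = 5.0) -> list[Subfamily]:
    """Single-linkage split: connected components of the member graph with
    edges wherever a pair's Ks is finite and <= ks_max.

    Chained pairs above the bound can still share a subfamily (single
    linkage); they are kept out of the density downstream but still count
    towards their node's m.
    """
    g = nx.Graph()
    g.add_nodes_from(member_ids)
    for (a, b), est in estimates.items():
        if a in g and b in g and math.isfinite(est.ks) and est.ks <= ks_max:
            g.add_edge(a, b)
    subfamilies = []
    for k, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        members = tuple(sorted(comp))
        sub_est = {
            _pair_key(a, b): estimates[_pair_key(a, b)]
            for i, a in enumerate(members)
            for b in members[i + 1:]
            if _pair_key(a, b) in estimates
        }
        subfamilies.append(Subfamily(
            subfamily_id=f"{family_id}.{k}",
            family_id=family_id,
            member_ids=members,
            estimates=sub_est,
        ))
    return subfamilies


def nj_tree(dist: np.ndarray, ids: Sequence[str]) -> TreeNode:
    """Neighbour-joining tree from a symmetric distance matrix.

    Additive matrices are recovered exactly (tree distances equal the
    input).  Negative branch lengths are clamped to zero with a warning;
    two taxa give the single-edge tree.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] != dist.shape[1] or dist.shape[0] != len(ids):
        raise ValueError("distance matrix and id list sizes disagree")
    if dist.shape[0] < 2:
        raise ValueError("need at least two taxa")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if len(ids) == 2:
        half = dist[0, 1] / 2.0
        left = TreeNode(name=ids[0], length=half)
        right = TreeNode(name=ids[1], length=half)
        root = TreeNode()
        root.extend([left, right])
        return root
    dm = DistanceMatrix(dist, ids=list(ids))
    tree = _skbio_nj(dm)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        logger.warning("nj_tree: clamped %d negative branch length(s) to 0",
                       clamped)
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Degenerate zero-diameter trees (all identical sequences) are rooted
    at an arbitrary but deterministic edge instead.
    """
    tree = tree.copy()
    try:
        rooted = tree.root_at_midpoint()
    except Exception:  # zero-length diameter or similar degeneracies
        tips = list(tree.tips())
        rooted = tree.root_at(tips[0].parent) if tips[0].parent is not None else tree
    return rooted


@dataclass(frozen=True)
class DuplicationNode:
    """One internal node of a rooted subfamily tree: a duplication event
    dated by its m cross-clade Ks estimates, each weighted 1/m."""

    node_id: str
    left: tuple[str, ...]
    right: tuple[str, ...]
    m: int
    consensus_ks: float


def weight_duplication_nodes(
    tree: TreeNode,
    estimates: Mapping[tuple[str, str], KsEstimate],
    subfamily_id: str = "SF0",
    family_id: str = "GF0",
) -> tuple[list[dict], list[DuplicationNode]]:
    """Entry rows for every duplication node of a rooted subfamily tree.

    Each internal node contributes its cross-clade pairs at weight 1/m
    (m = number of available estimates for that node), so the weights per
    event sum to one; a fully resolved subfamily of n members contributes
    total mass n - 1.  Missing cross-pair estimates reduce m with a log
    message.
    """
    entries: list[dict] = []
    nodes: list[DuplicationNode] = []
    counter = 0
    for node in tree.postorder():
        if node.is_tip() or len(node.children) < 2:
            continue
        node_id = f"{subfamily_id}.n{counter}"
        counter += 1
        clades = [tuple(sorted(t.name for t in child.tips(include_self=True)))
                  for child in node.children]
        cross_pairs: list[tuple[str, str]] = []
        for ci in range(len(clades)):
            for cj in range(ci + 1, len(clades)):
                for a in clades[ci]:
                    for b in clades[cj]:
                        cross_pairs.append(_pair_key(a, b))
        available = [p for p in cross_pairs if p in estimates]
        if len(available) < len(cross_pairs):
            logger.warning("node %s: %d of %d cross-clade estimates missing",
                           node_id, len(cross_pairs) - len(available),
                           len(cross_pairs))
        if not available:
            continue
        m = len(available)
        w = 1.0 / m
        ks_values = [estimates[p].ks for p in available]
        finite = [k for k in ks_values if math.isfinite(k)]
        nodes.append(DuplicationNode(
            node_id=node_id,
            left=clades[0],
            right=tuple(x for c in clades[1:] for x in c),
            m=m,
            consensus_ks=float(np.mean(finite)) if finite else math.nan,
        ))
        for (a, b), ksv in zip(available, ks_values):
            entries.append({
                "gene_a": a,
                "gene_b": b,
                "ks": ksv,
                "weight": w,
                "subfamily_id": subfamily_id,
                "node_id": node_id,
                "family_id": family_id,
            })
    return entries, nodes


@dataclass
class WeightedKsDistribution:
    """The corrected age distribution: a weighted multiset of Ks values."""

    entries: pd.DataFrame  # columns ENTRY_COLUMNS
    ks_max: float = 5.0
    min_ks: float = 0.05

    @property
    def total_weight(self) -> float:
        return float(self.entries["weight"].sum())

    def density_entries(self) -> pd.DataFrame:
        """Entries usable for density estimation: finite, inside
        [min_ks, ks_max] (saturated and near-identical pairs excluded)."""
        if self.entries.empty:
            return self.entries
        ks = self.entries["ks"].to_numpy(float)
        mask = np.isfinite(ks) & (ks >= self.min_ks) & (ks <= self.ks_max)
        return self.entries[mask]

    def write_tsv(self, path) -> None:
        from .seqio import write_tsv

        rows = self.entries.to_dict("records")
        write_tsv(rows, path, columns=list(ENTRY_COLUMNS))


def _distance_matrix_for_tree(subfamily: Subfamily, ks_max: float) -> np.ndarray:
    """Pairwise Ks matrix for NJ; saturated pairs get a finite cap."""
    members = subfamily.member_ids
    n = len(members)
    finite_vals = [e.ks for e in subfamily.estimates.values()
                   if math.isfinite(e.ks)]
    cap = max(2.0 * ks_max, 1.2 * max(finite_vals, default=ks_max))
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            est = subfamily.estimates.get(_pair_key(members[i], members[j]))
            val = cap if est is None or not math.isfinite(est.ks) else est.ks
            dist[i, j] = dist[j, i] = val
    return dist


def subfamily_distribution(subfamily: Subfamily, ks_max: float = 5.0
                           ) -> tuple[list[dict], list[DuplicationNode],
                                      TreeNode | None]:
    """Tree-correct one subfamily: NJ on its Ks matrix, midpoint rooting,
    1/m node weighting.  Subfamilies of one member contribute nothing."""
    if subfamily.n < 2:
        return [], [], None
    dist = _distance_matrix_for_tree(subfamily, ks_max)
    tree = nj_tree(dist, list(subfamily.member_ids))
    if subfamily.n > 2:  # the two-taxon tree is already rooted on its midpoint
        tree = midpoint_root(tree)
    entries, nodes = weight_duplication_nodes(
        tree, subfamily.estimates, subfamily.subfamily_id, subfamily.family_id)
    return entries, nodes, tree


def family_ks_estimates(members: Sequence[CodingSequence],
                        config: PipelineConfig
                        ) -> dict[tuple[str, str], KsEstimate]:
    """All pairwise NG86 estimates of a family from its codon alignment."""
    from .codon_align import align_family_codons, pairwise_codon_view

    alignment = align_family_codons(members, config.gap_open, config.gap_extend)
    estimates: dict[tuple[str, str], KsEstimate] = {}
    ids = sorted(alignment.member_ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            pairs = pairwise_codon_view(alignment, a, b)
            if not pairs:
                continue
            estimates[_pair_key(a, b)] = estimate_ks_ng86(pairs, a, b)
    return estimates


def build_paranome_distribution(
    transcriptome: Sequence[CodingSequence],
    config: PipelineConfig | None = None,
    return_details: bool = False,
):
    """End-to-end corrected Ks age distribution of one transcriptome.

    Orchestrates all-vs-all alignment, similarity graph, Markov
    clustering, per-family codon alignment and NG86 estimation, subfamily
    splitting at Ks <= ks_max, per-subfamily NJ trees with midpoint
    rooting, and 1/m duplication-node weighting.  Deterministic for a
    fixed input and configuration.
    """
    if not transcriptome:
        raise ValueError("empty transcriptome")
    config = config or PipelineConfig()
    from .mcl import mcl_cluster
    from .simgraph import all_vs_all, build_similarity_graph

    by_id = {c.id: c for c in transcriptome}
    if len(by_id) != len(transcriptome):
        raise ValueError("duplicate gene ids in transcriptome")
    hits = all_vs_all(transcriptome, config)
    graph = build_similarity_graph(hits, all_ids=by_id)
    families = mcl_cluster(graph, config.mcl_inflation)
    logger.info("clustered %d genes into %d families", len(by_id), len(families))
    all_entries: list[dict] = []
    all_nodes: list[DuplicationNode] = []
    trees: dict[str, TreeNode] = {}
    all_estimates: dict[tuple[str, str], KsEstimate] = {}
    for fam in families:
        if fam.n < 2:
            continue
        members = [by_id[g] for g in sorted(fam.member_ids)]
        estimates = family_ks_estimates(members, config)
        all_estimates.update(estimates)
        for sub in split_subfamilies(fam.family_id, sorted(fam.member_ids),
                                     estimates, config.ks_max):
            entries, nodes, tree = subfamily_distribution(sub, config.ks_max)
            all_entries.extend(entries)
            all_nodes.extend(nodes)
            if tree is not None:
                trees[sub.subfamily_id] = tree
    entries_df = pd.DataFrame(all_entries, columns=list(ENTRY_COLUMNS))
    dist = WeightedKsDistribution(entries=entries_df, ks_max=config.ks_max,
                                  min_ks=config.min_ks)
    if return_details:
        return dist, {"families": families, "nodes": all_nodes,
                      "trees": trees, "hits": hits, "graph": graph,
                      "estimates": all_estimates}
    return dist


# ---------------------------------------------------------------------------
# Density and peak calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityCurve:
    """Weighted KDE of a Ks distribution on a fixed grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    total_weight: float

    @property
    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


def _silverman_bandwidth(ks: np.ndarray, weights: np.ndarray) -> float:
    wsum = weights.sum()
    mean = float((ks * weights).sum() / wsum)
    var = float(((ks - mean) ** 2 * weights).sum() / wsum)
    sigma = math.sqrt(max(var, 1e-12))
    order = np.argsort(ks)
    cdf = np.cumsum(weights[order]) / wsum
    q25 = float(ks[order][np.searchsorted(cdf, 0.25)])
    q75 = float(ks[order][np.searchsorted(cdf, 0.75)])
    iqr = q75 - q25
    spread = min(sigma, iqr / 1.34) if iqr > 0 else sigma
    neff = float(wsum ** 2 / (weights ** 2).sum())
    return max(0.9 * spread * neff ** (-0.2), 1e-3)


def kde_density(distribution: WeightedKsDistribution,
                bandwidth: float | str = "auto",
                grid: np.ndarray | None = None) -> DensityCurve:
    """Weighted Gaussian KDE on [0, ks_max] with boundary reflection.

    Entries below ``min_ks`` (default 0.05) are excluded: near-zero pairs
    are dominated by thresholding artefacts, not duplication events.
    Reflection at both domain edges keeps the curve integrating to the
    total included weight.
    """
    if isinstance(bandwidth, (int, float)) and bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    used = distribution.density_entries()
    if used.empty:
        raise ValueError("no usable entries for density estimation")
    ks = used["ks"].to_numpy(float)
    weights = used["weight"].to_numpy(float)
    if grid is None:
        grid = np.linspace(0.0, distribution.ks_max, 1024)
    bw = _silverman_bandwidth(ks, weights) if bandwidth == "auto" else float(bandwidth)
    lo, hi = 0.0, float(distribution.ks_max)
    centres = np.concatenate([ks, 2 * lo - ks, 2 * hi - ks])
    w3 = np.concatenate([weights] * 3)
    z = (grid[:, None] - centres[None, :]) / bw
    density = (w3[None, :] * np.exp(-0.5 * z ** 2)).sum(axis=1) \
        / (bw * math.sqrt(2 * math.pi))
    return DensityCurve(grid=np.asarray(grid, float), density=density,
                        bandwidth=bw, total_weight=float(weights.sum()))


@dataclass(frozen=True)
class PeakCall:
    """One candidate duplication burst in the age distribution."""

    mode_ks: float
    weighted_median_ks: float
    mass: float
    interval: tuple[float, float]  # half-height bounds


def _weighted_median(ks: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ks)
    ks, weights = ks[order], weights[order]
    cdf = np.cumsum(weights)
    return float(ks[np.searchsorted(cdf, cdf[-1] / 2.0)])


def detect_peaks(density: DensityCurve,
                 distribution: WeightedKsDistribution,
                 prominence_factor: float = 1.5) -> list[PeakCall]:
    """Local density maxima exceeding ``prominence_factor`` times the
    median density level, with half-height intervals and the weighted
    median / summed weight of the entries inside each interval.

    Maxima whose half-height intervals overlap describe the same burst;
    only the highest of an overlapping group is reported.
    """
    from scipy.signal import find_peaks

    y = density.density
    threshold = prominence_factor * float(np.median(y))
    idx, _ = find_peaks(y, height=threshold)
    idx = sorted(idx, key=lambda i: -y[i])  # highest first
    used = distribution.density_entries()
    ks = used["ks"].to_numpy(float)
    weights = used["weight"].to_numpy(float)
    calls: list[PeakCall] = []
    for i in idx:
        half = y[i] / 2.0
        left = i
        while left > 0 and y[left] > half:
            left -= 1
        right = i
        while right < len(y) - 1 and y[right] > half:
            right += 1
        lo, hi = float(density.grid[left]), float(density.grid[right])
        if any(lo < c.interval[1] and c.interval[0] < hi for c in calls):
            continue  # same burst as an already-reported higher peak
        inside = (ks >= lo) & (ks <= hi)
        if not inside.any():
            continue
        calls.append(PeakCall(
            mode_ks=float(density.grid[i]),
            weighted_median_ks=_weighted_median(ks[inside], weights[inside]),
            mass=float(weights[inside].sum()),
            interval=(lo, hi),
        ))
    calls.sort(key=lambda c: c.mode_ks)
    return calls


def write_trees_newick(trees: Mapping[str, TreeNode], path) -> None:
    """All subfamily trees in one Newick file, one per line, labelled by a
    leading comment-free id line convention: id<TAB>newick."""
    lines = []
    for sid in sorted(trees):
        buf = io.StringIO()
        trees[sid].write(buf)
        lines.append(f"{sid}\t{buf.getvalue().strip()}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
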