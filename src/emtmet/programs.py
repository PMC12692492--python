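"""Robust meta-program discovery from per-sample NMF factorizations.

The chain: factorize each sample's highly-variable-gene submatrix at a
range of ranks with repeated random restarts; pick the rank whose repeat
clusterings are most stable (cophenetic correlation of the consensus
matrix); extract each factor's top-weight genes as a module; keep modules
that recur across samples (Jaccard similarity > 0.05 to at least five
others); build a gene co-occurrence network weighted by how many modules
contain both endpoints; partition it with the Infomap map-equation
algorithm; and merge similar programs across cancers by single linkage.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import anndata as ad
import igraph
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.decomposition import NMF

__all__ = [
    "GeneModule",
    "MetaProgram",
    "jaccard",
    "run_sample_nmf",
    "filter_robust_modules",
    "build_cooccurrence_graph",
    "detect_programs",
    "merge_programs",
    "screen_modules_by_program",
    "discover_meta_programs",
]


@dataclass
class GeneModule:
    """One NMF factor's top-weight genes, with provenance."""

    sample: str
    rank: int
    factor: int
    genes: list[str]            # sorted by descending weight
    weights: np.ndarray

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass
class MetaProgram:
    """Consensus gene module recurring across samples/cancers."""

    program_id: str
    genes: set[str]
    member_modules: list[str] = field(default_factory=list)
    cancers: set[str] = field(default_factory=set)
    label: str = ""


def jaccard(a: set[str] | frozenset[str], b: set[str] | frozenset[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def select_hvgs(adata: ad.AnnData, n_hvg: int = 2000) -> list[str]:
    """Top ``n_hvg`` genes by log-layer variance."""
    X = np.asarray(adata.X, dtype=float)
    var = X.var(axis=0)
    order = np.argsort(-var, kind="stable")[: min(n_hvg, X.shape[1])]
    return [adata.var_names[i] for i in order]


def _consensus_cophenetic(assignments: list[np.ndarray]) -> float:
    """Cophenetic correlation of the consensus matrix over repeat clusterings."""
    n = len(assignments[0])
    consensus = np.zeros((n, n))
    for lab in assignments:
        consensus += (lab[:, None] == lab[None, :]).astype(float)
    consensus /= len(assignments)
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0]):
        # perfectly (un)stable consensus has zero distance variance;
        # fully stable repeats count as cophenetic correlation 1
        return 1.0 if np.all((consensus == 0) | (consensus == 1)) else 0.0
    Z = linkage(condensed, method="average")
    c, _ = cophenet(Z, condensed)
    return float(c) if np.isfinite(c) else 0.0


def run_sample_nmf(adata: ad.AnnData, sample: str | None = None,
                   ranks: range | list[int] = range(4, 13),
                   repeats: int = 10, seed: int = 0, top_n: int = 50,
                   n_hvg: int = 2000, max_consensus_cells: int = 300,
                   max_iter: int = 300) -> list[GeneModule]:
    """Factorize one sample and return its stable-rank gene modules.

    The non-negative log layer restricted to highly variable genes is
    decomposed ``repeats`` times per rank with random restarts; the rank
    with the highest cophenetic correlation of the cell-cluster consensus
    matrix wins (ties to the smaller rank). Each factor of the winning
    rank contributes one module: its ``top_n`` genes by weight.
    """
    if sample is not None:
        adata = adata[adata.obs["sample"] == sample]
    name = sample if sample is not None else "all"
    if adata.n_obs <= 5:
        raise ValueError(f"sample {name!r} has <= 5 cells")
    X = np.asarray(adata.X, dtype=float)
    if (X < 0).any():
        raise ValueError("NMF input contains negative entries")
    hvgs = select_hvgs(adata, n_hvg=n_hvg)
    if len(hvgs) < 2:
        raise ValueError("fewer than 2 highly variable genes")
    gidx = [list(adata.var_names).index(g) for g in hvgs]
    X = X[:, gidx]

    rng = np.random.default_rng(seed)
    sub = np.arange(X.shape[0])
    if len(sub) > max_consensus_cells:
        sub = rng.choice(len(sub), size=max_consensus_cells, replace=False)

    ranks = [r for r in ranks if r < min(X.shape)]
    if not ranks:
        raise ValueError("no admissible rank for this matrix size")
    norm_X = np.linalg.norm(X)
    cophs, errors, first_H = {}, {}, {}
    import warnings as _warnings
    for r in ranks:
        assignments, errs = [], []
        for rep in range(repeats):
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                model = NMF(n_components=r, init="random", max_iter=max_iter,
                            random_state=int(rng.integers(0, 2**31 - 1)),
                            tol=1e-5)
                W = model.fit_transform(X)
            assignments.append(np.argmax(W[sub], axis=1))
            errs.append(model.reconstruction_err_ / max(norm_X, 1e-12))
            if rep == 0:
                first_H[r] = model.components_
        cophs[r] = _consensus_cophenetic(assignments)
        errors[r] = float(np.mean(errs))
    # composite rank choice: repeat-consensus stability plus reconstruction
    # quality, with a small per-rank penalty so extra factors must buy a
    # real error reduction; ties go to the smaller rank
    def composite(r: int) -> float:
        return cophs[r] - errors[r] - 0.01 * r

    best_rank = max(ranks, key=lambda r: (composite(r), -r))
    best_H = first_H[best_rank]
    modules = []
    for f in range(best_rank):
        weights = best_H[f]
        order = np.argsort(-weights, kind="stable")[: min(top_n, len(weights))]
        modules.append(GeneModule(
            sample=name, rank=best_rank, factor=f,
            genes=[hvgs[i] for i in order], weights=weights[order].copy()))
    return modules


def filter_robust_modules(modules: list[GeneModule], jaccard_min: float = 0.05,
                          min_partners: int = 5) -> list[GeneModule]:
    """Keep modules with Jaccard > ``jaccard_min`` to >= ``min_partners`` others."""
    if len(modules) < min_partners + 1:
        raise ValueError(
            f"need at least {min_partners + 1} modules, got {len(modules)}")
    sets = [m.gene_set for m in modules]
    kept = []
    for i, mi in enumerate(modules):
        partners = sum(
            1 for j in range(len(modules))
            if j != i and jaccard(sets[i], sets[j]) > jaccard_min)
        if partners >= min_partners:
            kept.append(mi)
    return kept


def build_cooccurrence_graph(modules: list[GeneModule],
                             min_degree: int = 2,
                             min_recurrence: int = 2) -> nx.Graph:
    """Gene co-occurrence network: edge weight = #modules containing both genes.

    Genes appearing in fewer than ``min_recurrence`` modules are dropped
    first (stable-gene pre-filter); then nodes with weighted degree below
    ``min_degree`` are removed.
    """
    if len(modules) < 2:
        raise ValueError("need at least 2 modules")
    counts: dict[str, int] = {}
    for m in modules:
        for g in m.gene_set:
            counts[g] = counts.get(g, 0) + 1
    stable = {g for g, c in counts.items() if c >= min_recurrence}
    graph = nx.Graph()
    for m in modules:
        genes = sorted(m.gene_set & stable)
        for i, g in enumerate(genes):
            for h in genes[i + 1:]:
                if graph.has_edge(g, h):
                    graph[g][h]["weight"] += 1
                else:
                    graph.add_edge(g, h, weight=1)
    low = [n for n in graph.nodes
           if graph.degree(n, weight="weight") < min_degree]
    graph.remove_nodes_from(low)
    return graph


def detect_programs(graph: nx.Graph, seed: int = 0,
                    prefix: str = "MP") -> list[MetaProgram]:
    """Partition the co-occurrence network with the Infomap map-equation.

    Delegates to igraph's Infomap community detection with a seeded RNG;
    singleton communities are dropped from the program output.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty co-occurrence graph")
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    weights = [graph[u][v].get("weight", 1) for u, v in graph.edges]
    g = igraph.Graph(n=len(nodes), edges=edges)
    igraph.set_random_number_generator(random.Random(seed))
    membership = g.community_infomap(edge_weights=weights).membership
    groups: dict[int, set[str]] = {}
    for n, com in zip(nodes, membership):
        groups.setdefault(com, set()).add(n)
    programs = []
    for k, com in enumerate(sorted(groups, key=lambda c: (-len(groups[c]), c))):
        if len(groups[com]) < 2:
            continue
        programs.append(MetaProgram(program_id=f"{prefix}{k:02d}",
                                    genes=set(groups[com])))
    return programs


def merge_programs(programs: list[MetaProgram],
                   jaccard_merge: float = 0.25) -> list[MetaProgram]:
    """Single-linkage merge of programs with pairwise Jaccard > threshold."""
    if not programs:
        raise ValueError("no programs to merge")
    parent = list(range(len(programs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(programs)):
        for j in range(i + 1, len(programs)):
            if jaccard(programs[i].genes, programs[j].genes) > jaccard_merge:
                parent[find(i)] = find(j)
    groups: dict[int, list[MetaProgram]] = {}
    for i, p in enumerate(programs):
        groups.setdefault(find(i), []).append(p)
    merged = []
    for k, members in enumerate(groups.values()):
        genes: set[str] = set()
        provenance: list[str] = []
        cancers: set[str] = set()
        for p in members:
            genes |= p.genes
            provenance += p.member_modules or [p.program_id]
            cancers |= p.cancers
        merged.append(MetaProgram(program_id=f"MERGED{k:02d}", genes=genes,
                                  member_modules=provenance, cancers=cancers))
    return merged


def screen_modules_by_program(module_scores: pd.DataFrame,
                              program_scores: pd.DataFrame,
                              r_min: float = 0.2, p_max: float = 0.05) -> list[str]:
    """Keep co-expression modules correlated with any program activity.

    ``module_scores`` and ``program_scores`` are cells x modules/programs
    frames of per-cell activities (the module score is a simplified
    eigengene: mean scaled expression of the module's genes). A module is
    selected when |Pearson r| > ``r_min`` and two-sided p < ``p_max``
    against at least one program.
    """
    if len(module_scores) < 3:
        raise ValueError("need at least 3 cells")
    if not module_scores.index.equals(program_scores.index):
        program_scores = program_scores.reindex(module_scores.index)
    selected = []
    for mod in module_scores.columns:
        for prog in program_scores.columns:
            r, p = pearsonr(module_scores[mod], program_scores[prog])
            if abs(r) > r_min and p < p_max:
                selected.append(mod)
                break
    return selected


def discover_meta_programs(adata: ad.AnnData, sample_key: str = "sample",
                           ranks: range | list[int] = range(4, 13),
                           repeats: int = 10, seed: int = 0, top_n: int = 50,
                           jaccard_min: float = 0.05, min_partners: int = 5,
                           min_degree: int = 2, min_recurrence: int = 2,
                           jaccard_merge: float = 0.25,
                           **nmf_kwargs) -> tuple[list[MetaProgram], list[GeneModule]]:
    """End-to-end chain: per-sample NMF -> robust filter -> graph -> Infomap."""
    modules: list[GeneModule] = []
    for k, sample in enumerate(pd.unique(adata.obs[sample_key])):
        if (adata.obs[sample_key] == sample).sum() <= 5:
            continue
        modules += run_sample_nmf(adata, sample=sample, ranks=ranks,
                                  repeats=repeats, seed=seed + k,
                                  top_n=top_n, **nmf_kwargs)
    robust = filter_robust_modules(modules, jaccard_min=jaccard_min,
                                   min_partners=min_partners)
    graph = build_cooccurrence_graph(robust, min_degree=min_degree,
                                     min_recurrence=min_recurrence)
    programs = detect_programs(graph, seed=seed)
    merged = merge_programs(programs, jaccard_merge=jaccard_merge)
    return merged, robust
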