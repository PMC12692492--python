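"""Network- and perturbation-based anti-metastatic drug prioritization.

Two independent evidence channels are combined per candidate drug:

* **Score_RWR** -- stationary probability mass on the drug node from a
  random walk with restart ``P_{t+1} = alpha * A * P_t + (1-alpha) * P_0``
  on the drug-target + PPI network, seeded at the metastasis-signature
  genes (``P_0`` = normalized binary seed indicator, ``alpha = 0.7``).
* **Score_GSEA** -- pre-ranked GSEA of the drug-vs-control perturbation
  contrast against the up-signature: a drug that pushes up-signature
  genes down gets a negative NES, so ``Score_GSEA = minmax(-NES)``.

Both channel scores are min-max normalized over the candidate set (the
drugs scored by both channels) and combined as
``DrugScore = 0.6 * Score_RWR + 0.4 * Score_GSEA``. A drug's effect is
labeled ``inhibits`` when its NES against the up-signature is negative,
``promotes`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ScoreModel, compute_score

__all__ = [
    "DrugNetwork",
    "build_network",
    "rwr",
    "rank_perturbation",
    "gsea_preranked",
    "score_gsea",
    "drug_score",
    "prioritize_drugs",
    "perturbation_mps_test",
]

ALPHA_DEFAULT = 0.7
L1_DEFAULT, L2_DEFAULT = 0.6, 0.4


@dataclass
class DrugNetwork:
    """Heterogeneous drug/gene graph with a column-stochastic transition matrix."""

    nodes: list[str]
    node_type: pd.Series          # 'drug' | 'gene' per node
    A: np.ndarray                 # column-normalized adjacency
    seeds: list[str]

    @property
    def drug_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.node_type[n] == "drug"]


def build_network(drug_target_edges: pd.DataFrame, ppi_edges: pd.DataFrame,
                  seeds: list[str]) -> DrugNetwork:
    """Assemble the drug-target network and its transition operator.

    Drug-target and gene-gene edges form one simple undirected graph;
    duplicate edges collapse; isolated nodes are removed. ``A`` is the
    adjacency matrix with each column normalized to sum 1. Seed genes
    absent from the network are dropped with a warning; an empty seed
    intersection is an error.
    """
    if drug_target_edges.empty and ppi_edges.empty:
        raise ValueError("no edges provided")
    edges: set[tuple[str, str]] = set()
    drugs: set[str] = set()
    genes: set[str] = set()
    for d, g in drug_target_edges.itertuples(index=False):
        d, g = str(d), str(g)
        drugs.add(d)
        genes.add(g)
        edges.add((min(d, g), max(d, g)))
    for a, b in ppi_edges.iloc[:, :2].itertuples(index=False):
        a, b = str(a), str(b)
        if a == b:
            continue
        genes.update((a, b))
        edges.add((min(a, b), max(a, b)))

    nodes = sorted(drugs) + sorted(genes - drugs)
    index = {n: i for i, n in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)))
    for u, v in edges:
        adj[index[u], index[v]] = 1.0
        adj[index[v], index[u]] = 1.0
    connected = adj.sum(axis=0) > 0
    nodes = [n for n, c in zip(nodes, connected) if c]
    adj = adj[np.ix_(connected, connected)]

    col_sums = adj.sum(axis=0)
    A = adj / col_sums[None, :]

    present = set(nodes)
    kept_seeds = [s for s in seeds if s in present]
    if not kept_seeds:
        raise ValueError("no seed gene is present in the network")
    if len(kept_seeds) < len(seeds):
        import warnings
        warnings.warn(f"dropped {len(seeds) - len(kept_seeds)} seed(s) "
                      "absent from the network", stacklevel=2)
    node_type = pd.Series(
        ["drug" if n in drugs else "gene" for n in nodes], index=nodes)
    return DrugNetwork(nodes=nodes, node_type=node_type, A=A,
                       seeds=kept_seeds)


def rwr(network: DrugNetwork, alpha: float = ALPHA_DEFAULT,
        tol: float = 1e-10, max_iter: int = 10000) -> pd.Series:
    """Random walk with restart to stationarity; returns P* per node.

    Iterates ``P_{t+1} = alpha*A*P_t + (1-alpha)*P_0`` with ``P_0`` the
    seed indicator normalized to sum 1, until the L1 residual drops
    below ``tol``. The stationary vector sums to 1.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    index = {n: i for i, n in enumerate(network.nodes)}
    p0 = np.zeros(len(network.nodes))
    for s in network.seeds:
        p0[index[s]] = 1.0
    p0 /= p0.sum()
    p = p0.copy()
    for _ in range(max_iter):
        p_next = alpha * (network.A @ p) + (1.0 - alpha) * p0
        residual = np.abs(p_next - p).sum()
        p = p_next
        if residual < tol:
            return pd.Series(p, index=network.nodes, name="rwr")
    raise RuntimeError(f"RWR did not converge; residual {residual:.3e}")


def rank_perturbation(drug_profiles: pd.DataFrame,
                      ctrl_profiles: pd.DataFrame) -> pd.Series:
    """Signed per-gene drug-vs-control statistic, ranked descending.

    Welch t statistic by default; with a single replicate per arm the
    ranking falls back to the log2 fold change. Ties break by gene id.
    """
    if drug_profiles.shape[1] == 0 or ctrl_profiles.shape[1] == 0:
        raise ValueError("each arm needs at least one profile")
    shared = drug_profiles.index.intersection(ctrl_profiles.index)
    a = drug_profiles.loc[shared].to_numpy(dtype=float)
    b = ctrl_profiles.loc[shared].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        stat = a.mean(axis=1) - b.mean(axis=1)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = stats.ttest_ind(a, b, axis=1, equal_var=False).statistic
        stat = np.nan_to_num(stat, nan=0.0)
    s = pd.Series(stat, index=shared, name="stat")
    return s.sort_values(ascending=False, kind="stable")


def _es(stat: np.ndarray, hits: np.ndarray, weight_exp: float = 1.0) -> float:
    """Weighted KS enrichment score for a ranked statistic and hit mask."""
    weights = np.abs(stat) ** weight_exp
    hit_w = np.where(hits, weights, 0.0)
    total_hit = hit_w.sum()
    if total_hit == 0:
        return 0.0
    n_miss = (~hits).sum()
    steps = hit_w / total_hit - np.where(hits, 0.0, 1.0 / max(n_miss, 1))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(ranking: pd.Series, gene_set: list[str],
                   n_perm: int = 1000, seed: int = 0,
                   weight_exp: float = 1.0) -> tuple[float, float, float]:
    """Pre-ranked GSEA with gene-label permutation; returns (ES, NES, p).

    The running sum increments at set genes proportionally to
    ``|stat|^weight_exp`` and decrements uniformly elsewhere; ES is the
    maximum deviation from zero. The null re-draws the hit positions
    uniformly; NES = ES / mean(|null ES| of the same sign) and p is the
    two-sided permutation tail ``(#{|null ES| >= |ES|} + 1) / (n_perm + 1)``,
    so its floor is ``1/(n_perm+1)`` and it is uniform under the null.
    Deterministic given seed.
    """
    stat = ranking.to_numpy(dtype=float)
    in_set = ranking.index.isin(set(gene_set))
    n_hit = int(in_set.sum())
    if n_hit < 3:
        raise ValueError("gene set overlaps the ranking in < 3 genes")
    es = _es(stat, in_set, weight_exp)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n = len(stat)
    for b in range(n_perm):
        perm_hits = np.zeros(n, dtype=bool)
        perm_hits[rng.choice(n, size=n_hit, replace=False)] = True
        null[b] = _es(stat, perm_hits, weight_exp)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    nes = 0.0 if len(same_sign) == 0 else es / np.mean(np.abs(same_sign))
    p = float((np.sum(np.abs(null) >= abs(es)) + 1) / (n_perm + 1))
    return es, float(nes), p


def score_gsea(nes: pd.Series) -> pd.Series:
    """Min-max of -NES across drugs: strongest down-regulator of the
    up-signature scores 1."""
    if len(nes) < 2:
        raise ValueError("need at least 2 drugs")
    neg = -nes.to_numpy(dtype=float)
    lo, hi = neg.min(), neg.max()
    scaled = np.zeros_like(neg) if hi == lo else (neg - lo) / (hi - lo)
    return pd.Series(scaled, index=nes.index, name="score_gsea")


def drug_score(score_rwr: pd.Series, score_gsea_: pd.Series,
               l1: float = L1_DEFAULT, l2: float = L2_DEFAULT) -> pd.Series:
    """Weighted combination over the candidate intersection of both channels."""
    if abs(l1 + l2 - 1.0) > 1e-9:
        import warnings
        warnings.warn("drug score weights do not sum to 1", stacklevel=2)
    common = score_rwr.index.intersection(score_gsea_.index)
    combined = l1 * score_rwr.loc[common] + l2 * score_gsea_.loc[common]
    combined.name = "drug_score"
    return combined.sort_values(ascending=False, kind="stable")


def prioritize_drugs(network: DrugNetwork,
                     profiles: dict[str, dict[str, pd.DataFrame]],
                     up_signature: list[str],
                     alpha: float = ALPHA_DEFAULT,
                     l1: float = L1_DEFAULT, l2: float = L2_DEFAULT,
                     n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Full prioritization: RWR + per-drug pre-ranked GSEA -> Drug Score.

    Returns a frame indexed by drug with columns ``score_rwr``, ``es``,
    ``nes``, ``p_gsea``, ``score_gsea``, ``drug_score``, ``effect``,
    sorted by descending Drug Score.
    """
    stationary = rwr(network, alpha=alpha)
    raw_rwr = stationary.reindex(network.drug_nodes).dropna()
    lo, hi = raw_rwr.min(), raw_rwr.max()
    norm_rwr = (raw_rwr - lo) / (hi - lo) if hi > lo else raw_rwr * 0.0

    rows = {}
    for k, (drug, arms) in enumerate(sorted(profiles.items())):
        ranking = rank_perturbation(arms["treated"], arms["control"])
        es, nes, p = gsea_preranked(ranking, up_signature, n_perm=n_perm,
                                    seed=seed + k)
        rows[drug] = {"es": es, "nes": nes, "p_gsea": p}
    gsea_df = pd.DataFrame(rows).T
    sg = score_gsea(gsea_df["nes"])

    combined = drug_score(norm_rwr, sg, l1=l1, l2=l2)
    out = pd.DataFrame({
        "score_rwr": norm_rwr.reindex(combined.index),
        "es": gsea_df["es"].reindex(combined.index),
        "nes": gsea_df["nes"].reindex(combined.index),
        "p_gsea": gsea_df["p_gsea"].reindex(combined.index),
        "score_gsea": sg.reindex(combined.index),
        "drug_score": combined,
    })
    out["effect"] = np.where(out["nes"] < 0, "inhibits", "promotes")
    return out


def perturbation_mps_test(model: ScoreModel, drug_profiles: pd.DataFrame,
                          ctrl_profiles: pd.DataFrame) -> tuple[float, float]:
    """MPS shift between treated and control profiles.

    Returns ``(delta, p)``: the difference of median MPS (treated minus
    control) and the two-sided Wilcoxon rank-sum p-value. Profiles are
    genes x samples.
    """
    overlap = [g for g in model.genes if g in drug_profiles.index]
    if not overlap:
        raise ValueError("model genes do not overlap profile genes")
    mps_drug = compute_score(model, drug_profiles.T)
    mps_ctrl = compute_score(model, ctrl_profiles.T)
    delta = float(np.median(mps_drug) - np.median(mps_ctrl))
    if np.ptp(np.concatenate([mps_drug, mps_ctrl])) == 0:
        return delta, 1.0
    p = float(stats.mannwhitneyu(mps_drug, mps_ctrl,
                                 alternative="two-sided").pvalue)
    return delta, p
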