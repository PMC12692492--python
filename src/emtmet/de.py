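"""Metastasis signature derivation: mapping-based contrastive differential
expression between hEMT and lEMT cells, pseudotime trend screening, and
direction-annotated signature intersection.

The mapping step pairs cells across the two EMT strata by mutual nearest
neighbors in a joint PCA embedding and removes highly similar pairs, so
the subsequent Wilcoxon rank-sum test contrasts the cells that actually
differ between the strata rather than the shared background. Trend genes
are screened with the Mann-Kendall test on spline-smoothed expression
along pseudotime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "SignatureSet",
    "anchor_map",
    "drop_similar",
    "wilcoxon_de",
    "natural_spline_basis",
    "smooth_curve",
    "mann_kendall",
    "trend_genes",
    "intersect_signatures",
    "cross_cancer_shared",
]


@dataclass
class SignatureSet:
    """Direction-annotated metastasis signature for one cancer."""

    cancer: str
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def direction_map(self) -> dict[str, str]:
        return {**{g: "up" for g in self.up}, **{g: "down" for g in self.down}}


# ---------------------------------------------------------------------------
# anchor mapping


def _log(adata: ad.AnnData) -> np.ndarray:
    return np.asarray(adata.X, dtype=float)


def anchor_map(a: ad.AnnData, b: ad.AnnData, n_pcs: int = 30,
               k: int = 5) -> pd.DataFrame:
    """Bidirectional correspondence between two cell groups.

    Cells are embedded with a joint PCA on the concatenated log layers
    (first ``n_pcs`` components); pairs are mutual k-nearest neighbors
    across the groups and ``similarity`` is the Pearson correlation of
    the paired cells' PC coordinates. Returns a frame with columns
    ``cell_a``, ``cell_b``, ``similarity``.
    """
    shared = [g for g in a.var_names if g in set(b.var_names)]
    if not shared:
        raise ValueError("groups share no genes")
    if a.n_obs < k or b.n_obs < k:
        raise ValueError(f"each group needs at least k={k} cells")
    Xa = _log(a[:, shared])
    Xb = _log(b[:, shared])
    X = np.vstack([Xa, Xb])
    n_pcs = min(n_pcs, min(X.shape) - 1)
    Z = PCA(n_components=n_pcs, random_state=0).fit_transform(
        X - X.mean(axis=0))
    Za, Zb = Z[: len(Xa)], Z[len(Xa):]

    nn_b = NearestNeighbors(n_neighbors=k).fit(Zb)
    nn_a = NearestNeighbors(n_neighbors=k).fit(Za)
    a_to_b = nn_b.kneighbors(Za, return_distance=False)
    b_to_a = nn_a.kneighbors(Zb, return_distance=False)
    b_sets = [set(row) for row in b_to_a]
    pairs = []
    for i in range(len(Za)):
        for j in a_to_b[i]:
            if i in b_sets[j]:
                zi, zj = Za[i], Zb[j]
                denom = zi.std() * zj.std()
                sim = float(np.corrcoef(zi, zj)[0, 1]) if denom > 0 else 0.0
                pairs.append((a.obs_names[i], b.obs_names[j], sim))
    return pd.DataFrame(pairs, columns=["cell_a", "cell_b", "similarity"])


def drop_similar(a: ad.AnnData, b: ad.AnnData, pairs: pd.DataFrame,
                 sim_thr: float = 0.9) -> tuple[list[str], list[str]]:
    """Remove both members of any anchor pair more similar than ``sim_thr``."""
    hot = pairs[pairs["similarity"] > sim_thr]
    drop_a = set(hot["cell_a"])
    drop_b = set(hot["cell_b"])
    keep_a = [c for c in a.obs_names if c not in drop_a]
    keep_b = [c for c in b.obs_names if c not in drop_b]
    return keep_a, keep_b


# ---------------------------------------------------------------------------
# differential expression


def wilcoxon_de(a: ad.AnnData, b: ad.AnnData, p_max: float = 0.05,
                lfc_min: float = 0.25) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum differential expression on the log layer.

    ``avg_log2FC = log2((mean expm1(a) + 1) / (mean expm1(b) + 1))`` with
    the +1 pseudocount so the fold change is finite for all-zero groups.
    Returns the genes passing ``p < p_max`` and ``|avg_log2FC| > lfc_min``
    with BH-adjusted p-values reported alongside.
    """
    if a.n_obs < 3 or b.n_obs < 3:
        raise ValueError("each group needs at least 3 cells")
    shared = [g for g in a.var_names if g in set(b.var_names)]
    Xa, Xb = _log(a[:, shared]), _log(b[:, shared])
    mean_a = np.expm1(Xa).mean(axis=0)
    mean_b = np.expm1(Xb).mean(axis=0)
    lfc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    pvals = np.ones(len(shared))
    for i in range(len(shared)):
        if np.ptp(np.concatenate([Xa[:, i], Xb[:, i]])) == 0:
            pvals[i] = 1.0
        else:
            pvals[i] = stats.mannwhitneyu(
                Xa[:, i], Xb[:, i], alternative="two-sided").pvalue
    padj = stats.false_discovery_control(pvals, method="bh")
    out = pd.DataFrame({
        "gene": shared, "avg_log2FC": lfc, "p": pvals, "p_adj": padj,
        "direction": np.where(lfc > 0, "up", "down"),
    }).set_index("gene")
    return out[(out["p"] < p_max) & (out["avg_log2FC"].abs() > lfc_min)]


# ---------------------------------------------------------------------------
# pseudotime trends


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (truncated power form, linear in the tails)."""
    x = np.asarray(x, dtype=float)
    K = len(knots)

    def d(k: int) -> np.ndarray:
        num = (np.clip(x - knots[k], 0, None) ** 3
               - np.clip(x - knots[-1], 0, None) ** 3)
        return num / (knots[-1] - knots[k])

    cols = [np.ones_like(x), x]
    dK1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK1)
    return np.column_stack(cols)


def smooth_curve(expr: np.ndarray, pseudotime: np.ndarray,
                 n_points: int = 100, df: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline regression of expression on pseudotime.

    Returns ``(grid, fitted)`` where ``grid`` is an even pseudotime grid
    of ``n_points`` values spanning the observed range. The basis
    dimension ``df`` is deliberately generous: an over-smooth fit turns
    pure noise into near-monotone curves, which would defeat the
    stringency of a downstream |tau| threshold.
    """
    pt = np.asarray(pseudotime, dtype=float)
    expr = np.asarray(expr, dtype=float)
    ok = np.isfinite(pt) & np.isfinite(expr)
    pt, expr = pt[ok], expr[ok]
    if len(pt) < 10:
        raise ValueError("need at least 10 cells with finite pseudotime")
    if np.ptp(pt) == 0:
        raise ValueError("pseudotime is constant")
    knots = np.quantile(pt, np.linspace(0, 1, max(df, 3)))
    knots = np.unique(knots)
    grid = np.linspace(pt.min(), pt.max(), n_points)
    if len(knots) < 3:
        # nearly tied pseudotime: fall back to a linear fit
        beta = np.polyfit(pt, expr, 1)
        return grid, np.polyval(beta, grid)
    B = natural_spline_basis(pt, knots)
    beta, *_ = np.linalg.lstsq(B, expr, rcond=None)
    return grid, natural_spline_basis(grid, knots) @ beta


def _exact_mk_p(s_obs: int, n: int) -> float:
    """Exact two-sided Mann-Kendall p from the permutation distribution of S.

    Uses the inversion-count recurrence: the number of permutations of n
    items with k inversions is conv of uniform blocks; S = n(n-1)/2 - 2k.
    Valid only for tie-free series.
    """
    counts = np.array([1.0])
    for m in range(2, n + 1):
        counts = np.convolve(counts, np.ones(m))
    counts /= counts.sum()
    max_s = n * (n - 1) // 2
    s_values = max_s - 2 * np.arange(len(counts))
    tail = counts[np.abs(s_values) >= abs(s_obs)].sum()
    return float(min(1.0, tail))


def mann_kendall(series: np.ndarray) -> tuple[float, float]:
    """Mann-Kendall trend test: returns ``(tau, p)``.

    ``tau = S / (n(n-1)/2)`` with ``S = sum_{i<j} sign(x_j - x_i)``.
    The p-value uses the tie-corrected normal approximation with
    continuity correction, or the exact S distribution for tie-free
    series of length <= 10. An all-tied series gives ``(0, 1)``.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("series must have length >= 4")
    diff = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(diff, 1).sum())
    denom = n * (n - 1) / 2
    tau = S / denom
    _, tie_counts = np.unique(x, return_counts=True)
    if np.all(tie_counts == n):  # pragma: no cover - single unique value
        return 0.0, 1.0
    if len(tie_counts) == 1:
        return 0.0, 1.0
    if n <= 10 and np.all(tie_counts == 1):
        return tau, _exact_mk_p(S, n)
    var = (n * (n - 1) * (2 * n + 5)
           - np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5))) / 18.0
    if var <= 0:
        return tau, 1.0
    if S > 0:
        z = (S - 1) / np.sqrt(var)
    elif S < 0:
        z = (S + 1) / np.sqrt(var)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return tau, float(min(1.0, p))


def trend_genes(adata: ad.AnnData, pseudotime: pd.Series,
                p_max: float = 0.05, tau_min: float = 0.7,
                n_points: int = 100) -> pd.DataFrame:
    """Screen genes with monotone expression trends along pseudotime.

    Each gene's log expression is spline-smoothed over pseudotime and the
    Mann-Kendall test is applied to the smoothed grid values; genes with
    ``p < p_max`` and ``|tau| > tau_min`` are kept, direction = sign(tau).
    """
    pt = pseudotime.reindex(adata.obs_names).to_numpy(dtype=float)
    X = _log(adata)
    rows = []
    for i, gene in enumerate(adata.var_names):
        _, curve = smooth_curve(X[:, i], pt, n_points=n_points)
        tau, p = mann_kendall(curve)
        rows.append((gene, tau, p))
    out = pd.DataFrame(rows, columns=["gene", "tau", "p"]).set_index("gene")
    out["direction"] = np.where(out["tau"] > 0, "up", "down")
    return out[(out["p"] < p_max) & (out["tau"].abs() > tau_min)]


# ---------------------------------------------------------------------------
# signature assembly


def intersect_signatures(gs1: set[str] | dict[str, str],
                         gs2: dict[str, str],
                         gs3: dict[str, str],
                         cancer: str = "",
                         min_membership: int = 2) -> SignatureSet:
    """Assemble one cancer's metastasis signature from the three gene sets.

    A gene enters when it belongs to at least ``min_membership`` of
    {GeneSet1, GeneSet2, GeneSet3}. Its direction comes from GeneSet2
    when present (the hEMT-vs-lEMT contrast is the phenotypic reference),
    else from GeneSet3's trend sign, else from GeneSet1's annotation.
    """
    gs1_dirs = gs1 if isinstance(gs1, dict) else {g: None for g in gs1}
    if not (gs1_dirs or gs2 or gs3):
        raise ValueError("all three gene sets are empty")
    sig = SignatureSet(cancer=cancer)
    universe = set(gs1_dirs) | set(gs2) | set(gs3)
    for gene in sorted(universe):
        tags = set()
        if gene in gs1_dirs:
            tags.add("GeneSet1")
        if gene in gs2:
            tags.add("GeneSet2")
        if gene in gs3:
            tags.add("GeneSet3")
        if len(tags) < min_membership:
            continue
        direction = gs2.get(gene) or gs3.get(gene) or gs1_dirs.get(gene)
        if direction not in ("up", "down"):
            continue
        sig.provenance[gene] = tags
        (sig.up if direction == "up" else sig.down).append(gene)
    return sig


def cross_cancer_shared(signatures: list[SignatureSet],
                        min_cancers: int = 3) -> dict[str, str]:
    """Genes sharing a direction in >= ``min_cancers`` cancers.

    Genes reaching the count in both directions are excluded as
    conflicting. Returns ``{gene: 'up'|'down'}``.
    """
    if len(signatures) < min_cancers:
        raise ValueError("fewer signature sets than min_cancers")
    up_count: dict[str, int] = {}
    down_count: dict[str, int] = {}
    for sig in signatures:
        for g in sig.up:
            up_count[g] = up_count.get(g, 0) + 1
        for g in sig.down:
            down_count[g] = down_count.get(g, 0) + 1
    out = {}
    for g in sorted(set(up_count) | set(down_count)):
        u, d = up_count.get(g, 0), down_count.get(g, 0)
        if u >= min_cancers and d >= min_cancers:
            continue
        if u >= min_cancers:
            out[g] = "up"
        elif d >= min_cancers:
            out[g] = "down"
    return out
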