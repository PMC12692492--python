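"""Synthetic data with the statistical structure the pipeline assumes.

Every generator here plants a known ground truth -- malignant cells with
CNV amplification/deletion blocks, a latent EMT gradient loading on an
EMT gene set, co-expression programs for NMF recovery, a pseudotime-ordered
transition, bulk cohorts whose metastasis label follows a logistic model on
signature genes, and drug-target networks with planted anti-metastatic
drugs -- so each downstream module can be validated by parameter recovery
instead of real downloads.

Expression is Gaussian on the log1p scale; the counts layer is
``round(expm1(log))``. Negative-binomial sequencing noise, doublets and
batch effects are deliberately out of scope.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "DrugWorld",
    "gen_single_cell",
    "gen_cnv_matrix",
    "gen_bulk",
    "gen_drug_world",
]


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with the study-condition defaults.

    A single global ``seed`` drives every generator through named
    substreams, so modules can be simulated in isolation and still be
    bit-reproducible.
    """

    seed: int = 0
    # single-cell world
    n_genes: int = 1000
    n_cells: int = 2000
    n_samples: int = 6
    n_cancers: int = 3
    malignant_frac: float = 0.5
    noise_sd: float = 0.5
    # latent EMT axis
    emt_set_size: int = 50
    emt_gradient_sd: float = 1.0
    # planted co-expression programs
    n_programs: int = 3
    program_size: int = 50
    program_effect: float = 1.0
    program_active_frac: float = 0.35
    # CNV matrix: blocks are (start, stop, mean shift) over feature index
    n_cnv_features: int = 1000
    cnv_blocks: tuple[tuple[int, int, float], ...] = (
        (100, 200, 0.3),
        (450, 550, -0.3),
        (800, 900, 0.3),
    )
    cnv_noise_sd: float = 0.05
    # bulk cohorts
    bulk_n: int = 400
    bulk_beta: float = 2.0
    bulk_n_genes: int = 300
    # drug world
    n_drugs: int = 50
    n_planted_drugs: int = 5
    targets_per_drug: int = 8
    target_overlap: float = 0.8
    perturb_delta: float = 1.0
    perturb_reps: int = 3
    ppi_extra_edges: int = 400

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_cells": self.n_cells,
            "n_samples": self.n_samples, "n_cancers": self.n_cancers,
            "emt_set_size": self.emt_set_size, "n_programs": self.n_programs,
            "program_size": self.program_size,
            "n_cnv_features": self.n_cnv_features, "bulk_n": self.bulk_n,
            "n_drugs": self.n_drugs, "targets_per_drug": self.targets_per_drug,
            "perturb_reps": self.perturb_reps,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"config field {name!r} must be a count >= 1, got {value}")
        nonneg = {
            "noise_sd": self.noise_sd, "emt_gradient_sd": self.emt_gradient_sd,
            "program_effect": self.program_effect,
            "cnv_noise_sd": self.cnv_noise_sd, "bulk_beta": self.bulk_beta,
            "perturb_delta": self.perturb_delta,
        }
        for name, value in nonneg.items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"config field {name!r} must be >= 0, got {value}")
        if not 0.0 < self.malignant_frac <= 1.0:
            raise ValueError("config field 'malignant_frac' must be in (0, 1]")
        if not 0.0 <= self.target_overlap <= 1.0:
            raise ValueError("config field 'target_overlap' must be in [0, 1]")
        if self.n_planted_drugs > self.n_drugs:
            raise ValueError("config field 'n_planted_drugs' exceeds n_drugs")
        for blk in self.cnv_blocks:
            start, stop, _shift = blk
            if not 0 <= start < stop <= self.n_cnv_features:
                raise ValueError(f"config field 'cnv_blocks' has invalid range {blk}")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted truth aligned by id with the generated matrices."""

    cell_ids: list[str] = field(default_factory=list)
    malignant_mask: np.ndarray | None = None        # bool per cell
    emt_latent: np.ndarray | None = None            # in [0, 1] per cell
    pseudotime: np.ndarray | None = None            # per cell
    program_membership: dict[str, int] = field(default_factory=dict)  # gene -> program
    emt_genes: list[str] = field(default_factory=list)
    signature_up: list[str] = field(default_factory=list)
    signature_down: list[str] = field(default_factory=list)
    planted_drugs: list[str] = field(default_factory=list)

    def program_gene_sets(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for gene, prog in self.program_membership.items():
            out.setdefault(prog, set()).add(gene)
        return out


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Deterministic substream: seed entropy = (global seed, crc32 of name)."""
    return np.random.default_rng([config.seed, zlib.crc32(stream.encode())])


# ---------------------------------------------------------------------------
# single-cell expression world


def gen_single_cell(config: SimConfig) -> tuple[ad.AnnData, pd.DataFrame, GroundTruth]:
    """Simulate a single-cell cohort with planted EMT gradient and programs.

    Returns an AnnData (cells x genes; ``X`` = log1p layer, ``layers['counts']``
    the rounded count layer), a per-cell metadata frame and the ground truth.
    Malignant cells carry the CNV blocks (materialized by
    :func:`gen_cnv_matrix`), EMT-set genes load linearly on a latent axis
    ``emt_latent``, and planted program genes co-vary within each program.
    """
    rng = _rng(config, "single_cell")
    G, C = config.n_genes, config.n_cells
    genes = [f"G{i:04d}" for i in range(G)]
    cells = [f"C{j:05d}" for j in range(C)]

    truth = GroundTruth(cell_ids=cells)
    truth.malignant_mask = rng.random(C) < config.malignant_frac
    truth.emt_latent = rng.random(C)
    # pseudotime follows the EMT axis with light observation noise
    truth.pseudotime = np.clip(
        truth.emt_latent + rng.normal(0.0, 0.05, C), 0.0, 1.0)

    baseline = rng.uniform(0.5, 2.5, G)
    X = baseline[None, :] + rng.normal(0.0, config.noise_sd, (C, G))

    # EMT gene set: the first emt_set_size genes after the program block
    used = config.n_programs * config.program_size
    emt_idx = np.arange(used, used + config.emt_set_size)
    if emt_idx[-1] >= G:
        raise ValueError("config field 'n_genes' too small for programs + EMT set")
    truth.emt_genes = [genes[i] for i in emt_idx]
    X[:, emt_idx] += config.emt_gradient_sd * truth.emt_latent[:, None]

    # planted programs: disjoint gene blocks, each active in a random
    # subset of malignant cells with a non-negative activity
    for p in range(config.n_programs):
        gidx = np.arange(p * config.program_size, (p + 1) * config.program_size)
        for i in gidx:
            truth.program_membership[genes[i]] = p
        active = rng.random(C) < config.program_active_frac
        activity = np.zeros(C)
        activity[active] = config.program_effect * (
            0.5 + rng.random(int(active.sum())))
        X[:, gidx] += activity[:, None]

    X = np.clip(X, 0.0, None)
    counts = np.round(np.expm1(X))

    adata = ad.AnnData(X=X)
    adata.obs_names = cells
    adata.var_names = genes
    adata.layers["counts"] = counts

    samples = np.array([f"S{j % config.n_samples:02d}" for j in range(C)])
    sample_to_cancer = {
        f"S{s:02d}": f"CA{s % config.n_cancers:02d}" for s in range(config.n_samples)}
    stage_bins = np.minimum((truth.emt_latent * 4).astype(int) + 1, 4)
    met_state = np.where(truth.emt_latent > 0.75, "DM",
                         np.where(truth.emt_latent > 0.5, "RM", "NM"))
    cell_type = np.where(truth.malignant_mask, "Epithelial",
                         rng.choice(["Epithelial", "T/NK", "Fibroblast"],
                                    size=C, p=[0.4, 0.4, 0.2]))
    meta = pd.DataFrame({
        "cell": cells,
        "sample": samples,
        "cancer": [sample_to_cancer[s] for s in samples],
        "stage": [["I", "II", "III", "IV"][s - 1] for s in stage_bins],
        "met_state": met_state,
        "cell_type": cell_type,
    }).set_index("cell", drop=False)
    adata.obs = meta.copy()
    return adata, meta, truth


def gen_cnv_matrix(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Simulate an inferCNV-style score matrix (cells x features, neutral 1).

    Non-malignant cells sit at ``1 + N(0, cnv_noise_sd)``; malignant cells
    additionally carry the configured amplification/deletion block shifts.
    Scores are truncated to stay positive.
    """
    rng = _rng(config, "cnv")
    C, F = len(truth.cell_ids), config.n_cnv_features
    scores = 1.0 + rng.normal(0.0, config.cnv_noise_sd, (C, F))
    mal = np.asarray(truth.malignant_mask, dtype=bool)
    for start, stop, shift in config.cnv_blocks:
        scores[mal, start:stop] += shift
    scores = np.clip(scores, 1e-3, None)
    features = [f"F{i:04d}" for i in range(F)]
    return pd.DataFrame(scores, index=truth.cell_ids, columns=features)


# ---------------------------------------------------------------------------
# bulk cohorts


def gen_bulk(config: SimConfig, signature: dict[str, str] | list[str],
             stream: str = "bulk") -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a bulk cohort whose metastasis label is logistic in a signature.

    ``signature`` is either a list of genes (all treated as up-regulated)
    or a ``{gene: 'up'|'down'}`` mapping. Each signature gene contributes
    coefficient ``+/- bulk_beta`` to the latent logit; the intercept is 0
    so the metastasis rate sits near one half. Returns (samples x genes
    expression, metastasis label series with values ``{'NM','M'}``).
    """
    if not signature:
        raise ValueError("signature is empty")
    if isinstance(signature, dict):
        sig_genes = list(signature)
        direction = np.array([1.0 if signature[g] == "up" else -1.0
                              for g in sig_genes])
    else:
        sig_genes = list(signature)
        direction = np.ones(len(sig_genes))

    rng = _rng(config, stream)
    n = config.bulk_n
    background = [f"B{i:04d}" for i in range(config.bulk_n_genes)]
    all_genes = sig_genes + [g for g in background if g not in set(sig_genes)]
    expr = rng.normal(0.0, 1.0, (n, len(all_genes)))
    df = pd.DataFrame(expr, columns=all_genes,
                      index=[f"BS{stream}{i:04d}" for i in range(n)])

    beta = config.bulk_beta * direction
    logit = df[sig_genes].to_numpy() @ beta
    prob = 1.0 / (1.0 + np.exp(-logit))
    labels = np.where(rng.random(n) < prob, "M", "NM")
    return df, pd.Series(labels, index=df.index, name="metastasis")


# ---------------------------------------------------------------------------
# drug world


@dataclass
class DrugWorld:
    """A simulated drug-target universe with planted anti-metastatic drugs."""

    drug_target_edges: pd.DataFrame     # columns: drug_id, gene_id
    ppi_edges: pd.DataFrame             # columns: gene_a, gene_b
    profiles: dict[str, dict[str, pd.DataFrame]]  # drug -> {treated, control}
    truth: GroundTruth
    genes: list[str]


def gen_drug_world(config: SimConfig,
                   signature: dict[str, str] | list[str]) -> DrugWorld:
    """Simulate drug-target edges, a PPI backbone and perturbation profiles.

    Planted drugs draw ``target_overlap`` of their targets from the
    signature genes and their treated profiles shift up-signature genes
    down (and down-signature genes up) by ``perturb_delta`` on the log
    scale; decoy drugs target random genes and have null profiles. The
    PPI backbone is a random spanning tree over the gene universe plus
    ``ppi_extra_edges`` random edges, so the network is connected.
    """
    if not signature:
        raise ValueError("signature is empty")
    if isinstance(signature, dict):
        up = [g for g, d in signature.items() if d == "up"]
        down = [g for g, d in signature.items() if d == "down"]
    else:
        up, down = list(signature), []
    sig_genes = up + down

    rng = _rng(config, "drugs")
    n_bg = max(4 * len(sig_genes), 100)
    background = [f"N{i:04d}" for i in range(n_bg)]
    genes = sig_genes + background

    drugs = [f"D{i:03d}" for i in range(config.n_drugs)]
    planted = drugs[: config.n_planted_drugs]

    dt_rows = []
    for d in drugs:
        k = config.targets_per_drug
        if d in planted:
            k_sig = min(int(round(config.target_overlap * k)), len(sig_genes))
            targets = list(rng.choice(sig_genes, size=k_sig, replace=False))
            targets += list(rng.choice(background, size=k - k_sig, replace=False))
        else:
            targets = list(rng.choice(background, size=k, replace=False))
        dt_rows += [(d, g) for g in targets]
    dt = pd.DataFrame(dt_rows, columns=["drug_id", "gene_id"])

    # connected PPI: random spanning tree + extra random edges
    perm = rng.permutation(len(genes))
    ppi_rows = []
    for i in range(1, len(genes)):
        j = int(rng.integers(0, i))
        ppi_rows.append((genes[perm[j]], genes[perm[i]]))
    for _ in range(config.ppi_extra_edges):
        a, b = rng.choice(len(genes), size=2, replace=False)
        ppi_rows.append((genes[a], genes[b]))
    ppi = pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b"])

    baseline = rng.uniform(2.0, 6.0, len(genes))
    up_idx = [genes.index(g) for g in up]
    down_idx = [genes.index(g) for g in down]
    profiles: dict[str, dict[str, pd.DataFrame]] = {}
    for d in drugs:
        ctrl = baseline[:, None] + rng.normal(0.0, 0.25,
                                              (len(genes), config.perturb_reps))
        treat = baseline[:, None] + rng.normal(0.0, 0.25,
                                               (len(genes), config.perturb_reps))
        if d in planted:
            treat[up_idx, :] -= config.perturb_delta
            treat[down_idx, :] += config.perturb_delta
        cols_t = [f"{d}_T{r}" for r in range(config.perturb_reps)]
        cols_c = [f"{d}_C{r}" for r in range(config.perturb_reps)]
        profiles[d] = {
            "treated": pd.DataFrame(treat, index=genes, columns=cols_t),
            "control": pd.DataFrame(ctrl, index=genes, columns=cols_c),
        }

    truth = GroundTruth(signature_up=up, signature_down=down,
                        planted_drugs=planted)
    return DrugWorld(drug_target_edges=dt, ppi_edges=ppi,
                     profiles=profiles, truth=truth, genes=genes)
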