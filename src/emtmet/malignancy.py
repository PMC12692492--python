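"""Malignant-cell identification from inferred CNV score profiles.

Cells are called Malignant / NotMalignant / Other from two statistics:

* **CNV deviation** of cell *j*: ``(1/n) * sum_i (score_ij - 1)^2``, the
  mean squared deviation of the cell's copy-number scores from the
  neutral value 1 over its *n* genomic features.
* **Reference correlation**: Pearson correlation of the cell's feature
  profile with a reference curve, the feature-wise mean profile of the
  top fraction (default 5%) of cells by CNV deviation.

The two-threshold rule (strict inequalities): deviation > ``dev_thr`` and
correlation > ``cor_thr`` is Malignant; deviation < ``dev_thr`` and
correlation < ``cor_thr`` is NotMalignant; everything else -- including
exact threshold equality -- is Other. Defaults ``dev_thr=0.002`` and
``cor_thr=0.1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CnvProfile",
    "compute_cnv_deviation",
    "build_reference_curve",
    "correlate_to_reference",
    "classify_malignancy",
    "call_malignancy",
]

DEV_THR_DEFAULT = 0.002
COR_THR_DEFAULT = 0.1


@dataclass
class CnvProfile:
    """Cells x genomically-ordered features CNV score matrix, neutral = 1."""

    scores: pd.DataFrame  # cells x features

    def __post_init__(self) -> None:
        if self.scores.shape[0] == 0 or self.scores.shape[1] == 0:
            raise ValueError("empty CNV profile")

    @property
    def cell_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.scores.columns


def _as_profile(profile: CnvProfile | pd.DataFrame) -> CnvProfile:
    if isinstance(profile, pd.DataFrame):
        return CnvProfile(profile)
    return profile


def compute_cnv_deviation(profile: CnvProfile | pd.DataFrame,
                          sqrt: bool = False) -> pd.Series:
    """Per-cell mean squared deviation of CNV scores from neutral 1.

    With ``sqrt=True`` the root-mean-square deviation is returned instead
    (sensitivity analysis; the squared form is the default scale on which
    the 0.002 threshold operates).
    """
    profile = _as_profile(profile)
    mat = profile.scores.to_numpy(dtype=float)
    bad = ~np.isfinite(mat)
    if bad.any():
        cells = profile.cell_ids[np.where(bad.any(axis=1))[0]].tolist()
        raise ValueError(f"non-finite CNV scores in cells: {cells[:10]}")
    dev = np.mean((mat - 1.0) ** 2, axis=1)
    if sqrt:
        dev = np.sqrt(dev)
    return pd.Series(dev, index=profile.cell_ids, name="cnv_deviation")


def build_reference_curve(profile: CnvProfile | pd.DataFrame,
                          top_frac: float = 0.05,
                          deviation: pd.Series | None = None) -> pd.Series:
    """Feature-wise mean CNV profile of the top ``top_frac`` highest-deviation cells.

    Ties at the cutoff are broken by stable cell-id order (first wins).
    """
    profile = _as_profile(profile)
    if not 0.0 < top_frac <= 1.0:
        raise ValueError("top_frac must be in (0, 1]")
    if deviation is None:
        deviation = compute_cnv_deviation(profile)
    n_top = max(1, int(np.ceil(top_frac * len(deviation))))
    # stable sort on -deviation keeps original id order among ties
    order = np.argsort(-deviation.to_numpy(), kind="stable")[:n_top]
    top_cells = profile.cell_ids[order]
    curve = profile.scores.loc[top_cells].mean(axis=0)
    curve.name = "reference_curve"
    return curve


def correlate_to_reference(profile: CnvProfile | pd.DataFrame,
                           curve: pd.Series | np.ndarray) -> pd.Series:
    """Pearson correlation of each cell's CNV profile with the reference curve.

    Cells (or a curve) with zero variance yield NaN; the classifier treats
    NaN as below the correlation threshold.
    """
    profile = _as_profile(profile)
    curve = np.asarray(curve, dtype=float)
    mat = profile.scores.to_numpy(dtype=float)
    if curve.shape[0] != mat.shape[1]:
        raise ValueError(
            f"curve length {curve.shape[0]} != feature count {mat.shape[1]}")
    xc = mat - mat.mean(axis=1, keepdims=True)
    yc = curve - curve.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc @ yc) / denom, np.nan)
    return pd.Series(r, index=profile.cell_ids, name="ref_correlation")


def classify_malignancy(deviation: pd.Series, correlation: pd.Series,
                        dev_thr: float = DEV_THR_DEFAULT,
                        cor_thr: float = COR_THR_DEFAULT,
                        cell_type: pd.Series | None = None) -> pd.DataFrame:
    """Apply the two-threshold malignancy rule per cell.

    If ``cell_type`` is given, only cells annotated ``'Epithelial'`` are
    eligible for the Malignant label; non-epithelial cells that meet the
    thresholds are labeled Other.
    """
    if not deviation.index.equals(correlation.index):
        correlation = correlation.reindex(deviation.index)
    dev = deviation.to_numpy(dtype=float)
    cor = correlation.to_numpy(dtype=float)
    cor_low = np.where(np.isnan(cor), True, cor < cor_thr)
    cor_high = np.where(np.isnan(cor), False, cor > cor_thr)
    label = np.full(len(dev), "Other", dtype=object)
    label[(dev > dev_thr) & cor_high] = "Malignant"
    label[(dev < dev_thr) & cor_low] = "NotMalignant"
    if cell_type is not None:
        epi = cell_type.reindex(deviation.index).to_numpy() == "Epithelial"
        label[(label == "Malignant") & ~epi] = "Other"
    return pd.DataFrame({
        "deviation": dev,
        "correlation": cor,
        "label": label,
    }, index=deviation.index)


def call_malignancy(profile: CnvProfile | pd.DataFrame,
                    dev_thr: float = DEV_THR_DEFAULT,
                    cor_thr: float = COR_THR_DEFAULT,
                    top_frac: float = 0.05,
                    sqrt: bool = False,
                    cell_type: pd.Series | None = None) -> pd.DataFrame:
    """Full malignancy pipeline: deviation, reference curve, correlation, call."""
    profile = _as_profile(profile)
    deviation = compute_cnv_deviation(profile, sqrt=sqrt)
    rank_dev = deviation if not sqrt else compute_cnv_deviation(profile)
    curve = build_reference_curve(profile, top_frac=top_frac, deviation=rank_dev)
    correlation = correlate_to_reference(profile, curve)
    return classify_malignancy(deviation, correlation, dev_thr=dev_thr,
                               cor_thr=cor_thr, cell_type=cell_type)
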