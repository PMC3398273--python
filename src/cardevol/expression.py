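"""Breadth, specificity, persistence and level statistics from a log2
expression matrix with AtGenExpress-like sample metadata.

The matrix holds log2 intensities (genes x samples); metadata assigns every
sample an organ, a developmental stage, and — for stress samples — a stress
label, timepoint and treated/control flag.  Breadth statistics operate on the
back-transformed (linear, 2^x) scale with a strict detection threshold of 75
intensity units; mean and maximum expression levels are reported on the log2
scale by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 75.0
DEFAULT_FOLD = 3.0


def _dev_mask(metadata: pd.DataFrame) -> pd.Series:
    return metadata["stress"].astype(str).fillna("") == ""


def back_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Linear-scale intensities: entrywise 2**x."""
    return np.power(2.0, matrix)


def organ_profile(gene_row: pd.Series, metadata: pd.DataFrame, agg: str = "max") -> pd.Series:
    """Per-organ aggregate (default: maximum across developmental stages) of a
    linear-scale gene row over the development-map samples."""
    meta = metadata.set_index("sample_id").loc[gene_row.index.intersection(metadata["sample_id"])]
    dev = meta[_dev_mask(meta.reset_index()).to_numpy()]
    vals = gene_row.loc[dev.index]
    return vals.groupby(dev["organ"]).agg(agg)


def spatial_breadth(
    gene_row: pd.Series, metadata: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> int:
    """Number of organs where any stage-sample exceeds the threshold
    (strictly greater), on linear-scale values."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    prof = organ_profile(gene_row, metadata, agg="max")
    return int((prof > threshold).sum())


def organ_specificity_tau(organ_values) -> float:
    """Organ specificity index tau on per-organ aggregated linear values:

        tau = sum_i (1 - x_i / x_max) / (N - 1)

    0 for uniform expression, approaching 1 for single-organ expression.
    """
    x = np.asarray(organ_values, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs >= 2 organs")
    xmax = x.max()
    if xmax <= 0:
        warnings.warn("all-zero organ profile; tau undefined", stacklevel=2)
        return np.nan
    return float((1.0 - x / xmax).sum() / (x.size - 1))


def temporal_breadth(
    gene_row: pd.Series,
    metadata: pd.DataFrame,
    tissue: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> int:
    """Number of developmental time points of one tissue series (flower or
    leaf) at which the linear-scale value strictly exceeds the threshold."""
    meta = metadata.set_index("sample_id")
    dev = meta[(_dev_mask(meta.reset_index()).to_numpy()) & (meta["organ"] == tissue)]
    if dev.empty:
        raise ValueError(f"tissue {tissue!r} absent from metadata")
    vals = gene_row.loc[dev.index]
    return int((vals > threshold).sum())


def stress_persistence(
    gene_row: pd.Series,
    metadata: pd.DataFrame,
    stress: str,
    fold: float = DEFAULT_FOLD,
) -> int:
    """Number of stress timepoints at which treated expression is at least
    ``fold`` times the paired control (linear scale, inclusive boundary)."""
    meta = metadata.set_index("sample_id")
    sel = meta[meta["stress"].astype(str) == stress]
    if sel.empty:
        raise ValueError(f"stress {stress!r} absent from metadata")
    count = 0
    for tp, grp in sel.groupby("timepoint"):
        treated = grp.index[grp["treated"].astype(int) == 1]
        control = grp.index[grp["treated"].astype(int) == 0]
        if len(treated) == 0 or len(control) == 0:
            warnings.warn(f"stress {stress} timepoint {tp}: missing pair; skipped", stacklevel=2)
            continue
        if gene_row.loc[treated].mean() >= fold * gene_row.loc[control].mean():
            count += 1
    return count


def expression_levels(gene_row: pd.Series, metadata: pd.DataFrame | None = None) -> tuple[float, float]:
    """(mean, max) of a gene row over the development-map samples, on the
    scale the row is given in (log2 by convention)."""
    if metadata is not None:
        meta = metadata.set_index("sample_id")
        dev = meta[_dev_mask(meta.reset_index()).to_numpy()]
        gene_row = gene_row.loc[gene_row.index.intersection(dev.index)]
    if gene_row.empty:
        raise ValueError("empty gene row")
    return float(gene_row.mean()), float(gene_row.max())


@dataclass
class BreadthProfile:
    """Per-gene breadth and level summary."""

    gene_id: str
    spatial_breadth: int
    tau: float
    temporal_breadth_flower: int
    temporal_breadth_leaf: int
    persistence: dict
    mean_expr: float
    max_expr: float


def breadth_profiles(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    fold: float = DEFAULT_FOLD,
) -> pd.DataFrame:
    """BreadthProfile table for every gene of a log2 expression matrix.

    Vectorized equivalent of the per-gene operations: thresholded statistics
    use the back-transformed matrix; mean/max levels stay on the log2 scale.
    """
    meta = metadata.set_index("sample_id").loc[matrix.columns.intersection(metadata["sample_id"])]
    linear = back_transform(matrix[meta.index])
    dev = meta[meta["stress"].astype(str).fillna("") == ""]
    dev_cols = dev.index

    # per-organ maximum across stages -> genes x organs
    organ_max = linear[dev_cols].T.groupby(dev["organ"]).max().T
    spatial = (organ_max > threshold).sum(axis=1).astype(int)
    xmax = organ_max.max(axis=1)
    n_org = organ_max.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - organ_max.div(xmax, axis=0)).sum(axis=1) / (n_org - 1)
    tau[xmax <= 0] = np.nan

    out = pd.DataFrame(
        {
            "spatial_breadth": spatial,
            "tau": tau,
            "mean_expr": matrix[dev_cols].mean(axis=1),
            "max_expr": matrix[dev_cols].max(axis=1),
        }
    )
    for tissue in ("flower", "leaf"):
        cols = dev.index[dev["organ"] == tissue]
        if len(cols):
            out[f"temporal_breadth_{tissue}"] = (linear[cols] > threshold).sum(axis=1).astype(int)
    stresses = sorted(s for s in meta["stress"].astype(str).unique() if s not in ("", "nan"))
    for s in stresses:
        sel = meta[meta["stress"].astype(str) == s]
        count = pd.Series(0, index=matrix.index)
        for _, grp in sel.groupby("timepoint"):
            treated = grp.index[grp["treated"].astype(int) == 1]
            control = grp.index[grp["treated"].astype(int) == 0]
            if len(treated) == 0 or len(control) == 0:
                warnings.warn(f"stress {s}: unpaired timepoint skipped", stacklevel=2)
                continue
            ratio_ok = linear[treated].mean(axis=1) >= fold * linear[control].mean(axis=1)
            count += ratio_ok.astype(int)
        out[f"persist_{s}"] = count
    out.index.name = "gene_id"
    return out
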