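"""Stage-1 exploratory sample-level QC: per-sample medians, classical MDS
and an annotated sample heatmap.

MDS here is classical metric scaling (principal coordinates): for samples
generated in a Euclidean space of matching rank the embedding reproduces the
input distances exactly, which makes it a cheap, deterministic batch-effect
detector.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist, squareform

from .core import Experiment, SampleTable
from .errors import MetadataError


def per_sample_medians(exp: Experiment, markers=None) -> pd.DataFrame:
    """Median transformed expression per (sample, marker).

    Samples with zero cells are excluded with a warning.
    """
    names = exp.panel.marker_names
    if markers is not None:
        idx = [exp.panel.index_of(m) for m in markers]
        names = [names[i] for i in idx]
    else:
        idx = list(range(exp.n_channels))
    rows = {}
    empty = []
    for sid in exp.samples.ids:
        mask = exp.sample_mask(sid)
        if not mask.any():
            empty.append(sid)
            continue
        rows[sid] = np.median(exp.transformed[np.flatnonzero(mask)][:, idx], axis=0)
    if empty:
        warnings.warn(f"samples with zero cells excluded from medians: {empty}", stacklevel=2)
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)


def mds_samples(medians: pd.DataFrame, n_dim: int = 2):
    """Classical MDS (principal coordinates) of the per-sample median table.

    Pipeline: Euclidean distance matrix -> double centering
    ``B = -1/2 J D^2 J`` -> top eigenpairs -> coordinates scaled by the
    square root of each eigenvalue.  Axes are ordered by decreasing
    eigenvalue and sign-fixed so the largest-magnitude loading on each axis
    is positive.  Negative eigenvalues (non-Euclidean input) are truncated to
    zero with a warning.

    Returns ``(coords, eigenvalues)`` where ``coords`` is a DataFrame indexed
    like ``medians``.
    """
    n = len(medians)
    if n < 3:
        raise ValueError(f"MDS needs >= 3 samples, got {n}")
    if not (0 < n_dim < n):
        raise ValueError(f"n_dim must be in 1..{n - 1}, got {n_dim}")
    X = medians.to_numpy(dtype=float)
    D = squareform(pdist(X, metric="euclidean"))
    D2 = D**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if (evals < -1e-8 * max(1.0, abs(evals[0]))).any():
        warnings.warn(
            "negative MDS eigenvalues truncated to zero (non-Euclidean distances)",
            stacklevel=2,
        )
    evals = np.clip(evals, 0.0, None)
    coords = evecs[:, :n_dim] * np.sqrt(evals[:n_dim])
    for j in range(coords.shape[1]):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    cols = [f"MDS{i+1}" for i in range(n_dim)]
    return pd.DataFrame(coords, index=medians.index, columns=cols), evals


def _scale_columns(m: pd.DataFrame, scale: str) -> pd.DataFrame:
    if scale == "none":
        return m.copy()
    if scale == "zero_one":
        lo, hi = m.min(axis=0), m.max(axis=0)
        rng = (hi - lo).replace(0, 1.0)
        return (m - lo) / rng
    if scale == "zscore":
        sd = m.std(axis=0, ddof=0).replace(0, 1.0)
        return (m - m.mean(axis=0)) / sd
    raise ValueError(f"unknown scale {scale!r}; expected none/zero_one/zscore")


def sample_heatmap(
    medians: pd.DataFrame,
    scale: str = "none",
    cluster_rows: bool = True,
    cluster_cols: bool = True,
    annotations=None,
    samples: SampleTable | None = None,
    render: bool = False,
):
    """Scaled/ordered sample x marker matrix for heatmap display.

    Hierarchical ordering uses Euclidean distance with average linkage.
    ``annotations`` names sample-metadata columns to join as tracks (requires
    ``samples``).  Returns a dict with the reordered matrix, row/col orders,
    the annotation frame, and (if ``render``) a matplotlib figure.
    """
    mat = _scale_columns(medians, scale)
    row_order = np.arange(len(mat))
    col_order = np.arange(mat.shape[1])
    if cluster_rows and len(mat) > 2:
        row_order = leaves_list(average(pdist(mat.to_numpy())))
    if cluster_cols and mat.shape[1] > 2:
        col_order = leaves_list(average(pdist(mat.to_numpy().T)))
    mat = mat.iloc[row_order, :].iloc[:, col_order]

    ann = None
    if annotations:
        if samples is None:
            raise MetadataError("annotations requested but no sample table given")
        ann = pd.DataFrame(index=mat.index)
        for col in annotations:
            ann[col] = samples.column(col).reindex(mat.index)

    fig = None
    if render:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1 + 0.4 * mat.shape[1], 1 + 0.3 * len(mat)))
        im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(mat)), mat.index, fontsize=7)
        fig.colorbar(im, ax=ax, shrink=0.7)
        fig.tight_layout()
    return {
        "matrix": mat,
        "row_order": row_order,
        "col_order": col_order,
        "annotations": ann,
        "figure": fig,
    }
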