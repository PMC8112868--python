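"""Stage-3 cluster identification: expression summaries, rank heatmap,
table-driven cluster merging and plot-data extraction."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import Experiment
from .errors import CompletenessError, MetadataError, PanelError, StateError


def _get_labels(exp: Experiment, clustering: str, K: int) -> np.ndarray:
    if clustering not in exp.clusterings:
        raise StateError(
            f"no clustering named {clustering!r}; available: {list(exp.clusterings)}"
        )
    return exp.clusterings[clustering].labels(K)


def cluster_medians(
    exp: Experiment,
    clustering: str,
    K: int,
    scale: str = "none",
) -> pd.DataFrame:
    """Median transformed expression per (cluster, marker).

    ``scale='zero_one'`` rescales each marker column to [0, 1] across
    clusters.  Empty clusters yield NaN rows with a warning.
    """
    if scale not in ("none", "zero_one"):
        raise ValueError(f"unknown scale {scale!r}")
    labels = _get_labels(exp, clustering, K)
    rows = {}
    empty = []
    for c in range(1, K + 1):
        mask = labels == c
        if mask.any():
            rows[c] = np.median(exp.transformed[mask], axis=0)
        else:
            empty.append(c)
            rows[c] = np.full(exp.n_channels, np.nan)
    if empty:
        warnings.warn(f"empty clusters at K={K}: {empty}", stacklevel=2)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=exp.panel.marker_names)
    out.index.name = "cluster"
    if scale == "zero_one":
        lo, hi = out.min(axis=0), out.max(axis=0)
        rng = (hi - lo).replace(0, 1.0)
        out = (out - lo) / rng
    return out


def imc_rank(medians: pd.DataFrame) -> pd.DataFrame:
    """Rank clusters within each marker (1 = lowest median, n = highest).

    Ties get the average (mid) rank, which makes the table invariant under
    any strictly monotone transform of a marker's medians.
    """
    if len(medians) < 2:
        raise ValueError(f"ranking needs >= 2 clusters, got {len(medians)}")
    ranked = medians.apply(lambda col: stats.rankdata(col, method="average"), axis=0)
    return pd.DataFrame(ranked, index=medians.index, columns=medians.columns)


class MergeTable:
    """Cluster -> cell-type name lookup for one K, versionable as CSV."""

    def __init__(self, mapping: dict[int, str], version: str = "v1"):
        clean: dict[int, str] = {}
        for k, v in mapping.items():
            name = str(v).strip()
            if not name:
                raise ValueError(f"empty cell-type name for cluster {k}")
            clean[int(k)] = name
        self.mapping = clean
        self.version = version

    @classmethod
    def from_csv(cls, path, version: str | None = None) -> "MergeTable":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("merge table CSV needs two columns: cluster, name")
        col_c, col_n = df.columns[:2]
        return cls(
            dict(zip(df[col_c].astype(int), df[col_n].astype(str))),
            version=version or str(path),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"cluster": sorted(self.mapping), "name": [self.mapping[c] for c in sorted(self.mapping)]}
        ).to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.mapping)


def merge_clusters(
    exp: Experiment,
    clustering: str,
    K: int,
    merge: MergeTable,
    layer_name: str | None = None,
) -> np.ndarray:
    """Collapse integer clusters at K into named cell types.

    Adds a text label layer; the original integer labels are retained
    untouched and the merge table is stored in provenance so the merge is
    reproducible (and reversible).  The table must cover every cluster
    present at K.
    """
    labels = _get_labels(exp, clustering, K)
    present = sorted(int(u) for u in np.unique(labels))
    missing = [c for c in present if c not in merge.mapping]
    if missing:
        raise CompletenessError(
            f"merge table does not cover clusters {missing} at K={K}"
        )
    name = layer_name or f"{clustering}_K{K}_merged"
    text = np.array([merge.mapping[int(l)] for l in labels], dtype=object)
    exp.add_cell_labels(name, text)
    exp.merge_provenance[name] = {
        "clustering": clustering,
        "K": K,
        "table": dict(merge.mapping),
        "version": merge.version,
    }
    return text


def unmerge_labels(exp: Experiment, layer_name: str) -> np.ndarray:
    """Recover the integer labels a merged layer was built from."""
    if layer_name not in exp.merge_provenance:
        raise StateError(f"no merge provenance for layer {layer_name!r}")
    prov = exp.merge_provenance[layer_name]
    return _get_labels(exp, prov["clustering"], prov["K"])


def biaxial_data(
    exp: Experiment,
    marker_x: str,
    marker_y: str,
    clustering: str | None = None,
    K: int | None = None,
    clusters=None,
    labels_layer: str | None = None,
    labels=None,
    sample_ids=None,
    levels=(0.25, 0.5, 0.75),
    grid_size: int = 128,
):
    """Two-marker scatter data with KDE contour polylines.

    The subset can be a set of clusters (with ``clustering``/``K``), a set of
    text labels, or a set of samples.  Contour levels are density quantiles
    of the selected points; returned polylines are in data coordinates.
    """
    ix = exp.panel.index_of(marker_x)
    iy = exp.panel.index_of(marker_y)

    mask = np.ones(exp.n_cells, dtype=bool)
    if clusters is not None:
        if clustering is None or K is None:
            raise ValueError("cluster subset needs clustering and K")
        labs = _get_labels(exp, clustering, K)
        mask &= np.isin(labs, list(clusters))
    if labels is not None:
        if labels_layer is None or labels_layer not in exp.cell_labels:
            raise StateError(f"no cell_labels layer named {labels_layer!r}")
        mask &= np.isin(exp.cell_labels[labels_layer], list(labels))
    if sample_ids is not None:
        mask &= np.isin(exp.cell_sample.astype(str), [str(s) for s in sample_ids])

    pts = exp.transformed[mask][:, [ix, iy]]
    points = pd.DataFrame(pts, columns=[marker_x, marker_y])

    contours = []
    if len(pts) >= 10 and not np.allclose(pts.std(axis=0), 0):
        try:
            kde = stats.gaussian_kde(pts.T)
        except np.linalg.LinAlgError:
            kde = None
        if kde is not None:
            from skimage import measure

            lo = pts.min(axis=0)
            hi = pts.max(axis=0)
            pad = 0.1 * (hi - lo + 1e-12)
            xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_size)
            ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_size)
            gx, gy = np.meshgrid(xs, ys, indexing="ij")
            dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(grid_size, grid_size)
            point_dens = kde(pts.T)
            for q in sorted(levels):
                thr = float(np.quantile(point_dens, q))
                lines = []
                for contour in measure.find_contours(dens, thr):
                    cx = np.interp(contour[:, 0], np.arange(grid_size), xs)
                    cy = np.interp(contour[:, 1], np.arange(grid_size), ys)
                    lines.append(np.column_stack([cx, cy]))
                contours.append({"level": q, "threshold": thr, "paths": lines})
    return points, contours


def feature_overlay(exp: Experiment, reduction: str, feature: str):
    """Per-cell values for coloring an embedding (Fig-style marker overlay).

    ``feature`` may be a marker name, a sample-metadata column, or a cell
    label layer.  Only embedded cells (finite coordinates) are returned.
    """
    if reduction not in exp.reductions:
        raise StateError(
            f"no reduction named {reduction!r}; available: {list(exp.reductions)}"
        )
    coords = exp.reductions[reduction]
    ok = np.isfinite(coords).all(axis=1)

    values: np.ndarray
    try:
        idx = exp.panel.index_of(feature)
        values = exp.transformed[:, idx]
    except PanelError:
        if feature in exp.cell_labels:
            values = exp.cell_labels[feature]
        elif feature in exp.samples.table.columns:
            lut = exp.samples.column(feature)
            values = np.array([lut[s] for s in exp.cell_sample], dtype=object)
        else:
            raise MetadataError(
                f"{feature!r} is neither a marker, a label layer, nor a "
                "sample metadata column"
            )
    return pd.DataFrame(
        {
            "x": coords[ok, 0],
            "y": coords[ok, 1],
            "value": np.asarray(values)[ok],
        }
    )
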