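"""Stage-2 nonlinear 2-D embeddings (UMAP, tSNE) and per-cell density.

Embeddings operate on the channels flagged ``use_reduction`` and may run on
a downsampled subset; excluded cells carry NaN coordinates in the stored
reduction so every reduction stays aligned to the full cell set.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core import Experiment, marker_matrix
from .errors import DegenerateDataError
from .preprocess import DownsampleConfig, select_downsample_indices


def _embed_subset(exp: Experiment, ds: DownsampleConfig | None):
    m, names = marker_matrix(exp, "reduction")
    if ds is not None and ds.mode != "none":
        kept = select_downsample_indices(exp.cell_sample, exp.samples.ids, ds)
    else:
        kept = np.arange(exp.n_cells)
    return m[kept], kept, names


def _store(exp: Experiment, name: str, kept: np.ndarray, coords2: np.ndarray) -> np.ndarray:
    full = np.full((exp.n_cells, 2), np.nan)
    full[kept] = coords2
    exp.add_reduction(name, full)
    return full


def run_umap(
    exp: Experiment,
    ds: DownsampleConfig | None = None,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    name: str = "umap",
) -> np.ndarray:
    """UMAP embedding of the reduction markers; stored as ``reductions[name]``.

    With a fixed seed and a single thread the run is reproducible.
    """
    m, kept, _ = _embed_subset(exp, ds)
    if len(kept) < n_neighbors + 1:
        raise ValueError(
            f"need >= n_neighbors+1 = {n_neighbors + 1} cells after downsampling, "
            f"got {len(kept)}"
        )
    import umap  # deferred: numba compilation is slow at import

    model = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=int(seed),
        n_jobs=1,
    )
    coords = model.fit_transform(m)
    return _store(exp, name, kept, np.asarray(coords, dtype=float))


def run_tsne(
    exp: Experiment,
    ds: DownsampleConfig | None = None,
    seed: int = 0,
    perplexity: float = 30.0,
    name: str = "tsne",
) -> np.ndarray:
    """tSNE embedding of the reduction markers; stored as ``reductions[name]``."""
    m, kept, _ = _embed_subset(exp, ds)
    bound = (len(kept) - 1) / 3
    if perplexity >= bound:
        raise ValueError(
            f"perplexity must be < (n_cells-1)/3 = {bound:.2f}, got {perplexity}"
        )
    from sklearn.manifold import TSNE

    model = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=int(seed),
        init="pca",
    )
    coords = model.fit_transform(m)
    return _store(exp, name, kept, np.asarray(coords, dtype=float))


def embedding_density(coords: np.ndarray) -> np.ndarray:
    """Gaussian KDE (Scott's rule) evaluated at every embedded point.

    NaN coordinate rows (cells excluded from the embedding) get NaN density.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError(f"expected (n, 2) coordinates, got shape {coords.shape}")
    ok = np.isfinite(coords).all(axis=1)
    pts = coords[ok]
    if len(pts) < 2:
        raise ValueError("need >= 2 embedded points for a density estimate")
    if np.allclose(pts, pts[0]):
        raise DegenerateDataError(
            "all embedded points coincide; add jitter before estimating density"
        )
    try:
        kde = stats.gaussian_kde(pts.T)  # Scott's rule by default
        dens = kde(pts.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(
            f"degenerate embedding (singular covariance): {exc}; add jitter"
        ) from exc
    out = np.full(len(coords), np.nan)
    out[ok] = dens
    return out
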