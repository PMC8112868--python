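"""Import-time preprocessing: intensity recovery, arcsinh transform, and
seeded downsampling.

Default arcsinh cofactors by modality: 5 (mass cytometry), 150 (fluorescence
flow), 0.8 (imaging mass cytometry cell tables).  "Adaptive" downsampling is
implemented as two explicit modes: ``equal_per_sample`` (every sample
contributes the same number of cells, up to its size) and ``total_cap``
(a global budget split into per-sample quotas).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Experiment, Panel, SampleTable, build_experiment
from .errors import MetadataError
from .fcs import RawSample, read_cell_table, read_fcs

DEFAULT_COFACTORS = {"mass": 5.0, "flow": 150.0, "imc": 0.8}


@dataclass
class TransformConfig:
    """Entrywise transform applied at import.

    ``imc_recover`` multiplies by 65,535 first (segmentation tools export
    mean intensities normalised to [0, 1] from 16-bit images).
    """

    kind: str = "arcsinh"  # 'arcsinh' | 'none'
    cofactor: float = 5.0
    imc_recover: bool = False

    def __post_init__(self):
        if self.kind not in ("arcsinh", "none"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.cofactor <= 0:
            raise ValueError(f"cofactor must be > 0, got {self.cofactor}")


@dataclass
class DownsampleConfig:
    mode: str = "none"  # 'equal_per_sample' | 'total_cap' | 'none'
    target: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("equal_per_sample", "total_cap", "none"):
            raise ValueError(f"unknown downsample mode {self.mode!r}")
        if self.target < 1:
            raise ValueError(f"downsample target must be >= 1, got {self.target}")


def recover_imc_intensity(m: np.ndarray) -> np.ndarray:
    """Rescale [0, 1] mean intensities back to 16-bit image units (x 65,535)."""
    m = np.asarray(m, dtype=float)
    if m.size and (np.nanmin(m) < 0 or np.nanmax(m) > 1):
        warnings.warn(
            "recover_imc_intensity: values outside [0, 1]; input may already "
            "be on the image scale",
            stacklevel=2,
        )
    return m * 65535.0


def arcsinh_transform(m: np.ndarray, cofactor: float) -> np.ndarray:
    """Entrywise ``asinh(x / cofactor)``."""
    if cofactor <= 0:
        raise ValueError(f"cofactor must be > 0, got {cofactor}")
    return np.arcsinh(np.asarray(m, dtype=float) / cofactor)


def apply_transform(exp: Experiment, cfg: TransformConfig) -> Experiment:
    """Set ``exp.transformed`` from ``exp.raw`` according to ``cfg`` (in place)."""
    m = exp.raw
    if cfg.imc_recover:
        m = recover_imc_intensity(m)
    if cfg.kind == "arcsinh":
        exp.transformed = arcsinh_transform(m, cfg.cofactor)
    else:
        exp.transformed = np.array(m, dtype=float, copy=True)
    return exp


def _per_sample_quota(sizes: dict[str, int], cfg: DownsampleConfig) -> dict[str, int]:
    if cfg.mode == "equal_per_sample":
        quota = {}
        for sid, n in sizes.items():
            if n < cfg.target:
                warnings.warn(
                    f"sample {sid!r} has {n} cells < target {cfg.target}; keeping all",
                    stacklevel=3,
                )
            quota[sid] = min(cfg.target, n)
        return quota
    if cfg.mode == "total_cap":
        n_samples = len(sizes)
        base = cfg.target // n_samples
        remainder = cfg.target % n_samples
        # remainder cells go to the largest samples first
        order = sorted(sizes, key=lambda s: (-sizes[s], s))
        quota = {sid: base for sid in sizes}
        for sid in order[:remainder]:
            quota[sid] += 1
        return {sid: min(q, sizes[sid]) for sid, q in quota.items()}
    raise ValueError(cfg.mode)


def select_downsample_indices(
    cell_sample: np.ndarray, sample_order: Sequence[str], cfg: DownsampleConfig
) -> np.ndarray:
    """Kept cell indices (sorted ascending) for a downsampling config.

    Each sample's draw is seeded by ``(cfg.seed, sample position)`` so adding
    or removing one sample never perturbs another sample's draw.
    """
    cell_sample = np.asarray(cell_sample)
    if cfg.mode == "none":
        return np.arange(len(cell_sample))
    present = [s for s in sample_order if (cell_sample == s).any()]
    sizes = {s: int((cell_sample == s).sum()) for s in present}
    quota = _per_sample_quota(sizes, cfg)
    kept: list[np.ndarray] = []
    for pos, sid in enumerate(sample_order):
        if sid not in sizes:
            continue
        idx = np.flatnonzero(cell_sample == sid)
        q = quota[sid]
        if q >= len(idx):
            kept.append(idx)
        else:
            rng = np.random.default_rng((int(cfg.seed), pos))
            kept.append(np.sort(rng.choice(idx, size=q, replace=False)))
    return np.sort(np.concatenate(kept)) if kept else np.array([], dtype=int)


def downsample(exp: Experiment, cfg: DownsampleConfig):
    """Subset an experiment by seeded downsampling.

    Returns ``(experiment, kept_indices)``; kept indices are reported for
    provenance.
    """
    kept = select_downsample_indices(exp.cell_sample, exp.samples.ids, cfg)
    if cfg.mode == "none":
        return exp.copy(), kept
    from .core import subset_experiment

    mask = np.zeros(exp.n_cells, dtype=bool)
    mask[kept] = True
    return subset_experiment(exp, mask=mask), kept


# ---------------------------------------------------------------------------
# dataset import
# ---------------------------------------------------------------------------

def _normalise_files(files) -> list[tuple[str, Path]]:
    if isinstance(files, Mapping):
        items = [(str(k), Path(v)) for k, v in files.items()]
    else:
        items = [(str(k), Path(v)) for k, v in files]
    seen: set[str] = set()
    for sid, _ in items:
        if sid in seen:
            raise MetadataError(f"duplicate sample_id in file list: {sid!r}")
        seen.add(sid)
    return items


def _read_any(path: Path) -> RawSample:
    if path.suffix.lower() == ".csv":
        return read_cell_table(path)
    return read_fcs(path)


def import_dataset(
    files,
    panel: Panel,
    samples: SampleTable,
    transform: TransformConfig | None = None,
    downsample_cfg: DownsampleConfig | None = None,
) -> Experiment:
    """Read one file per sample, align channels to the panel, transform and
    optionally downsample.

    ``files`` maps sample_id -> FCS/CSV path (mapping or (id, path) pairs).
    Events are concatenated in sample-table order, so the result is invariant
    to the ordering of the input file list.  Per-cell provenance (source file
    and original row) is retained in ``cell_meta``.
    """
    items = dict(_normalise_files(files))
    unknown = sorted(set(items) - set(samples.ids))
    if unknown:
        raise MetadataError(
            f"files given for sample ids absent from the sample table: {unknown}"
        )

    blocks: list[np.ndarray] = []
    sample_col: list[str] = []
    meta_frames: list[pd.DataFrame] = []
    missing_report: dict[str, list[str]] = {}
    for sid in samples.ids:  # canonical order
        if sid not in items:
            continue
        raw = _read_any(items[sid])
        missing = [c for c in panel.channel_ids if c not in raw.channel_ids]
        if missing:
            missing_report[sid] = missing
            continue
        cols = [raw.channel_ids.index(c) for c in panel.channel_ids]
        blocks.append(raw.data[:, cols])
        sample_col.extend([sid] * raw.n_events)
        meta = pd.DataFrame(
            {
                "source_file": str(items[sid]),
                "source_row": np.arange(raw.n_events),
            }
        )
        if raw.cell_meta is not None:
            meta = pd.concat([meta, raw.cell_meta.reset_index(drop=True)], axis=1)
        meta_frames.append(meta)
    if missing_report:
        lines = "; ".join(f"{sid}: missing {m}" for sid, m in missing_report.items())
        raise MetadataError(f"panel channels absent from input files — {lines}")
    if not blocks:
        raise MetadataError("no input files matched the sample table")

    raw_matrix = np.vstack(blocks)
    cell_meta = pd.concat(meta_frames, ignore_index=True)
    exp = build_experiment(raw_matrix, sample_col, panel, samples, cell_meta)
    if transform is not None:
        apply_transform(exp, transform)
    if downsample_cfg is not None and downsample_cfg.mode != "none":
        exp, _ = downsample(exp, downsample_cfg)
    return exp
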