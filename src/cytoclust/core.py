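"""Central data model: panel, sample table, cluster assignments and the
experiment container.

The :class:`Experiment` holds a raw and a transformed cell × channel matrix,
a per-cell sample map, panel and sample metadata, plus named layers added by
later pipeline stages (2-D reductions, clusterings, text cell labels).  Cells
are rows; channels/markers are columns.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConfigurationError,
    EmptySelectionError,
    MetadataError,
    StateError,
)

ROLES = ("lineage", "functional", "none")

PANEL_COLUMNS = ("channel_id", "marker_name", "role", "use_clustering", "use_reduction")


class Panel:
    """Per-channel marker metadata with use-flags.

    Parameters
    ----------
    table:
        DataFrame with columns ``channel_id``, ``marker_name``, ``role``
        (one of ``lineage``/``functional``/``none``), ``use_clustering`` and
        ``use_reduction`` (booleans).  Missing flag/role columns get
        permissive defaults (role ``none``, both flags true).
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "channel_id" not in table.columns:
            raise MetadataError("panel table requires a 'channel_id' column")
        if "marker_name" not in table.columns:
            table["marker_name"] = table["channel_id"]
        if "role" not in table.columns:
            table["role"] = "none"
        for flag in ("use_clustering", "use_reduction"):
            if flag not in table.columns:
                table[flag] = True
            table[flag] = table[flag].astype(bool)
        table["channel_id"] = table["channel_id"].astype(str)
        table["marker_name"] = table["marker_name"].astype(str)
        ids = table["channel_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise MetadataError(f"duplicate channel_id values in panel: {dupes}")
        bad_roles = set(table["role"]) - set(ROLES)
        if bad_roles:
            raise MetadataError(f"unknown panel roles: {sorted(bad_roles)}")
        self.table = table.reset_index(drop=True)[list(PANEL_COLUMNS)]

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_channels(
        cls,
        channel_ids: Sequence[str],
        marker_names: Sequence[str] | None = None,
        role: str = "none",
        use_clustering: bool = True,
        use_reduction: bool = True,
    ) -> "Panel":
        df = pd.DataFrame(
            {
                "channel_id": list(channel_ids),
                "marker_name": list(marker_names or channel_ids),
                "role": role,
                "use_clustering": use_clustering,
                "use_reduction": use_reduction,
            }
        )
        return cls(df)

    @classmethod
    def from_csv(cls, path) -> "Panel":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    # -- accessors ---------------------------------------------------------
    @property
    def channel_ids(self) -> list[str]:
        return list(self.table["channel_id"])

    @property
    def marker_names(self) -> list[str]:
        return list(self.table["marker_name"])

    @property
    def n_channels(self) -> int:
        return len(self.table)

    def flagged(self, which: str) -> np.ndarray:
        """Boolean mask over channels for a use ('clustering'/'reduction'/'all')."""
        if which == "all":
            return np.ones(self.n_channels, dtype=bool)
        if which in ("clustering", "reduction"):
            return self.table[f"use_{which}"].to_numpy()
        raise ConfigurationError(
            f"unknown marker selection {which!r}; expected 'clustering', 'reduction' or 'all'"
        )

    def index_of(self, marker: str) -> int:
        """Column index of a marker (by marker_name, falling back to channel_id)."""
        names = self.marker_names
        if marker in names:
            return names.index(marker)
        ids = self.channel_ids
        if marker in ids:
            return ids.index(marker)
        from .errors import PanelError

        raise PanelError(f"marker {marker!r} not in panel")

    def __eq__(self, other) -> bool:
        return isinstance(other, Panel) and self.table.equals(other.table)

    def __repr__(self) -> str:
        return f"Panel({self.n_channels} channels)"


class SampleTable:
    """Sample-level metadata keyed by a unique ``sample_id`` column."""

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "sample_id" not in table.columns:
            raise MetadataError("sample table requires a 'sample_id' column")
        table["sample_id"] = table["sample_id"].astype(str)
        ids = table["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise MetadataError(f"duplicate sample_id values: {dupes}")
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "SampleTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def column(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise MetadataError(
                f"unknown sample metadata column {name!r}; "
                f"available: {[c for c in self.table.columns]}"
            )
        return self.table.set_index("sample_id")[name]

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleTable) and self.table.equals(other.table)

    def __repr__(self) -> str:
        return f"SampleTable({len(self)} samples)"


@dataclass
class ClusterAssignments:
    """Per-cell integer labels for every stored K of one clustering run.

    ``labels_by_k`` maps K (the number of metaclusters) to a 1-based integer
    label vector over cells.  ``node_of_cell`` is the SOM node index per cell
    when the run came from a SOM ensemble.
    """

    algorithm: str  # 'som_consensus' | 'graph_community' | 'kmeans'
    params: dict = field(default_factory=dict)
    labels_by_k: dict[int, np.ndarray] = field(default_factory=dict)
    node_of_cell: np.ndarray | None = None
    model: object | None = None  # SomModel / ConsensusResult, optional

    def __post_init__(self):
        for k, labels in self.labels_by_k.items():
            labels = np.asarray(labels)
            if labels.size and (labels.min() < 1 or labels.max() > k):
                raise AlignmentError(
                    f"labels for K={k} must lie in 1..{k}, got "
                    f"[{labels.min()}, {labels.max()}]"
                )
            self.labels_by_k[k] = labels

    @property
    def ks(self) -> list[int]:
        return sorted(self.labels_by_k)

    def labels(self, k: int) -> np.ndarray:
        if k not in self.labels_by_k:
            raise StateError(f"no labels stored for K={k}; stored K: {self.ks}")
        return self.labels_by_k[k]

    def subset(self, idx: np.ndarray) -> "ClusterAssignments":
        return ClusterAssignments(
            algorithm=self.algorithm,
            params=dict(self.params),
            labels_by_k={k: v[idx] for k, v in self.labels_by_k.items()},
            node_of_cell=None if self.node_of_cell is None else self.node_of_cell[idx],
            model=self.model,
        )


class Experiment:
    """Container for one multi-sample cytometry experiment.

    Attributes
    ----------
    raw, transformed:
        ``(n_cells, n_channels)`` float arrays, always shape-identical.
    cell_sample:
        sample_id per cell.
    reductions:
        name -> ``(n_cells, 2)`` coordinates (NaN rows = cell not embedded).
    clusterings:
        name -> :class:`ClusterAssignments`.
    cell_labels:
        name -> per-cell text label array.
    cell_meta:
        per-cell provenance / metadata DataFrame (source file, original row,
        optional barcode, ...).
    """

    def __init__(
        self,
        raw: np.ndarray,
        transformed: np.ndarray,
        cell_sample: np.ndarray,
        panel: Panel,
        samples: SampleTable,
        cell_meta: pd.DataFrame | None = None,
    ):
        self.raw = raw
        self.transformed = transformed
        self.cell_sample = cell_sample
        self.panel = panel
        self.samples = samples
        self.cell_meta = (
            cell_meta if cell_meta is not None else pd.DataFrame(index=range(len(raw)))
        )
        self.reductions: dict[str, np.ndarray] = {}
        self.clusterings: dict[str, ClusterAssignments] = {}
        self.cell_labels: dict[str, np.ndarray] = {}
        self.merge_provenance: dict[str, dict] = {}

    @property
    def n_cells(self) -> int:
        return self.raw.shape[0]

    @property
    def n_channels(self) -> int:
        return self.raw.shape[1]

    def sample_mask(self, sample_id: str) -> np.ndarray:
        return self.cell_sample == sample_id

    def add_reduction(self, name: str, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape[0] != self.n_cells:
            raise AlignmentError(
                f"reduction {name!r} has {coords.shape[0]} rows for {self.n_cells} cells"
            )
        self.reductions[name] = coords

    def add_clustering(self, name: str, ca: ClusterAssignments) -> None:
        for k, labels in ca.labels_by_k.items():
            if len(labels) != self.n_cells:
                raise AlignmentError(
                    f"clustering {name!r} K={k} has {len(labels)} labels "
                    f"for {self.n_cells} cells"
                )
        self.clusterings[name] = ca

    def add_cell_labels(self, name: str, labels: Iterable[str]) -> None:
        labels = np.asarray(list(labels), dtype=object)
        if len(labels) != self.n_cells:
            raise AlignmentError(
                f"label layer {name!r} has {len(labels)} entries for {self.n_cells} cells"
            )
        self.cell_labels[name] = labels

    def copy(self) -> "Experiment":
        new = Experiment(
            self.raw.copy(),
            self.transformed.copy(),
            self.cell_sample.copy(),
            Panel(self.panel.table),
            SampleTable(self.samples.table),
            self.cell_meta.copy(),
        )
        new.reductions = {k: v.copy() for k, v in self.reductions.items()}
        new.clusterings = {k: copy.deepcopy(v) for k, v in self.clusterings.items()}
        new.cell_labels = {k: v.copy() for k, v in self.cell_labels.items()}
        new.merge_provenance = copy.deepcopy(self.merge_provenance)
        return new

    def __repr__(self) -> str:
        return (
            f"Experiment({self.n_cells} cells x {self.n_channels} channels, "
            f"{len(self.samples)} samples, reductions={list(self.reductions)}, "
            f"clusterings={list(self.clusterings)}, labels={list(self.cell_labels)})"
        )


def build_experiment(
    raw: np.ndarray,
    cell_sample: Sequence[str],
    panel: Panel,
    samples: SampleTable,
    cell_meta: pd.DataFrame | None = None,
) -> Experiment:
    """Assemble an :class:`Experiment`, validating alignment and metadata.

    ``transformed`` is initialised equal to ``raw``; apply a transform
    afterwards (see :mod:`cytoclust.preprocess`).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise AlignmentError(f"raw matrix must be 2-D, got {raw.ndim}-D")
    cell_sample = np.asarray([str(s) for s in cell_sample], dtype=object)
    if len(cell_sample) != raw.shape[0]:
        raise AlignmentError(
            f"cell_sample has {len(cell_sample)} entries but raw has "
            f"{raw.shape[0]} rows (cells)"
        )
    if raw.shape[1] != panel.n_channels:
        raise AlignmentError(
            f"raw has {raw.shape[1]} columns (channels) but panel describes "
            f"{panel.n_channels}"
        )
    unknown = sorted(set(cell_sample) - set(samples.ids))
    if unknown:
        raise MetadataError(
            f"cell_sample contains ids absent from the sample table: {unknown}; "
            f"known ids: {samples.ids}"
        )
    if cell_meta is not None and len(cell_meta) != raw.shape[0]:
        raise AlignmentError(
            f"cell_meta has {len(cell_meta)} rows for {raw.shape[0]} cells"
        )
    return Experiment(raw, raw.copy(), cell_sample, panel, samples, cell_meta)


def subset_experiment(
    exp: Experiment,
    mask: Sequence[bool] | None = None,
    sample_ids: Sequence[str] | None = None,
    labels: Sequence[str] | None = None,
    labels_layer: str | None = None,
) -> Experiment:
    """Return a new experiment restricted to the selected cells.

    Exactly one of ``mask``, ``sample_ids`` or ``labels`` selects cells; all
    per-cell layers are subset consistently while panel and sample metadata
    are retained in full.
    """
    given = sum(x is not None for x in (mask, sample_ids, labels))
    if given != 1:
        raise ValueError("provide exactly one of mask, sample_ids or labels")

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != exp.n_cells:
            raise AlignmentError(
                f"mask has {len(mask)} entries for {exp.n_cells} cells"
            )
    elif sample_ids is not None:
        wanted = set(str(s) for s in sample_ids)
        unknown = sorted(wanted - set(exp.samples.ids))
        if unknown:
            raise MetadataError(f"unknown sample ids: {unknown}")
        mask = np.isin(exp.cell_sample.astype(str), list(wanted))
    else:
        if not exp.cell_labels:
            raise StateError("no cell_labels layer to select labels from")
        layer = labels_layer or next(iter(exp.cell_labels))
        if layer not in exp.cell_labels:
            raise StateError(f"no cell_labels layer named {layer!r}")
        mask = np.isin(exp.cell_labels[layer], list(labels))

    if not mask.any():
        raise EmptySelectionError("selection matched zero cells")

    idx = np.flatnonzero(mask)
    new = Experiment(
        exp.raw[idx],
        exp.transformed[idx],
        exp.cell_sample[idx],
        Panel(exp.panel.table),
        SampleTable(exp.samples.table),
        exp.cell_meta.iloc[idx].reset_index(drop=True),
    )
    new.reductions = {k: v[idx] for k, v in exp.reductions.items()}
    new.clusterings = {k: v.subset(idx) for k, v in exp.clusterings.items()}
    new.cell_labels = {k: v[idx] for k, v in exp.cell_labels.items()}
    new.merge_provenance = copy.deepcopy(exp.merge_provenance)
    return new


def marker_matrix(exp: Experiment, which: str = "all") -> tuple[np.ndarray, list[str]]:
    """Transformed expression restricted to channels flagged for a use.

    ``which`` is ``'clustering'``, ``'reduction'`` or ``'all'``.  Column order
    follows panel order.  Returns ``(matrix, marker_names)``.
    """
    flags = exp.panel.flagged(which)
    if not flags.any():
        raise ConfigurationError(
            f"no panel channels flagged for use_{which}; set the flag on at "
            "least one channel"
        )
    names = [n for n, f in zip(exp.panel.marker_names, flags) if f]
    return exp.transformed[:, flags], names
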