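"""Synthetic multi-sample cytometry datasets with known population structure
and group effects.

Populations are Gaussian in transformed (asinh) space; the raw assay is
back-computed through the inverse transform so the full import path can be
exercised end to end.  Per-sample abundances are Dirichlet draws around
group-adjusted base abundances, cell counts are multinomial, and everything
is driven by one seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Experiment, Panel, SampleTable, build_experiment
from .fcs import write_fcs


@dataclass
class PopulationSpec:
    name: str
    mean: np.ndarray  # transformed-space mean per marker
    cov_scale: float = 0.25  # isotropic variance in transformed space

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        if self.cov_scale <= 0:
            raise ValueError(f"covariance scale must be > 0 for {self.name!r}")


@dataclass
class Effect:
    """A group-specific perturbation: abundance multiplier or marker shift."""

    population: str
    group: str
    abundance_multiplier: float | None = None
    marker: str | None = None
    marker_shift: float | None = None

    def __post_init__(self):
        if self.abundance_multiplier is not None and self.abundance_multiplier <= 0:
            raise ValueError(
                f"abundance multiplier must be > 0 (population {self.population!r})"
            )
        if (self.marker is None) != (self.marker_shift is None):
            raise ValueError("marker and marker_shift must be given together")


@dataclass
class SimulationSpec:
    populations: list[PopulationSpec]
    base_abundance: np.ndarray
    marker_names: list[str]
    groups: tuple[str, ...] = ("A", "B")
    n_samples_per_group: int = 8
    cells_per_sample: int = 5000
    effects: list[Effect] = field(default_factory=list)
    concentration: float = 100.0
    cofactor: float = 5.0
    seed: int = 0

    def __post_init__(self):
        self.base_abundance = np.asarray(self.base_abundance, dtype=float)
        if len(self.base_abundance) != len(self.populations):
            raise ValueError("base_abundance length must equal number of populations")
        if abs(self.base_abundance.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"base_abundance must sum to 1, got {self.base_abundance.sum()!r}"
            )
        if (self.base_abundance <= 0).any():
            raise ValueError("base_abundance entries must be positive")
        if self.concentration <= 0:
            raise ValueError("dirichlet concentration must be > 0")
        dims = {len(p.mean) for p in self.populations}
        if dims != {len(self.marker_names)}:
            raise ValueError(
                f"population mean dimensions {dims} do not match "
                f"{len(self.marker_names)} marker_names"
            )
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        for e in self.effects:
            if e.population not in names:
                raise ValueError(f"effect references unknown population {e.population!r}")
            if e.group not in self.groups:
                raise ValueError(f"effect references unknown group {e.group!r}")

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def to_yaml(self, path) -> None:
        import yaml

        doc = {
            "populations": [
                {"name": p.name, "mean": p.mean.tolist(), "cov_scale": p.cov_scale}
                for p in self.populations
            ],
            "base_abundance": self.base_abundance.tolist(),
            "marker_names": list(self.marker_names),
            "groups": list(self.groups),
            "n_samples_per_group": self.n_samples_per_group,
            "cells_per_sample": self.cells_per_sample,
            "effects": [
                {
                    "population": e.population,
                    "group": e.group,
                    "abundance_multiplier": e.abundance_multiplier,
                    "marker": e.marker,
                    "marker_shift": e.marker_shift,
                }
                for e in self.effects
            ],
            "concentration": self.concentration,
            "cofactor": self.cofactor,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            populations=[
                PopulationSpec(d["name"], np.asarray(d["mean"]), d.get("cov_scale", 0.25))
                for d in doc["populations"]
            ],
            base_abundance=np.asarray(doc["base_abundance"]),
            marker_names=list(doc["marker_names"]),
            groups=tuple(doc.get("groups", ("A", "B"))),
            n_samples_per_group=int(doc.get("n_samples_per_group", 8)),
            cells_per_sample=int(doc.get("cells_per_sample", 5000)),
            effects=[Effect(**d) for d in doc.get("effects", [])],
            concentration=float(doc.get("concentration", 100.0)),
            cofactor=float(doc.get("cofactor", 5.0)),
            seed=int(doc.get("seed", 0)),
        )


def default_spec(seed: int = 0, **overrides) -> SimulationSpec:
    """The stock 8-population / 16-marker spec with one rare (1%) population
    (``P8``) that carries a 2x abundance spike in group ``A`` — the
    rare-subset monitoring scenario.

    Each population is high on its own pair of markers, giving well-separated
    Gaussian islands in transformed space.  The default Dirichlet
    concentration (1500) keeps sample-to-sample abundance noise small enough
    that the rare-population effect is recoverable with 8 samples per group;
    pass ``concentration=`` for noisier designs.
    """
    n_pops, n_markers = 8, 16
    markers = [f"M{i+1:02d}" for i in range(n_markers)]
    pops = []
    for i in range(n_pops):
        mean = np.full(n_markers, 0.3)
        mean[2 * i] = 3.0
        mean[2 * i + 1] = 3.0
        pops.append(PopulationSpec(name=f"P{i+1}", mean=mean, cov_scale=0.25))
    base = np.array([0.24, 0.20, 0.15, 0.12, 0.10, 0.09, 0.09, 0.01])
    effects = [Effect(population="P8", group="A", abundance_multiplier=2.0)]
    kwargs = dict(
        populations=pops,
        base_abundance=base,
        marker_names=markers,
        effects=effects,
        concentration=1500.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationSpec(**kwargs)


def _group_abundance(spec: SimulationSpec, group: str) -> np.ndarray:
    base = spec.base_abundance.copy()
    for e in spec.effects:
        if e.group == group and e.abundance_multiplier is not None:
            base[spec.population_names.index(e.population)] *= e.abundance_multiplier
    return base / base.sum()


def simulate_experiment(spec: SimulationSpec):
    """Generate an :class:`Experiment` plus ground truth.

    Returns ``(exp, truth)`` where ``truth`` has per-cell population labels
    (``cell_population``), the per-sample Dirichlet-true proportions
    (``sample_proportions``) and realized counts (``sample_counts``).
    """
    rng = np.random.default_rng(spec.seed)
    n_markers = len(spec.marker_names)
    pop_names = spec.population_names

    sample_ids: list[str] = []
    sample_groups: list[str] = []
    blocks: list[np.ndarray] = []
    cell_sample: list[str] = []
    cell_pop: list[str] = []
    true_props: dict[str, np.ndarray] = {}
    true_counts: dict[str, np.ndarray] = {}

    for group in spec.groups:
        adj = _group_abundance(spec, group)
        for j in range(spec.n_samples_per_group):
            sid = f"{group}{j+1}"
            sample_ids.append(sid)
            sample_groups.append(group)
            props = rng.dirichlet(spec.concentration * adj)
            counts = rng.multinomial(spec.cells_per_sample, props)
            true_props[sid] = props
            true_counts[sid] = counts
            for pi, pop in enumerate(spec.populations):
                c = int(counts[pi])
                if c == 0:
                    continue
                mean = pop.mean.copy()
                for e in spec.effects:
                    if (
                        e.group == group
                        and e.population == pop.name
                        and e.marker is not None
                    ):
                        mean[spec.marker_names.index(e.marker)] += e.marker_shift
                x = mean + rng.normal(0.0, np.sqrt(pop.cov_scale), size=(c, n_markers))
                blocks.append(x)
                cell_sample.extend([sid] * c)
                cell_pop.extend([pop.name] * c)

    transformed = np.vstack(blocks)
    raw = spec.cofactor * np.sinh(transformed)

    panel = Panel.from_channels(spec.marker_names, role="lineage")
    samples = SampleTable(pd.DataFrame({"sample_id": sample_ids, "group": sample_groups}))
    exp = build_experiment(raw, cell_sample, panel, samples)
    exp.transformed = transformed
    exp.cell_meta["true_population"] = cell_pop

    truth = {
        "cell_population": np.asarray(cell_pop, dtype=object),
        "sample_proportions": pd.DataFrame.from_dict(
            true_props, orient="index", columns=pop_names
        ),
        "sample_counts": pd.DataFrame.from_dict(
            true_counts, orient="index", columns=pop_names
        ),
        "spec": spec,
    }
    return exp, truth


def write_simulation_fcs(exp: Experiment, truth: dict, out_dir) -> dict:
    """Write one FCS per sample plus panel/sample metadata CSVs and a truth
    manifest; importable via :func:`cytoclust.preprocess.import_dataset`.

    Returns a dict of written paths.  The manifest is deterministic for a
    given seed (no timestamps).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec: SimulationSpec = truth["spec"]

    fcs_paths: dict[str, str] = {}
    for sid in exp.samples.ids:
        mask = exp.sample_mask(sid)
        path = out / f"{sid}.fcs"
        write_fcs(exp.raw[mask], exp.panel.channel_ids, path, exp.panel.marker_names)
        fcs_paths[sid] = str(path)

    panel_path = out / "panel.csv"
    exp.panel.to_csv(panel_path)
    samples_path = out / "samples.csv"
    exp.samples.to_csv(samples_path)

    labels_path = out / "truth_labels.csv"
    pd.DataFrame(
        {
            "sample_id": exp.cell_sample,
            "row_in_sample": np.concatenate(
                [np.arange(int(exp.sample_mask(s).sum())) for s in exp.samples.ids]
            ),
            "population": truth["cell_population"],
        }
    ).to_csv(labels_path, index=False)

    manifest = {
        "seed": spec.seed,
        "cofactor": spec.cofactor,
        "concentration": spec.concentration,
        "groups": list(spec.groups),
        "n_samples_per_group": spec.n_samples_per_group,
        "cells_per_sample": spec.cells_per_sample,
        "populations": [
            {"name": p.name, "mean": p.mean.tolist(), "cov_scale": p.cov_scale}
            for p in spec.populations
        ],
        "base_abundance": spec.base_abundance.tolist(),
        "marker_names": list(spec.marker_names),
        "effects": [
            {
                "population": e.population,
                "group": e.group,
                "abundance_multiplier": e.abundance_multiplier,
                "marker": e.marker,
                "marker_shift": e.marker_shift,
            }
            for e in spec.effects
        ],
        "files": {sid: Path(p).name for sid, p in fcs_paths.items()},
        "sample_proportions": {
            sid: truth["sample_proportions"].loc[sid].tolist()
            for sid in exp.samples.ids
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "fcs": fcs_paths,
        "panel": str(panel_path),
        "samples": str(samples_path),
        "truth_labels": str(labels_path),
        "manifest": str(manifest_path),
    }
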