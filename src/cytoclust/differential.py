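"""Stage-3 statistics: per-sample cluster abundances, two-group differential
abundance and differential marker expression with BH-FDR.

The Wilcoxon rank-sum test enumerates the exact null distribution for small
tie-free inputs (combined n <= 20) and otherwise uses the tie- and
continuity-corrected normal approximation.  The rank-sum and step-up FDR
primitives are implemented directly (they are contract-tested against brute
force); only distribution functions come from scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Experiment, SampleTable
from .errors import DegenerateDataError, DesignError


@dataclass
class AbundanceTable:
    """Per-sample cluster composition: proportions plus the paired counts."""

    proportions: pd.DataFrame  # samples x populations, rows sum to 1
    counts: pd.DataFrame  # same shape, nonnegative integers

    @property
    def populations(self) -> list:
        return list(self.proportions.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.index)


def cluster_abundances(exp: Experiment, labels) -> AbundanceTable:
    """Count and proportion of each population per sample.

    ``labels`` is a cell-label layer name, a clustering spec ``(name, K)``,
    or an explicit per-cell array.  Populations absent from a sample get
    proportion 0 (not missing); samples with zero cells are excluded with a
    warning.
    """
    if isinstance(labels, str):
        lab = exp.cell_labels.get(labels)
        if lab is None:
            from .errors import StateError

            raise StateError(f"no cell_labels layer named {labels!r}")
    elif isinstance(labels, tuple) and len(labels) == 2:
        name, k = labels
        lab = exp.clusterings[name].labels(k)
    else:
        lab = np.asarray(labels)
        if len(lab) != exp.n_cells:
            from .errors import AlignmentError

            raise AlignmentError(
                f"labels cover {len(lab)} cells, experiment has {exp.n_cells}"
            )

    pops = sorted(pd.unique(pd.Series(lab)).tolist(), key=lambda v: (str(type(v)), v))
    counts = {}
    empty = []
    for sid in exp.samples.ids:
        mask = exp.sample_mask(sid)
        if not mask.any():
            empty.append(sid)
            continue
        sub = pd.Series(lab[mask])
        counts[sid] = [int((sub == p).sum()) for p in pops]
    if empty:
        warnings.warn(f"samples with zero cells excluded: {empty}", stacklevel=2)
    counts_df = pd.DataFrame.from_dict(counts, orient="index", columns=pops)
    props = counts_df.div(counts_df.sum(axis=1), axis=0)
    return AbundanceTable(proportions=props, counts=counts_df)


# ---------------------------------------------------------------------------
# test primitives
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Returns ``(W, p)`` where W is the rank sum of ``x`` in the pooled
    ranking.  Exact enumeration of all rank splits when the pooled sample
    has no ties and n_x + n_y <= 20; otherwise a normal approximation with
    tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError(f"each group needs >= 2 values, got {nx} and {ny}")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:nx].sum())
    n = nx + ny
    has_ties = len(np.unique(pooled)) < n

    if not has_ties and n <= 20:
        # exact: W ranges over sums of nx-subsets of {1..n}
        target = int(round(w))
        le = ge = total = 0
        for comb in combinations(range(1, n + 1), nx):
            s = sum(comb)
            total += 1
            if s <= target:
                le += 1
            if s >= target:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return w, p

    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0
    diff = w - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns ``(t, df, two-sided p)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError(f"each group needs >= 2 values, got {nx} and {ny}")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(nx + ny - 2), 1.0
        raise DegenerateDataError(
            "both groups have zero variance but different means; t is undefined"
        )
    sx, sy = vx / nx, vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx**2 / (nx - 1) + sy**2 / (ny - 1))
    p = float(min(1.0, 2.0 * sps.t.sf(abs(t), df)))
    return float(t), float(df), p


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def _contrast_samples(samples: SampleTable, grouping: str, contrast) -> tuple[list, list]:
    level_a, level_b = contrast
    col = samples.column(grouping)
    a = [s for s in samples.ids if col[s] == level_a]
    b = [s for s in samples.ids if col[s] == level_b]
    if len(a) < 2 or len(b) < 2:
        raise DesignError(
            f"each contrast level needs >= 2 samples; {level_a!r} has {len(a)}, "
            f"{level_b!r} has {len(b)}"
        )
    return a, b


def _log2fc(mean_a: float, mean_b: float, floor: float) -> tuple[float, bool]:
    pseudo_used = False
    a, b = mean_a, mean_b
    if a == 0 or b == 0:
        if a == b:
            return 0.0, False
        a, b = a + floor, b + floor
        pseudo_used = True
    return float(np.log2(a / b)), pseudo_used


def stat_test_clust(
    ab: AbundanceTable,
    samples: SampleTable,
    grouping: str,
    contrast,
    test: str = "wilcox",
) -> pd.DataFrame:
    """Differential abundance between two groups, per population.

    Tests per-sample proportions (first contrast level minus/over second;
    positive log2FC means higher in the first level).  BH-FDR is applied
    across populations.  ``test`` is ``'wilcox'`` or ``'ttest'``.
    """
    if test not in ("wilcox", "ttest"):
        raise ValueError(f"unknown test {test!r}")
    ids_a, ids_b = _contrast_samples(samples, grouping, contrast)
    ids_a = [s for s in ids_a if s in ab.proportions.index]
    ids_b = [s for s in ids_b if s in ab.proportions.index]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise DesignError("fewer than 2 samples with cells in a contrast level")

    positive = ab.proportions.to_numpy()
    positive = positive[positive > 0]
    floor = 0.5 * float(positive.min()) if positive.size else 0.5

    rows = []
    for pop in ab.populations:
        xa = ab.proportions.loc[ids_a, pop].to_numpy(dtype=float)
        xb = ab.proportions.loc[ids_b, pop].to_numpy(dtype=float)
        ma, mb = float(xa.mean()), float(xb.mean())
        lfc, pseudo = _log2fc(ma, mb, floor)
        if test == "wilcox":
            stat, p = wilcoxon_rank_sum(xa, xb)
        else:
            try:
                t, _, p = welch_t(xa, xb)
            except DegenerateDataError:
                t, p = 0.0, 1.0
            stat = t
        rows.append(
            {
                "population": pop,
                "mean_a": ma,
                "mean_b": mb,
                "log2fc": lfc,
                "pseudo_used": pseudo,
                "stat": stat,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["test"] = "wilcoxon_rank_sum" if test == "wilcox" else "welch_t"
    return out


def stat_test_expression(
    exp: Experiment,
    labels,
    markers,
    samples: SampleTable,
    grouping: str,
    contrast,
    test: str = "wilcox",
) -> pd.DataFrame:
    """Differential marker expression within populations, between two groups.

    The per-sample summary is the median transformed expression of the
    marker over that sample's cells in the population; samples lacking the
    population are omitted for it (>= 2 per group still required, else the
    pair is dropped with a warning).  BH-FDR is applied jointly across all
    (population, marker) pairs.
    """
    if test not in ("wilcox", "ttest"):
        raise ValueError(f"unknown test {test!r}")
    if isinstance(labels, str):
        lab = exp.cell_labels[labels]
    elif isinstance(labels, tuple):
        lab = exp.clusterings[labels[0]].labels(labels[1])
    else:
        lab = np.asarray(labels)
    ids_a, ids_b = _contrast_samples(samples, grouping, contrast)
    marker_idx = {m: exp.panel.index_of(m) for m in markers}
    pops = sorted(pd.unique(pd.Series(lab)).tolist(), key=lambda v: (str(type(v)), v))

    rows = []
    dropped = []
    for pop in pops:
        pop_mask = lab == pop
        for m, mi in marker_idx.items():
            per_sample = {}
            for sid in ids_a + ids_b:
                cmask = pop_mask & exp.sample_mask(sid)
                if cmask.any():
                    per_sample[sid] = float(np.median(exp.transformed[cmask, mi]))
            xa = np.array([per_sample[s] for s in ids_a if s in per_sample])
            xb = np.array([per_sample[s] for s in ids_b if s in per_sample])
            if len(xa) < 2 or len(xb) < 2:
                dropped.append((pop, m))
                continue
            if test == "wilcox":
                stat, p = wilcoxon_rank_sum(xa, xb)
            else:
                try:
                    stat, _, p = welch_t(xa, xb)
                except DegenerateDataError:
                    stat, p = 0.0, 1.0
            rows.append(
                {
                    "population": pop,
                    "marker": m,
                    "mean_a": float(xa.mean()),
                    "mean_b": float(xb.mean()),
                    "diff": float(xa.mean() - xb.mean()),
                    "stat": stat,
                    "p": p,
                }
            )
    if dropped:
        warnings.warn(
            f"{len(dropped)} (population, marker) pairs dropped for <2 samples "
            "per group",
            stacklevel=2,
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["test"] = "wilcoxon_rank_sum" if test == "wilcox" else "welch_t"
    return out


def export_for_differential_tools(exp: Experiment, labels, out_dir) -> dict:
    """Write per-cell labels and per-sample metadata for external
    differential-discovery packages.

    Emits ``cells.csv`` (cell index, sample, population label) and
    ``samples.csv`` (the sample metadata table); returns the paths.
    """
    from pathlib import Path

    if isinstance(labels, str):
        lab = exp.cell_labels[labels]
    elif isinstance(labels, tuple):
        lab = exp.clusterings[labels[0]].labels(labels[1])
    else:
        lab = np.asarray(labels)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells_path = out / "cells.csv"
    pd.DataFrame(
        {"cell": np.arange(exp.n_cells), "sample_id": exp.cell_sample, "population": lab}
    ).to_csv(cells_path, index=False)
    samples_path = out / "samples.csv"
    exp.samples.to_csv(samples_path)
    return {"cells": str(cells_path), "samples": str(samples_path)}


def volcano_data(dr: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Volcano-plot table: effect, -log10 FDR and a strict-inequality flag."""
    if dr is None or len(dr) == 0:
        raise ValueError("empty differential result")
    effect_col = "log2fc" if "log2fc" in dr.columns else "diff"
    out = dr.copy()
    out["neg_log10_fdr"] = -np.log10(np.clip(out["fdr"].to_numpy(dtype=float), 1e-300, 1.0))
    out["significant"] = out["fdr"].to_numpy(dtype=float) < fdr_threshold
    out["effect"] = out[effect_col]
    return out
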