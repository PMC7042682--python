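"""Parameter-grid scans: where is fitness-dependent recombination favored?

For every cell of a selection-parameter grid (s, h, epistasis components,
interference, modifier linkage) the scan locates the optimal constant
recombination rate and then pits FD strategies against it: the +FD strategy
``(0, delta)`` when the optimum is zero, and the requested variants
(+FD / -FD / +-FD / distant) when it is intermediate.  Summaries report the
proportion of cells in which FD recombination is favored, conditioned on the
optimum class and grouped by (s, |e_axa|, h) for heatmap-style exports.

Everything is deterministic, so scans are bit-reproducible; an optional
JSON-lines cache makes long scans restartable.
"""

from __future__ import annotations

import json
import sys
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .experiments import (
    FD_VARIANTS,
    compare_fd_vs_optimal,
    optimal_constant_rr,
)
from .genetics import (
    FitnessParams,
    SystemConfig,
    R_MA_LINKED,
    R_MA_UNLINKED,
    fitness_from_counts,
)

__all__ = ["ScanGrid", "ScanSummary", "run_scan", "summarize",
           "export_heatmap_table", "in_msb_regime"]

#: default plastic-effect magnitude Delta = r_max - r_min
DEFAULT_DELTA = 0.05

_FULL_S = (0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
_FULL_H = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
_FULL_E_AXA = tuple(round(-1.0 + 0.1 * k, 1) for k in range(21))
_COARSE_E = (-1.0, -0.5, 0.0, 0.5, 1.0)


@dataclass
class ScanGrid:
    """Axes of a parameter scan.

    The defaults follow the headline scan design: s from nearly neutral
    (0.01) to lethal (1) in steps of 0.1, h from 0 to 1 in steps of 0.2,
    additive-by-additive epistasis from -1 to 1 in steps of 0.1 with the
    weaker components treated coarsely (e_axd in five steps, e_dxd = 0),
    no interference (c = 1), and both modifier linkages.
    """

    s_values: tuple[float, ...] = _FULL_S
    h_values: tuple[float, ...] = _FULL_H
    e_axa_values: tuple[float, ...] = _FULL_E_AXA
    e_axd_values: tuple[float, ...] = _COARSE_E
    e_dxd_values: tuple[float, ...] = (0.0,)
    c_values: tuple[float, ...] = (1.0,)
    r_ma_values: tuple[float, ...] = (R_MA_UNLINKED, R_MA_LINKED)
    n_selected: int = 3
    u: float = 1e-4
    delta: float = DEFAULT_DELTA
    variants: tuple[str, ...] = ("+FD", "-FD", "+-FD")

    def __post_init__(self) -> None:
        for v in self.variants:
            if v not in FD_VARIANTS:
                raise ValueError(f"unknown FD variant {v!r}")

    def reduce(self, factor: int) -> "ScanGrid":
        """Coarsen every parameter axis by an integer factor (keeps the first
        value of each axis); used for desk-scale runs of the same protocol."""
        if factor < 1:
            raise ValueError("reduction factor must be >= 1")
        thin = lambda vals: tuple(vals[::factor])
        return ScanGrid(
            s_values=thin(self.s_values), h_values=thin(self.h_values),
            e_axa_values=thin(self.e_axa_values),
            e_axd_values=thin(self.e_axd_values),
            e_dxd_values=thin(self.e_dxd_values),
            c_values=self.c_values, r_ma_values=self.r_ma_values,
            n_selected=self.n_selected, u=self.u, delta=self.delta,
            variants=self.variants)

    def cells(self) -> Iterable[tuple[FitnessParams, SystemConfig]]:
        for r_ma in self.r_ma_values:
            for c in self.c_values:
                config = SystemConfig(n_selected=self.n_selected, r_ma=r_ma,
                                      u=self.u, c=c)
                for s in self.s_values:
                    for h in self.h_values:
                        for ea in self.e_axa_values:
                            for ed in self.e_axd_values:
                                for edd in self.e_dxd_values:
                                    yield (FitnessParams(s=s, h=h, e_axa=ea,
                                                         e_axd=ed, e_dxd=edd),
                                           config)

    @property
    def n_cells(self) -> int:
        return (len(self.s_values) * len(self.h_values) * len(self.e_axa_values)
                * len(self.e_axd_values) * len(self.e_dxd_values)
                * len(self.c_values) * len(self.r_ma_values))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGrid":
        kw = {k: (tuple(v) if isinstance(v, (list, tuple)) else v)
              for k, v in d.items()}
        return cls(**kw)


def in_msb_regime(params: FitnessParams, n_selected: int = 3) -> bool:
    """True when every genotype class is at most as fit as the wild type.

    Strong epistasis can invert the deleterious effect (e.g. a multi-mutant
    homozygote fitter than wild type), in which case mutant alleles sweep and
    the population leaves mutation-selection balance; such cells are flagged
    so summaries can condition on the regime the model is meant for.
    """
    for n_he in range(n_selected + 1):
        for n_ho in range(n_selected - n_he + 1):
            if fitness_from_counts(n_he, n_ho, params) > 1.0 + 1e-12:
                return False
    return True


def _cell_key(params: FitnessParams, config: SystemConfig) -> str:
    d = {**params.to_dict(), **config.to_dict()}
    return json.dumps({k: d[k] for k in sorted(d)})


def run_scan(grid: ScanGrid, cache_path: str | Path | None = None,
             generations: int = 10_000, max_generations: int = 10 ** 6,
             progress: bool = False) -> pd.DataFrame:
    """Run the grid scan; one output row per cell x applicable variant.

    The expensive optimal-rate search is performed once per cell and shared
    by all variants.  With ``cache_path`` set, finished rows are appended as
    JSON lines and skipped on restart.  Per-cell failures are recorded in the
    ``error`` column and the scan continues.
    """
    cache: dict[str, list[dict]] = {}
    cache_file = None
    if cache_path is not None:
        cache_path = Path(cache_path)
        if cache_path.exists():
            with open(cache_path) as fh:
                for line in fh:
                    rec = json.loads(line)
                    cache.setdefault(rec["cell_key"], []).append(rec)
        cache_file = open(cache_path, "a")

    rows: list[dict] = []
    try:
        for idx, (params, config) in enumerate(grid.cells()):
            key = _cell_key(params, config)
            if key in cache:
                rows.extend(cache[key])
                continue
            t0 = time.time()
            cell_rows = _scan_cell(params, config, grid, key, generations,
                                   max_generations)
            rows.extend(cell_rows)
            if cache_file is not None:
                for rec in cell_rows:
                    cache_file.write(json.dumps(rec) + "\n")
                cache_file.flush()
            if progress:
                print(f"[{idx + 1}/{grid.n_cells}] s={params.s} h={params.h} "
                      f"e_axa={params.e_axa} r_MA={config.r_ma} "
                      f"-> {cell_rows[0]['classification']} "
                      f"({time.time() - t0:.1f}s)", file=sys.stderr)
    finally:
        if cache_file is not None:
            cache_file.close()
    return pd.DataFrame(rows)


def _scan_cell(params: FitnessParams, config: SystemConfig, grid: ScanGrid,
               key: str, generations: int, max_generations: int) -> list[dict]:
    base = {**params.to_dict(), **config.to_dict(),
            "delta": grid.delta, "cell_key": key,
            "msb_regime": in_msb_regime(params, config.n_selected),
            "error": ""}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            opt = optimal_constant_rr(params, config, generations=generations,
                                      max_generations=max_generations)
    except Exception as exc:  # pragma: no cover - defensive
        return [{**base, "classification": "error", "variant": "",
                 "error": f"{type(exc).__name__}: {exc}"}]
    base.update(r_low=opt.r_low, r_high=opt.r_high, r_star=opt.r_star,
                classification=opt.classification,
                n_invasion_tests=opt.n_invasion_tests,
                equilibria_converged=opt.equilibria_converged)
    if opt.classification == "free":
        return [{**base, "variant": ""}]
    variants = ("+FD",) if opt.classification == "zero" else grid.variants
    out = []
    for variant in variants:
        row = dict(base)
        row["variant"] = variant
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmp = compare_fd_vs_optimal(
                    params, config, delta=grid.delta, variant=variant,
                    r_star=opt.r_star, generations=generations,
                    max_generations=max_generations)
            row.update(fd_invades=cmp.s1_invades, fd_resists=cmp.s1_resists,
                       fd_favored=cmp.advantageous,
                       delta_mean_fitness=cmp.delta_mean_fitness,
                       delta_variation=cmp.delta_variation,
                       delta_mean_rs=cmp.delta_mean_rs,
                       rates_clipped=cmp.rates_clipped)
        except Exception as exc:  # pragma: no cover - defensive
            row["error"] = f"{type(exc).__name__}: {exc}"
        out.append(row)
    return out


@dataclass
class ScanSummary:
    """Aggregated scan outcome: counts and FD-favored proportions."""

    n_cells: int
    n_zero_optimal: int
    n_intermediate_optimal: int
    n_free: int
    #: among zero-optimal cells: +FD favored over constant 0
    zero_fd_favored: int
    zero_fd_proportion: float
    #: among intermediate-optimal cells, per variant
    intermediate_favored: dict[str, int] = field(default_factory=dict)
    intermediate_proportion: dict[str, float] = field(default_factory=dict)
    #: long-format per-(s, |e_axa|, h) table for heatmaps (zero-optimal cells)
    heatmap: pd.DataFrame | None = None
    #: the conditioning axes of the scan this summary came from
    grid_note: str = ""


def summarize(results: pd.DataFrame, grid_note: str = "") -> ScanSummary:
    """Aggregate a scan result table into headline proportions.

    Proportions follow the reporting convention of the study design: among
    cells with a *zero* optimal constant rate, the fraction where the +FD
    strategy is favored; among cells with an *intermediate* optimum, the
    per-variant fractions.
    """
    if len(results) == 0:
        return ScanSummary(0, 0, 0, 0, 0, float("nan"), {}, {}, None, grid_note)
    cells = results.drop_duplicates("cell_key")
    n_cells = len(cells)
    n_free = int((cells["classification"] == "free").sum())
    zero = results[(results["classification"] == "zero")
                   & (results["variant"] == "+FD")]
    inter = results[results["classification"] == "intermediate"]
    n_zero = len(zero)
    n_inter = inter["cell_key"].nunique()
    zero_fav = int(zero["fd_favored"].sum()) if n_zero else 0
    inter_fav, inter_prop = {}, {}
    for variant, sub in inter.groupby("variant"):
        inter_fav[variant] = int(sub["fd_favored"].sum())
        inter_prop[variant] = inter_fav[variant] / len(sub)
    heat = None
    if n_zero:
        z = zero.copy()
        z["abs_e_axa"] = z["e_axa"].abs()
        heat = (z.groupby(["s", "abs_e_axa", "h"], as_index=False)
                .agg(n=("fd_favored", "size"),
                     n_favored=("fd_favored", "sum")))
        heat["proportion"] = heat["n_favored"] / heat["n"]
        heat = heat[["s", "abs_e_axa", "h", "proportion", "n"]]
    return ScanSummary(
        n_cells=n_cells, n_zero_optimal=n_zero,
        n_intermediate_optimal=n_inter, n_free=n_free,
        zero_fd_favored=zero_fav,
        zero_fd_proportion=zero_fav / n_zero if n_zero else float("nan"),
        intermediate_favored=inter_fav, intermediate_proportion=inter_prop,
        heatmap=heat, grid_note=grid_note)


def export_heatmap_table(summary: ScanSummary, path: str | Path) -> Path:
    """Write the (s, |e_axa|, h, proportion, n) long-format heatmap CSV."""
    path = Path(path)
    heat = summary.heatmap
    if heat is None:
        heat = pd.DataFrame(columns=["s", "abs_e_axa", "h", "proportion", "n"])
    heat.to_csv(path, index=False)
    return path
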