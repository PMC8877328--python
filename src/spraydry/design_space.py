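"""Feasible operating region and design space of the dryer.

The atomizing experiments bound the evaporation capability of the
equipment: at each inlet-temperature level they give the maximum feed rate
at the maximum and minimum aspirator flow, plus a global minimum feed rate.
Piecewise-linear interpolation between levels (and least-squares
extrapolation below the lowest level, down to the apex where the feasible
feed interval collapses) turns those limits into a 3-D operating region
over (Tin, FR, Gin).  Meshing the region and assigning the model's outlet
temperature to every node yields the design space; constant-Tin and
constant-Tout sections are the 2-D views used to read it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .energy_balance import BalanceOptions, DEFAULT_OPTIONS, DryerGeometry
from .tout_solver import DEFAULT_SETTINGS, SolverSettings, solve_tout_vec
from .wall_surrogate import FEATURES, WallSurrogate

__all__ = [
    "OperatingRegion",
    "DesignSpaceGrid",
    "build_region",
    "region_apex",
    "mesh_region",
    "assign_tout",
    "section",
    "fr_vs_ad_dominance",
    "iso_tout_tradeoff",
]

log = logging.getLogger(__name__)

LEVEL_COLUMNS = ("Tin", "gin_min", "gin_max", "fr_max_at_gin_min", "fr_max_at_gin_max")


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


@dataclass(frozen=True)
class OperatingRegion:
    """Per-level processing limits with interpolation rules.

    ``levels`` holds one row per inlet-temperature level with the Gin
    bounds and the maximum feasible FR at each bound; ``fr_min`` is the
    global minimum feed rate the pump can deliver.
    """

    levels: pd.DataFrame
    fr_min: float = 0.07

    def __post_init__(self) -> None:
        lv = self.levels
        missing = [c for c in LEVEL_COLUMNS if c not in lv.columns]
        if missing:
            raise ValueError(f"levels table missing columns: {missing}")
        if lv["Tin"].duplicated().any():
            raise ValueError("duplicate Tin levels")
        if not lv["Tin"].is_monotonic_increasing:
            raise ValueError("Tin levels must be sorted ascending")
        if len(lv) < 1:
            raise ValueError("need at least 1 Tin level")
        if (lv["fr_max_at_gin_max"] < lv["fr_max_at_gin_min"] - 1e-12).any():
            raise ValueError("fr_max_at_gin_max must be >= fr_max_at_gin_min at every level")
        if (lv[["fr_max_at_gin_min", "fr_max_at_gin_max"]].min(axis=1) < self.fr_min - 1e-12).any():
            raise ValueError("fr_min exceeds a level's maximum FR")

    @property
    def tin_low(self) -> float:
        return float(self.levels["Tin"].iloc[0])

    @property
    def tin_high(self) -> float:
        return float(self.levels["Tin"].iloc[-1])

    def _column(self, name: str, Tin) -> np.ndarray:
        """Piecewise-linear within the levels; OLS line below the lowest one."""
        Tin = np.asarray(Tin, dtype=float)
        x = self.levels["Tin"].to_numpy(dtype=float)
        y = self.levels[name].to_numpy(dtype=float)
        out = np.interp(Tin, x, y)
        below = Tin < self.tin_low
        if np.any(below) and len(x) >= 2:
            slope, intercept = _ols_line(x, y)
            out = np.where(below, slope * Tin + intercept, out)
        return out

    def tin_floor(self) -> float:
        """Lowest admissible Tin: the apex when the FR limits collapse, else
        the lowest measured level."""
        try:
            return region_apex(self)
        except ValueError:
            return self.tin_low

    def gin_bounds(self, Tin) -> tuple[np.ndarray, np.ndarray]:
        return self._column("gin_min", Tin), self._column("gin_max", Tin)

    def fr_max(self, Tin, Gin) -> np.ndarray:
        """Maximum feasible feed rate at (Tin, Gin).

        Linear in Gin between the two measured FR-limit anchors (clamped
        outside them); the anchors sit at the flows the limits were actually
        measured at, which may differ slightly from the level's extreme
        flows.
        """
        Tin = np.asarray(Tin, dtype=float)
        Gin = np.asarray(Gin, dtype=float)
        g_lo = self._column(self._anchor_lo, Tin)
        g_hi = self._column(self._anchor_hi, Tin)
        f_lo = self._column("fr_max_at_gin_min", Tin)
        f_hi = self._column("fr_max_at_gin_max", Tin)
        frac = np.clip((Gin - g_lo) / np.where(g_hi > g_lo, g_hi - g_lo, 1.0), 0.0, 1.0)
        return f_lo + frac * (f_hi - f_lo)

    @property
    def _anchor_lo(self) -> str:
        return "gin_anchor_min" if "gin_anchor_min" in self.levels.columns else "gin_min"

    @property
    def _anchor_hi(self) -> str:
        return "gin_anchor_max" if "gin_anchor_max" in self.levels.columns else "gin_max"

    def contains(self, Tin, FR, Gin, tol: float = 1e-9) -> np.ndarray:
        Tin = np.asarray(Tin, dtype=float)
        FR = np.asarray(FR, dtype=float)
        Gin = np.asarray(Gin, dtype=float)
        g_lo, g_hi = self.gin_bounds(Tin)
        inside = (Tin <= self.tin_high + tol) & (Tin >= self.tin_floor() - tol)
        inside &= (Gin >= g_lo - tol) & (Gin <= g_hi + tol)
        inside &= (FR >= self.fr_min - tol) & (FR <= self.fr_max(Tin, Gin) + tol)
        return inside


def build_region(limits, fr_min: float = 0.07) -> OperatingRegion:
    """Build the operating region from a limits table.

    ``limits`` is either a per-level table with columns
    ``(Tin, gin_min, gin_max, fr_max_at_gin_min, fr_max_at_gin_max)`` or a
    raw runs table with columns ``(Tin, FR, Gin)`` (e.g. the atomizing
    fixture), which is aggregated per Tin level: the Gin bounds are the
    level's extreme flows, and the FR limit at each bound is the largest
    feed rate observed in the corresponding half of the flow range.
    """
    df = pd.DataFrame(limits)
    if len(df) < 2:
        raise ValueError("need at least 2 Tin levels to build a region")
    if set(LEVEL_COLUMNS) <= set(df.columns):
        levels = df[list(LEVEL_COLUMNS)].sort_values("Tin").reset_index(drop=True)
        return OperatingRegion(levels=levels, fr_min=fr_min)
    if not {"Tin", "FR", "Gin"} <= set(df.columns):
        raise ValueError("limits must carry either level columns or (Tin, FR, Gin)")
    rows = []
    for tin, grp in df.groupby("Tin"):
        g_lo, g_hi = grp["Gin"].min(), grp["Gin"].max()
        mid = 0.5 * (g_lo + g_hi)
        high, low = grp[grp["Gin"] > mid], grp[grp["Gin"] <= mid]
        hi_lim = high.loc[high["FR"].idxmax()]
        lo_lim = low.loc[low["FR"].idxmax()]
        rows.append(
            {
                "Tin": float(tin),
                "gin_min": float(g_lo),
                "gin_max": float(g_hi),
                "fr_max_at_gin_min": float(lo_lim["FR"]),
                "fr_max_at_gin_max": float(hi_lim["FR"]),
                "gin_anchor_min": float(lo_lim["Gin"]),
                "gin_anchor_max": float(hi_lim["Gin"]),
            }
        )
    levels = pd.DataFrame(rows).sort_values("Tin").reset_index(drop=True)
    return OperatingRegion(levels=levels, fr_min=fr_min)


def region_apex(region: OperatingRegion) -> float:
    """Inlet temperature at which the feasible FR interval collapses to fr_min.

    An ordinary least-squares line through the per-level FR limits at the
    maximum-Gin bound is extrapolated down to fr_min.  The value is
    extrapolation-method-dependent and should be read qualitatively.
    """
    x = region.levels["Tin"].to_numpy(dtype=float)
    y = region.levels["fr_max_at_gin_max"].to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("apex extrapolation needs at least 2 Tin levels")
    slope, intercept = _ols_line(x, y)
    if slope <= 0:
        raise ValueError("FR limits do not collapse towards lower Tin; no apex")
    return (region.fr_min - intercept) / slope


@dataclass
class DesignSpaceGrid:
    """Meshed operating region, optionally with Tout assigned at every node.

    ``nodes`` has one row per mesh node with columns
    (Tin, FR, Gin, AD[, Textwall, Tout, converged, iterations]); the lattice
    vectors record the structured mesh the nodes were drawn from.
    """

    nodes: pd.DataFrame
    region: OperatingRegion
    tin_levels: np.ndarray
    fr_values: np.ndarray
    gin_values: np.ndarray
    ambient: dict = field(default_factory=dict)

    @property
    def mesh_size(self) -> int:
        return len(self.nodes)

    @property
    def has_tout(self) -> bool:
        return "Tout" in self.nodes.columns


def _mesh_once(region: OperatingRegion, n_tin: int, n_fr: int, n_gin: int):
    if n_tin == 1:
        tin_levels = np.array([region.tin_low])
    else:
        tin_levels = np.linspace(region.tin_floor() + 0.5, region.tin_high, n_tin)
    g_lo_all, g_hi_all = region.gin_bounds(tin_levels)
    fr_hi_all = region._column("fr_max_at_gin_max", tin_levels)
    fr_values = np.linspace(region.fr_min, float(np.max(fr_hi_all)), n_fr)
    gin_values = np.linspace(float(np.min(g_lo_all)), float(np.max(g_hi_all)), n_gin)
    T, F, G = np.meshgrid(tin_levels, fr_values, gin_values, indexing="ij")
    mask = region.contains(T.ravel(), F.ravel(), G.ravel())
    nodes = pd.DataFrame(
        {"Tin": T.ravel()[mask], "FR": F.ravel()[mask], "Gin": G.ravel()[mask]}
    )
    nodes["AD"] = nodes["FR"] / nodes["Gin"]
    return nodes, tin_levels, fr_values, gin_values


def mesh_region(region: OperatingRegion, n_target: int = 22241) -> DesignSpaceGrid:
    """Quasi-uniform structured mesh of the region with ~n_target nodes.

    A (Tin x FR x Gin) lattice is clipped to the region; the per-axis
    resolutions are calibrated so the clipped node count lands within 5% of
    the target.  A degenerate single-level region falls back to a 2-D mesh.
    """
    if n_target < 100:
        raise ValueError("n_target must be at least 100")
    degenerate = region.tin_high - region.tin_low < 1e-9
    n0 = max(5, round(n_target ** (1.0 / 3.0)))
    dims = [1 if degenerate else n0, n0, n0]

    for _ in range(40):
        nodes, tl, fv, gv = _mesh_once(region, *dims)
        count = len(nodes)
        if abs(count - n_target) <= 0.05 * n_target:
            return DesignSpaceGrid(nodes, region, tl, fv, gv)
        scale = (n_target / max(count, 1)) ** (1.0 / (2.0 if degenerate else 3.0))
        new_dims = [
            dims[0] if degenerate else max(2, round(dims[0] * scale)),
            max(2, round(dims[1] * scale)),
            max(2, round(dims[2] * scale)),
        ]
        if new_dims == dims:  # fine-tune one axis at a time
            new_dims[1] += 1 if count < n_target else -1
        dims = new_dims
    raise RuntimeError(f"mesh calibration failed to reach {n_target} +/- 5% nodes")


def assign_tout(
    grid: DesignSpaceGrid,
    surrogate: WallSurrogate,
    geom: DryerGeometry | None = None,
    settings: SolverSettings = DEFAULT_SETTINGS,
    opts: BalanceOptions = DEFAULT_OPTIONS,
    Text: float = 296.0,
    RHext: float = 30.0,
    max_nonconverged_frac: float = 0.01,
) -> DesignSpaceGrid:
    """Solve the outlet temperature at every mesh node.

    Ambient temperature and humidity are held fixed across the volume (they
    are environmental, not process, parameters).  More than 1% non-converged
    nodes is treated as a hard error; isolated failures are flagged in the
    ``converged`` column and excluded from sectioning.
    """
    geom = geom or DryerGeometry()
    nodes = grid.nodes.copy()
    X = pd.DataFrame(
        {
            "Tin": nodes["Tin"],
            "Text": Text,
            "RHext": RHext,
            "FR": nodes["FR"],
            "Gin": nodes["Gin"],
        }
    )[list(FEATURES)]
    textwall = surrogate.predict(X)
    tout, converged, iters = solve_tout_vec(
        nodes["Tin"].to_numpy(),
        nodes["FR"].to_numpy(),
        nodes["Gin"].to_numpy(),
        Text,
        RHext,
        textwall,
        geom=geom,
        settings=settings,
        opts=opts,
    )
    frac_bad = 1.0 - converged.mean()
    if frac_bad > max_nonconverged_frac:
        raise RuntimeError(f"{100 * frac_bad:.1f}% of mesh nodes failed to converge")
    if frac_bad > 0:
        log.warning("%d mesh nodes non-converged; excluded from sections", (~converged).sum())
    nodes["Textwall"] = textwall
    nodes["Tout"] = tout
    nodes["converged"] = converged
    nodes["iterations"] = iters
    return DesignSpaceGrid(
        nodes, grid.region, grid.tin_levels, grid.fr_values, grid.gin_values,
        ambient={"Text": Text, "RHext": RHext},
    )


def _require_tout(grid: DesignSpaceGrid) -> pd.DataFrame:
    if not grid.has_tout:
        raise ValueError("grid has no Tout; run assign_tout first")
    return grid.nodes[grid.nodes["converged"]]


def section(grid: DesignSpaceGrid, axis: str, value: float) -> pd.DataFrame:
    """Cut a 2-D section of the design space.

    ``axis='const_Tin'`` returns the nodes of the nearest lattice level
    (columns FR, Gin, AD, Tout).  ``axis='const_Tout'`` interpolates, for
    every (FR, Gin) lattice pair, the inlet temperature at which the model
    reaches the requested outlet temperature (columns FR, Gin, AD, Tin).
    """
    nodes = _require_tout(grid)
    if axis == "const_Tin":
        lo, hi = grid.tin_levels.min(), grid.tin_levels.max()
        if not lo - 1e-9 <= value <= hi + 1e-9:
            raise ValueError(f"Tin={value} outside the meshed interval [{lo:.1f}, {hi:.1f}] K")
        level = grid.tin_levels[np.argmin(np.abs(grid.tin_levels - value))]
        out = nodes[np.isclose(nodes["Tin"], level)]
        return out[["FR", "Gin", "AD", "Tout"]].reset_index(drop=True)
    if axis == "const_Tout":
        lo, hi = nodes["Tout"].min(), nodes["Tout"].max()
        if not lo <= value <= hi:
            raise ValueError(f"Tout={value} outside the attained interval [{lo:.1f}, {hi:.1f}] K")
        rows = []
        for (fr, gin), grp in nodes.groupby(["FR", "Gin"]):
            grp = grp.sort_values("Tin")
            if len(grp) < 2:
                continue
            touts = grp["Tout"].to_numpy()
            if not touts.min() <= value <= touts.max():
                continue
            order = np.argsort(touts)
            tin_at = float(np.interp(value, touts[order], grp["Tin"].to_numpy()[order]))
            rows.append({"FR": fr, "Gin": gin, "AD": fr / gin, "Tin": tin_at})
        return pd.DataFrame(rows)
    raise ValueError("axis must be 'const_Tin' or 'const_Tout'")


def _slice_lattice(grid: DesignSpaceGrid, tin_value: float):
    """Pivot a const-Tin slice back onto its (FR, Gin) lattice (NaN outside)."""
    sl = section(grid, "const_Tin", tin_value)
    pivot = sl.pivot_table(index="FR", columns="Gin", values="Tout")
    return pivot


def _slice_gradients(grid: DesignSpaceGrid, tin_value: float):
    pivot = _slice_lattice(grid, tin_value)
    Z = pivot.to_numpy()
    fr = pivot.index.to_numpy(dtype=float)
    gin = pivot.columns.to_numpy(dtype=float)
    if Z.shape[0] < 3 or Z.shape[1] < 3:
        raise ValueError("slice too small for finite differencing")
    dT_dF = np.gradient(Z, fr, axis=0)
    dT_dG = np.gradient(Z, gin, axis=1)
    return Z, fr, gin, dT_dF, dT_dG


def fr_vs_ad_dominance(grid: DesignSpaceGrid, tin_value: float) -> float:
    """Fraction of interior slice nodes where FR drives Tout more than AD.

    On a constant-Tin section, compares the axis-range-normalized
    sensitivities |dTout/dFR| (at fixed Gin) and |dTout/dAD| (at fixed FR,
    via the chain rule dGin/dAD = -Gin^2/FR).  Because the AD axis span is
    wide on these slices (the composite variable varies ten-fold), its
    normalized sensitivity is substantial; the cleaner leverage comparison
    against the raw gas flow is :func:`fr_vs_gin_leverage`.
    """
    Z, fr, gin, dT_dF, dT_dG = _slice_gradients(grid, tin_value)
    G2 = np.broadcast_to(gin, Z.shape)
    F2 = np.broadcast_to(fr[:, None], Z.shape)
    dT_dAD = dT_dG * (-(G2**2) / F2)
    ad = F2 / G2
    valid = ~np.isnan(Z)
    ad_range = np.nanmax(np.where(valid, ad, np.nan)) - np.nanmin(np.where(valid, ad, np.nan))
    fr_range = fr.max() - fr.min()
    interior = valid[1:-1, 1:-1] & ~np.isnan(dT_dF[1:-1, 1:-1]) & ~np.isnan(dT_dAD[1:-1, 1:-1])
    fr_sens = np.abs(dT_dF[1:-1, 1:-1]) * fr_range
    ad_sens = np.abs(dT_dAD[1:-1, 1:-1]) * ad_range
    n_int = interior.sum()
    if n_int == 0:
        raise ValueError("no interior nodes on the slice")
    return float((fr_sens > ad_sens)[interior].sum() / n_int)


def fr_vs_gin_leverage(grid: DesignSpaceGrid, tin_value: float) -> float:
    """Median |dTout/dFR| / |dTout/dGin| on a constant-Tin section.

    Both flows are in kg/h, so this is the per-unit-flow leverage of the
    feed rate over the drying-gas rate; values far above 1 mean the outlet
    temperature is governed by the evaporative load.
    """
    _, _, _, dT_dF, dT_dG = _slice_gradients(grid, tin_value)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(dT_dF) / np.abs(dT_dG)
    ratio = ratio[np.isfinite(ratio)]
    if ratio.size == 0:
        raise ValueError("no finite leverage ratio on the slice")
    return float(np.median(ratio))


def iso_tout_tradeoff(grid: DesignSpaceGrid, tin_value: float, dfr: float = 0.1) -> float:
    """Median Gin change (kg/h) compensating a ``dfr`` feed-rate change.

    The slope of an iso-Tout curve on a constant-Tin section is
    dGin/dFR = -(dTout/dFR)/(dTout/dGin); reported as a diagnostic of the
    relative leverage of the two flows (sign included).
    """
    pivot = _slice_lattice(grid, tin_value)
    Z = pivot.to_numpy()
    fr = pivot.index.to_numpy(dtype=float)
    gin = pivot.columns.to_numpy(dtype=float)
    dT_dF = np.gradient(Z, fr, axis=0)
    dT_dG = np.gradient(Z, gin, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = -dT_dF / dT_dG
    slope = slope[np.isfinite(slope)]
    if slope.size == 0:
        raise ValueError("no finite iso-curve slope on the slice")
    return float(np.median(slope) * dfr)
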