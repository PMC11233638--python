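"""Topographic organization of CN neurons by number of input zones.

Cells are grouped by how many transverse zones they receive input from
(0-4).  For each group and each of two planes (rostral-caudal x
ventral-dorsal; medial-lateral x ventral-dorsal) an ordinary least-squares
line is fitted and its R^2 recorded.  Significance is assessed with a
subsampling bootstrap: groups of the same size are drawn at random from the
whole population 50,000 times, and the observed R^2 is called significant
when fewer than 5% of resampled groups reach it (one-tailed exceedance
percentile).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import defaults


class FitError(ValueError):
    """Raised when a group is too small or degenerate to fit."""


Plane = Literal["rc_dv", "ml_dv"]

#: Plane id -> (x attribute, y attribute) of CellCoordinate.
PLANES: dict[Plane, tuple[str, str]] = {
    "rc_dv": ("y_ap", "z_dv"),   # rostral-caudal vs ventral-dorsal
    "ml_dv": ("x_ml", "z_dv"),   # medial-lateral vs ventral-dorsal
}


@dataclass(frozen=True)
class CellCoordinate:
    """Soma position in the Allen atlas frame (µm) with its zone-count group."""

    cell_id: str
    x_ml: float
    y_ap: float
    z_dv: float
    n_zones: int

    def __post_init__(self) -> None:
        if self.n_zones not in (0, 1, 2, 3, 4):
            raise ValueError(f"n_zones must be 0..4, got {self.n_zones}")
        for v in (self.x_ml, self.y_ap, self.z_dv):
            if not np.isfinite(v):
                raise ValueError(f"non-finite coordinate for {self.cell_id}")

    def plane_xy(self, plane: Plane) -> tuple[float, float]:
        xa, ya = PLANES[plane]
        return getattr(self, xa), getattr(self, ya)


@dataclass(frozen=True)
class GroupFit:
    group: int
    plane: Plane
    slope: float
    intercept: float
    r2: float
    n: int


@dataclass(frozen=True)
class BootstrapResult:
    observed_r2: float
    iterations: int
    samples_ge: int
    seed: int

    @property
    def p_boot(self) -> float:
        return self.samples_ge / self.iterations

    @property
    def significant(self) -> bool:
        return self.p_boot < defaults.BOOTSTRAP_ALPHA


def fit_r2(points: Sequence[tuple[float, float]] | np.ndarray) -> tuple[float, float, float]:
    """OLS of y on x; returns (slope, intercept, r2).

    r2 = 1 - SS_res / SS_tot with SS_tot about the mean of y.  Constant y
    (SS_tot = 0) is defined as r2 = 0: there is no variance to explain.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise FitError("need at least 2 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise FitError("all x values identical: line undefined")
    syy = float(np.sum((y - y.mean()) ** 2))
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0.0:
        return slope, intercept, 0.0
    r2 = sxy * sxy / (sxx * syy)
    return slope, intercept, float(r2)


def _r2_batch(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise simple-regression R^2 for (B, n) sample matrices.

    Degenerate rows (zero variance in x or y) get R^2 = 0.
    """
    xm = x - x.mean(axis=1, keepdims=True)
    ym = y - y.mean(axis=1, keepdims=True)
    sxx = np.sum(xm * xm, axis=1)
    syy = np.sum(ym * ym, axis=1)
    sxy = np.sum(xm * ym, axis=1)
    r2 = np.zeros(x.shape[0])
    ok = (sxx > 0) & (syy > 0)
    r2[ok] = (sxy[ok] ** 2) / (sxx[ok] * syy[ok])
    return r2


def bootstrap_r2(
    population: Sequence[tuple[float, float]] | np.ndarray,
    group_size: int,
    observed_r2: float,
    iterations: int = defaults.BOOTSTRAP_ITERATIONS,
    seed: int = 0,
    replace: bool = False,
) -> BootstrapResult:
    """Exceedance percentile of an observed R^2 among random same-size groups.

    Each iteration draws ``group_size`` cells from the population (without
    replacement by default, mimicking a relabeling of real cells; with
    replacement optionally) and refits the line in the same plane.
    p_boot = fraction of bootstrap R^2 >= observed.
    """
    pts = np.asarray(population, dtype=float)
    n_pop = pts.shape[0]
    if group_size < 2:
        raise ValueError("group_size must be >= 2")
    if not replace and group_size > n_pop:
        raise ValueError("group_size exceeds population for sampling without replacement")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    if replace:
        idx = rng.integers(0, n_pop, size=(iterations, group_size))
    else:
        keys = rng.random((iterations, n_pop))
        idx = np.argpartition(keys, group_size - 1, axis=1)[:, :group_size]
    r2 = _r2_batch(pts[idx, 0], pts[idx, 1])
    # tolerance absorbs summation-order float wobble when a resample is a
    # permutation of the observed group itself
    samples_ge = int(np.sum(r2 >= observed_r2 - 1e-12))
    return BootstrapResult(
        observed_r2=float(observed_r2),
        iterations=iterations,
        samples_ge=samples_ge,
        seed=seed,
    )


@dataclass(frozen=True)
class TopographyRow:
    fit: GroupFit
    bootstrap: BootstrapResult


@dataclass(frozen=True)
class TopographyReport:
    rows: tuple[TopographyRow, ...]
    skipped: tuple[tuple[int, Plane, str], ...]  # (group, plane, reason)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": r.fit.group,
                    "plane": r.fit.plane,
                    "n": r.fit.n,
                    "slope": r.fit.slope,
                    "intercept": r.fit.intercept,
                    "r2": r.fit.r2,
                    "p_boot": r.bootstrap.p_boot,
                    "significant": r.bootstrap.significant,
                    "iterations": r.bootstrap.iterations,
                    "seed": r.bootstrap.seed,
                }
                for r in self.rows
            ]
        )


def topography_report(
    coords: Sequence[CellCoordinate],
    iterations: int = defaults.BOOTSTRAP_ITERATIONS,
    seed: int = 0,
    replace: bool = False,
    min_group: int = 3,
) -> TopographyReport:
    """Fit + bootstrap every zone-count group (0-4) in both planes.

    Groups with fewer than ``min_group`` cells are reported as skipped.
    The bootstrap population is every cell with coordinates; a derived seed
    per (group, plane) keeps all draws reproducible from one input seed.
    """
    rows: list[TopographyRow] = []
    skipped: list[tuple[int, Plane, str]] = []
    groups = sorted({c.n_zones for c in coords})
    for plane_i, plane in enumerate(PLANES):
        pop = np.array([c.plane_xy(plane) for c in coords])
        for group in groups:
            pts = np.array([c.plane_xy(plane) for c in coords if c.n_zones == group])
            if pts.shape[0] < min_group:
                skipped.append((group, plane, f"only {pts.shape[0]} cells (<{min_group})"))
                continue
            try:
                slope, intercept, r2 = fit_r2(pts)
            except FitError as err:
                skipped.append((group, plane, str(err)))
                continue
            sub_seed = (seed * 1009 + plane_i * 101 + group) % (2**31)
            boot = bootstrap_r2(
                pop, pts.shape[0], r2, iterations=iterations, seed=sub_seed, replace=replace
            )
            rows.append(
                TopographyRow(
                    fit=GroupFit(
                        group=group, plane=plane, slope=slope,
                        intercept=intercept, r2=r2, n=pts.shape[0],
                    ),
                    bootstrap=boot,
                )
            )
    return TopographyReport(rows=tuple(rows), skipped=tuple(skipped))


def read_coordinates(path: str | Path) -> list[CellCoordinate]:
    """Read a coordinate table: ``cell_id,ml_um,ap_um,dv_um,n_zones``."""
    df = pd.read_csv(path, dtype={"cell_id": str}, float_precision="round_trip")
    required = {"cell_id", "ml_um", "ap_um", "dv_um", "n_zones"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing coordinate columns: {sorted(missing)}")
    return [
        CellCoordinate(
            cell_id=str(r.cell_id),
            x_ml=float(r.ml_um),
            y_ap=float(r.ap_um),
            z_dv=float(r.dv_um),
            n_zones=int(r.n_zones),
        )
        for r in df.itertuples()
    ]


def write_coordinates(coords: Sequence[CellCoordinate], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "ml_um": c.x_ml,
                "ap_um": c.y_ap,
                "dv_um": c.z_dv,
                "n_zones": c.n_zones,
            }
            for c in coords
        ]
    ).to_csv(path, index=False, float_format="%.17g")
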