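"""Kernel utilization distributions, overlap and spatial-segregation testing.

Monthly space use per individual is summarized by a fixed-bandwidth bivariate
Gaussian kernel utilization distribution (UD) on a planar grid centred on the
colony (azimuthal equidistant frame, so distance and azimuth from the colony
are exact).  Pairwise overlap uses the Utilization Distribution Overlap Index
(UDOI): the area of intersection of the chosen isopleths times the integral of
the product of the two densities.  Group segregation is tested by correlating
the off-diagonal overlap matrix with a 0/1 group-membership matrix and
comparing the observed correlation against a null built by independently
rotating each individual's points around the colony — a null that preserves
every individual's range shape and colony distance while destroying
inter-individual spatial correspondence.  The p-value is the lower-tail
proportion of null correlations below the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .geo import azimuthal_equidistant_forward, haversine_km

logger = logging.getLogger(__name__)

DEFAULT_BANDWIDTH_M = 100_000.0
DEFAULT_CELL_M = 1_000.0
DEFAULT_DOMAIN_LEVEL = 0.90
MIN_POINTS_PER_UD = 5


@dataclass
class ProjectedPoints:
    """Planar point cloud of one individual (azimuthal equidistant metres)."""

    individual_id: str
    x: np.ndarray
    y: np.ndarray
    month: str | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if len(self.x) and not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("projected coordinates must be finite")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class UDGrid:
    """Gridded utilization density integrating to 1 over the grid."""

    x0: float  # west edge (m)
    y0: float  # south edge (m)
    cell: float  # cell size (m)
    density: np.ndarray  # [ny, nx], cell-centre densities (1/m^2)

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell

    @property
    def xs(self) -> np.ndarray:
        return self.x0 + (np.arange(self.density.shape[1]) + 0.5) * self.cell

    @property
    def ys(self) -> np.ndarray:
        return self.y0 + (np.arange(self.density.shape[0]) + 0.5) * self.cell

    def mass(self) -> float:
        return float(self.density.sum() * self.cell_area)


@dataclass
class Isopleth:
    """Percent-volume contour: smallest-density-threshold region holding ``level`` mass."""

    level: float
    mask: np.ndarray  # boolean [ny, nx]
    grid: UDGrid

    @property
    def area_km2(self) -> float:
        return float(self.mask.sum()) * self.grid.cell_area / 1e6

    def polygons(self):
        """Contour rings as shapely polygons (for GeoJSON export)."""
        from shapely.geometry import Polygon
        from skimage import measure

        dens = np.pad(self.grid.density, 1)
        inside = self.grid.density[self.mask]
        if inside.size == 0:
            return []
        crit = inside.min()
        polys = []
        for ring in measure.find_contours(dens, crit * (1 - 1e-9)):
            ys = self.grid.y0 + (ring[:, 0] - 0.5) * self.grid.cell
            xs = self.grid.x0 + (ring[:, 1] - 0.5) * self.grid.cell
            if len(ring) >= 4:
                polys.append(Polygon(np.column_stack([xs, ys])))
        return polys


@dataclass
class RandomizationResult:
    """Observed vs rotation-null correlation between overlap and membership."""

    r_obs: float
    r_rand: np.ndarray
    p_value: float
    n_iter: int
    seed: int


def project_points(fixes, colony: tuple, month: str | None = None) -> dict[str, ProjectedPoints]:
    """Project clean fixes into the colony-centred planar frame, per individual.

    ``fixes`` is a list of GeoFix (flagged or latitude-less fixes are dropped)
    or a DataFrame with id/lat/lon columns.  Returns {individual_id: points}.
    """
    if isinstance(fixes, pd.DataFrame):
        df = fixes
        clean = df[df.get("flags", "").fillna("").eq("")] if "flags" in df else df
        ids, lats, lons = clean["id"].to_numpy(), clean["lat"].to_numpy(), clean["lon"].to_numpy()
    else:
        keep = [f for f in fixes if not f.flags and np.isfinite(f.lat)]
        ids = np.array([f.individual_id for f in keep], dtype=object)
        lats = np.array([f.lat for f in keep])
        lons = np.array([f.lon for f in keep])
    ok = np.isfinite(lats) & np.isfinite(lons)
    ids, lats, lons = ids[ok], lats[ok], lons[ok]
    x, y = azimuthal_equidistant_forward(lats, lons, colony[0], colony[1])
    out = {}
    for uid in pd.unique(ids):
        sel = ids == uid
        out[str(uid)] = ProjectedPoints(str(uid), x[sel], y[sel], month=month)
    return out


def make_grid(extent_m: float, cell: float) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Symmetric square grid about the origin covering [-extent, extent]."""
    half = int(np.ceil(extent_m / cell))
    edges = (np.arange(-half, half) + 0.5) * cell
    x0 = y0 = -half * cell
    return edges, edges, x0, y0


def _kde_density(x, y, xs, ys, h: float) -> np.ndarray:
    """Separable Gaussian KDE on the grid; returns [ny, nx], normalized to mass 1."""
    ax = np.exp(-0.5 * ((xs[None, :] - x[:, None]) / h) ** 2)  # (n, nx)
    ay = np.exp(-0.5 * ((ys[None, :] - y[:, None]) / h) ** 2)  # (n, ny)
    dens = ay.T @ ax  # (ny, nx)
    cell = float(xs[1] - xs[0]) if len(xs) > 1 else h
    total = dens.sum() * cell * cell
    if total <= 0:
        raise ValueError("degenerate KDE: zero total mass on grid")
    return dens / total


def estimate_ud(
    points: ProjectedPoints,
    h: float = DEFAULT_BANDWIDTH_M,
    cell: float = DEFAULT_CELL_M,
    grid: tuple | None = None,
    min_points: int = MIN_POINTS_PER_UD,
) -> UDGrid | None:
    """Fixed-bandwidth Gaussian kernel UD of one individual's points.

    The grid is padded at least 3 bandwidths beyond the point extent (or pass a
    shared ``grid`` = (xs, ys, x0, y0) to co-register individuals) and the
    density is renormalized to integrate to exactly 1 on the grid.  Individuals
    with fewer than ``min_points`` points are skipped (returns None, logged).
    """
    if len(points) < min_points:
        logger.info("UD skipped for %s: %d < %d points", points.individual_id, len(points), min_points)
        return None
    if grid is None:
        extent = max(
            np.abs(points.x).max() + 3 * h,
            np.abs(points.y).max() + 3 * h,
        )
        xs, ys, x0, y0 = make_grid(extent, cell)
    else:
        xs, ys, x0, y0 = grid
    dens = _kde_density(points.x, points.y, xs, ys, h)
    return UDGrid(x0=x0, y0=y0, cell=float(xs[1] - xs[0]) if len(xs) > 1 else cell, density=dens)


def _volume_mask(density: np.ndarray, level: float, cell_area: float) -> np.ndarray:
    """Boolean mask of the percent-volume region (ties at the threshold included)."""
    flat = density.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order]) * cell_area
    k = int(np.searchsorted(csum, level * min(csum[-1], 1.0) - 1e-12))
    k = min(k, len(flat) - 1)
    crit = flat[order[k]]
    return density >= crit


def percent_volume_contour(ud: UDGrid, level: float) -> Isopleth:
    """Smallest set of highest-density cells whose mass reaches ``level``."""
    if not 0.0 < level <= 1.0:
        raise ValueError("contour level must lie in (0, 1]")
    mask = _volume_mask(ud.density, level, ud.cell_area)
    return Isopleth(level=level, mask=mask, grid=ud)


def compute_udoi(ud1: UDGrid, ud2: UDGrid, domain_level: float | None = DEFAULT_DOMAIN_LEVEL) -> float:
    """Utilization Distribution Overlap Index of two co-registered UDs.

    UDOI = A_overlap * sum(ud1 * ud2) * cell_area, where A_overlap is the area
    of intersection of the two ``domain_level`` isopleths (``None`` uses the
    area where both densities are positive, the full-grid variant).  0 = no
    overlap; 1 = two identical uniform distributions.
    """
    if ud1.density.shape != ud2.density.shape or ud1.cell != ud2.cell:
        raise ValueError("UDs must share one grid; re-estimate on a common grid")
    ca = ud1.cell_area
    prod = float((ud1.density * ud2.density).sum() * ca)
    if domain_level is None:
        inter = (ud1.density > 0) & (ud2.density > 0)
    else:
        inter = _volume_mask(ud1.density, domain_level, ca) & _volume_mask(ud2.density, domain_level, ca)
    a_overlap = float(inter.sum()) * ca
    return a_overlap * prod


def membership_matrix(labels: list) -> np.ndarray:
    """Pairwise indicator: 0 same group, 1 different group (zero diagonal)."""
    lab = np.asarray(labels, dtype=object)
    m = (lab[:, None] != lab[None, :]).astype(float)
    np.fill_diagonal(m, 0.0)
    return m


def offdiag_correlation(overlap: np.ndarray, membership: np.ndarray) -> float:
    """Pearson correlation of the off-diagonal (upper-triangle) matrix entries."""
    overlap = np.asarray(overlap, dtype=float)
    membership = np.asarray(membership, dtype=float)
    if overlap.shape != membership.shape:
        raise ValueError("matrices must have matching shape")
    iu = np.triu_indices(overlap.shape[0], k=1)
    a, b = overlap[iu], membership[iu]
    if np.unique(b).size < 2:
        raise ValueError("membership matrix is constant off the diagonal (single group)")
    if np.std(a) == 0:
        raise ValueError("overlap matrix is constant off the diagonal")
    return float(np.corrcoef(a, b)[0, 1])


def _udoi_matrix_from_stack(dens: np.ndarray, masks: np.ndarray, cell_area: float) -> np.ndarray:
    """Pairwise UDOI for a stack of flattened co-registered UDs."""
    prod = (dens @ dens.T) * cell_area
    inter = (masks.astype(float) @ masks.astype(float).T) * cell_area
    udoi = prod * inter
    np.fill_diagonal(udoi, 0.0)
    return udoi


def _stack_masks(dens: np.ndarray, level: float | None, cell_area: float) -> np.ndarray:
    if level is None:
        return dens > 0
    order = np.argsort(dens, axis=1)[:, ::-1]
    sorted_d = np.take_along_axis(dens, order, axis=1)
    csum = np.cumsum(sorted_d, axis=1) * cell_area
    total = np.minimum(csum[:, -1], 1.0)
    k = np.array([np.searchsorted(csum[i], level * total[i] - 1e-12) for i in range(dens.shape[0])])
    k = np.minimum(k, dens.shape[1] - 1)
    crit = sorted_d[np.arange(dens.shape[0]), k]
    return dens >= crit[:, None]


def rotation_randomization_test(
    points_by_id: dict[str, ProjectedPoints],
    labels: dict[str, str],
    n_iter: int = 1000,
    h: float = DEFAULT_BANDWIDTH_M,
    cell: float = DEFAULT_CELL_M,
    domain_level: float | None = DEFAULT_DOMAIN_LEVEL,
    seed: int = 0,
) -> RandomizationResult:
    """Rotation-randomization test of spatial segregation between two groups.

    The observed statistic r_obs is the off-diagonal Pearson correlation
    between the pairwise UDOI matrix and the 0/1 membership matrix.  Each
    iteration independently rotates every individual's point cloud by a uniform
    angle about the colony (an exact isometry in the projected plane),
    re-estimates the UDs and overlap matrix on a shared grid and recomputes the
    correlation; the p-value is the proportion of null correlations *below*
    r_obs (lower tail: segregation makes between-group overlap, and hence the
    correlation, unusually low).
    """
    ids = sorted(points_by_id)
    lab = [labels[i] for i in ids]
    counts = pd.Series(lab).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least two individuals in each of two groups")
    rng = np.random.default_rng(seed)
    radius = max(float(np.hypot(points_by_id[i].x, points_by_id[i].y).max()) for i in ids)
    xs, ys, x0, y0 = make_grid(radius + 3 * h, cell)
    cell_area = float((xs[1] - xs[0]) ** 2)
    member = membership_matrix(lab)

    def stack_for(rotations: np.ndarray | None) -> np.ndarray:
        dens = np.empty((len(ids), len(ys) * len(xs)))
        for j, uid in enumerate(ids):
            p = points_by_id[uid]
            if rotations is None:
                px, py = p.x, p.y
            else:
                c, s = np.cos(rotations[j]), np.sin(rotations[j])
                px = c * p.x - s * p.y
                py = s * p.x + c * p.y
            dens[j] = _kde_density(px, py, xs, ys, h).ravel()
        return dens

    dens = stack_for(None)
    masks = _stack_masks(dens, domain_level, cell_area)
    r_obs = offdiag_correlation(_udoi_matrix_from_stack(dens, masks, cell_area), member)

    r_rand = np.empty(n_iter)
    for it in range(n_iter):
        angles = rng.uniform(0.0, 2.0 * np.pi, size=len(ids))
        d = stack_for(angles)
        m = _stack_masks(d, domain_level, cell_area)
        r_rand[it] = offdiag_correlation(_udoi_matrix_from_stack(d, m, cell_area), member)

    p = float(np.mean(r_rand < r_obs))
    return RandomizationResult(r_obs=r_obs, r_rand=r_rand, p_value=p, n_iter=n_iter, seed=seed)


def representativeness_bootstrap(
    points_by_id: dict[str, ProjectedPoints],
    level: float = 0.90,
    n_iter: int = 100,
    h: float = DEFAULT_BANDWIDTH_M,
    cell: float = DEFAULT_CELL_M,
    seed: int = 0,
) -> tuple[pd.DataFrame, float | None]:
    """Sample-size representativeness of the tracked cohort.

    For each subsample size k = 1..n-1, ``n_iter`` random k-subsets of
    individuals are pooled into one UD whose ``level`` isopleth is scored by
    the fraction of the held-out individuals' points it contains.  A saturating
    Michaelis–Menten curve fitted to mean inclusion vs k yields the
    representativeness percentage, 100 * predicted(n) / asymptote.

    Returns (curve DataFrame with columns k/mean_inclusion, percentage or None
    if the curve fit fails or n < 3).
    """
    ids = sorted(points_by_id)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two individuals")
    rng = np.random.default_rng(seed)
    radius = max(float(np.hypot(points_by_id[i].x, points_by_id[i].y).max()) for i in ids)
    xs, ys, x0, y0 = make_grid(radius + 3 * h, cell)
    cell_area = float((xs[1] - xs[0]) ** 2)

    rows = []
    for k in range(1, n):
        incl = np.empty(n_iter)
        for b in range(n_iter):
            chosen = rng.choice(n, size=k, replace=False)
            px = np.concatenate([points_by_id[ids[j]].x for j in chosen])
            py = np.concatenate([points_by_id[ids[j]].y for j in chosen])
            dens = _kde_density(px, py, xs, ys, h)
            mask = _volume_mask(dens, level, cell_area)
            held = [j for j in range(n) if j not in set(chosen.tolist())]
            hx = np.concatenate([points_by_id[ids[j]].x for j in held])
            hy = np.concatenate([points_by_id[ids[j]].y for j in held])
            ix = np.clip(((hx - x0) / (xs[1] - xs[0])).astype(int), 0, len(xs) - 1)
            iy = np.clip(((hy - y0) / (xs[1] - xs[0])).astype(int), 0, len(ys) - 1)
            incl[b] = float(mask[iy, ix].mean())
        rows.append({"k": k, "mean_inclusion": float(incl.mean()), "sd_inclusion": float(incl.std())})
    curve = pd.DataFrame(rows)
    if n < 3:
        return curve, None
    try:
        popt, _ = curve_fit(
            lambda k, a, b: a * k / (b + k),
            curve["k"],
            curve["mean_inclusion"],
            p0=[1.0, 1.0],
            maxfev=10_000,
        )
        a, b = popt
        pct = float(100.0 * (a * n / (b + n)) / a)
    except RuntimeError:
        logger.warning("representativeness curve fit failed; reporting raw curve only")
        return curve, None
    return curve, pct


def distance_to_colony(fixes: pd.DataFrame, colony: tuple) -> pd.Series:
    """Per-individual mean great-circle distance (km) to the colony.

    ``fixes`` needs columns id/lat/lon; flagged rows should be excluded by the
    caller (project_points drops them).
    """
    d = haversine_km(fixes["lat"].to_numpy(), fixes["lon"].to_numpy(), colony[0], colony[1])
    return pd.Series(d).groupby(fixes["id"].to_numpy()).mean().rename("mean_km")


def bootstrap_group_difference(
    values: pd.Series,
    labels: pd.Series,
    n_iter: int = 1000,
    seed: int = 0,
) -> dict:
    """Bootstrap + permutation comparison of two group means (individual = unit).

    Returns the observed difference of group means (first group minus second,
    groups in sorted label order), a percentile bootstrap CI from resampling
    individuals within groups, and a two-sided permutation p-value from label
    shuffling.
    """
    values = pd.Series(values).astype(float)
    labels = pd.Series(labels).astype(str)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a = values[labels == groups[0]].to_numpy()
    b = values[labels == groups[1]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two individuals per group")
    rng = np.random.default_rng(seed)
    obs = a.mean() - b.mean()
    boot = np.empty(n_iter)
    for i in range(n_iter):
        boot[i] = rng.choice(a, len(a)).mean() - rng.choice(b, len(b)).mean()
    pooled = np.concatenate([a, b])
    perm = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.permutation(len(pooled))
        perm[i] = pooled[idx[: len(a)]].mean() - pooled[idx[len(a):]].mean()
    p = float((np.sum(np.abs(perm) >= abs(obs)) + 1) / (n_iter + 1))
    return {
        "groups": groups,
        "difference": float(obs),
        "ci_low": float(np.quantile(boot, 0.025)),
        "ci_high": float(np.quantile(boot, 0.975)),
        "p_permutation": p,
        "n_iter": n_iter,
    }
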