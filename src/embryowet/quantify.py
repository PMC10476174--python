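"""Geometric measurement operators for 3D light-sheet segmentations.

Reimplementations of the image-derived measurements used to quantify embryo
shape inside the engineered uterine crypt: contact angle at the wall by
radial reslicing and tangent fitting, middle-axis arc length by a
distance-transform shortest path with a B-spline fit, cross-sectional
diameter, embryo length along the crypt axis, kymograph front tracking,
polar-TE aspect ratios, label counting and tissue volume.

Conventions
-----------
Volumes are indexed ``[z, y, x]`` with anisotropic voxel spacing given as
``(sx, sy, sz)`` in μm per voxel (e.g. 0.295 x 0.295 x 1.0).  Coordinates
are voxel centers; 0-based indices map to physical μm through the spacing,
and all outputs are in μm.  The crypt / symmetry axis is the volume's first
(``z``) axis after alignment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import interpolate
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .wetting import ConfinementGeometry

__all__ = [
    "LabeledVolume",
    "MiddleAxis",
    "measure_contact_angle",
    "middle_axis_length",
    "diameter_at",
    "embryo_length",
    "kymograph_fronts",
    "front_speed",
    "aspect_ratio",
    "count_labels",
    "tissue_volume",
]


@dataclass
class LabeledVolume:
    """A 3D label or binary volume with anisotropic voxel spacing.

    ``data[z, y, x]``; ``spacing = (sx, sy, sz)`` μm per voxel.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabeledVolume requires a 3-D array")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (sx, sy, sz)")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def spacing_zyx(self) -> Tuple[float, float, float]:
        sx, sy, sz = self.spacing
        return (sz, sy, sx)

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def voxel_coords_um(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Physical (x, y, z) μm coordinates of voxel centers."""
        idx = np.argwhere(self.data != 0 if mask is None else mask)
        sz, sy, sx = self.spacing_zyx
        return np.column_stack([idx[:, 2] * sx, idx[:, 1] * sy, idx[:, 0] * sz])

    # --- IO -----------------------------------------------------------------
    def to_tiff(self, path) -> None:
        import tifffile
        import yaml

        tifffile.imwrite(path, self.data)
        with open(str(path) + ".yaml", "w") as fh:
            yaml.safe_dump({"spacing": list(self.spacing)}, fh)

    @classmethod
    def from_tiff(cls, path, spacing=None) -> "LabeledVolume":
        import tifffile

        data = tifffile.imread(path)
        if spacing is None:
            import yaml

            with open(str(path) + ".yaml") as fh:
                spacing = yaml.safe_load(fh)["spacing"]
        return cls(data=data, spacing=tuple(spacing))

    def to_h5(self, path, dataset="volume") -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset(dataset, data=self.data)
            ds.attrs["spacing"] = self.spacing

    @classmethod
    def from_h5(cls, path, dataset="volume") -> "LabeledVolume":
        import h5py

        with h5py.File(path, "r") as fh:
            ds = fh[dataset]
            return cls(data=ds[...], spacing=tuple(ds.attrs["spacing"]))


# ---------------------------------------------------------------------------
# Contact angle at the wall
# ---------------------------------------------------------------------------


def _wall_s(geometry: ConfinementGeometry, z_phys, z_origin: float):
    """Radial wall coordinate s(z) of the confinement at physical height z."""
    if geometry.kind == "cylinder":
        return np.full_like(np.asarray(z_phys, dtype=float), float(geometry.r))
    return np.tan(geometry.alpha) * (np.asarray(z_phys, dtype=float) + z_origin)


def _meridional_slice(vol: LabeledVolume, psi: float, center_xy, s_grid, z_grid):
    """Sample the mask on the half-plane at azimuth ``psi`` (radians)."""
    sx, sy, sz = vol.spacing
    cx, cy = center_xy
    S, Z = np.meshgrid(s_grid, z_grid)  # rows: z, cols: s
    x = (cx + S * math.cos(psi)) / sx
    y = (cy + S * math.sin(psi)) / sy
    z = Z / sz
    coords = np.stack([z.ravel(), y.ravel(), x.ravel()])
    vals = ndi.map_coordinates(
        (vol.data != 0).astype(np.float32), coords, order=1, mode="constant", cval=0.0
    )
    return vals.reshape(S.shape)


def _tangent_direction(points: np.ndarray, anchor: np.ndarray, method: str) -> np.ndarray:
    """Unit tangent of a planar point set at ``anchor``.

    ``method="quad"`` fits a quadratic in a chord-aligned frame and evaluates
    its tangent at the anchor, removing the first-order curvature bias of a
    straight chord; ``method="tls"`` is the plain total-least-squares line.
    """
    rel = points - anchor
    # TLS direction from the second-moment matrix
    cov = rel.T @ rel
    evals, evecs = np.linalg.eigh(cov)
    d = evecs[:, -1]
    far = rel[np.argmax(np.abs(rel @ d))]
    if d @ far < 0:
        d = -d
    if method == "tls" or len(points) < 4:
        return d
    # chord-aligned quadratic: u along d, v across
    u = rel @ d
    v = rel @ np.array([-d[1], d[0]])
    A = np.column_stack([u * u, u, np.ones_like(u)])
    try:
        coef, *_ = np.linalg.lstsq(A, v, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover
        return d
    slope = coef[1]  # dv/du at the anchor (u = 0)
    tangent = d + slope * np.array([-d[1], d[0]])
    return tangent / np.linalg.norm(tangent)


def measure_contact_angle(
    vol: LabeledVolume,
    geometry: ConfinementGeometry,
    side: str = "bottom",
    handle_length: float = 15.0,
    angular_step: float = 30.0,
    z_origin: float = 0.0,
    center_xy: Optional[Tuple[float, float]] = None,
    method: str = "quad",
):
    """Contact angle between the droplet surface and the crypt wall.

    Emulates the radial-reslice procedure: the volume is resliced about the
    symmetry axis over 180° in steps of ``angular_step`` (left and right
    sides of each reslice give a full 360° sweep); on each meridional
    half-plane the droplet boundary near the wall is extracted, a tangent is
    fitted over the ``handle_length`` window (default 15 μm), and the angle
    to the wall, measured through the droplet, is recorded.  The reported
    value is the circumferential average.

    Parameters
    ----------
    vol : LabeledVolume
        Binary droplet mask, crypt axis along the array's z axis.
    geometry : ConfinementGeometry
        Analytic wall surface (the symmetry axis is taken as the crypt axis).
    side : {"bottom", "top"}
        Which contact line to measure (mural vs polar).
    z_origin : float
        Physical axial coordinate of the voxel plane ``z = 0`` relative to
        the frustum apex (μm); ignored for cylinders.
    center_xy : (float, float), optional
        Symmetry-axis position in μm; defaults to the volume center.

    Returns
    -------
    (theta_deg, table) : float and pandas.DataFrame
        Circumferential average and the per-azimuth measurements.
    """
    from skimage import measure as skmeasure

    sx, sy, sz = vol.spacing
    nz, ny, nx = vol.data.shape
    if center_xy is None:
        center_xy = ((nx - 1) * sx / 2.0, (ny - 1) * sy / 2.0)

    s_step = min(sx, sy)
    s_max = max(nx * sx, ny * sy) / 2.0
    s_grid = np.arange(0.0, s_max, s_step)
    z_grid = np.arange(nz) * sz
    wall = _wall_s(geometry, z_grid, z_origin)

    azimuths = np.arange(0.0, 360.0, angular_step)
    half = azimuths < 180.0
    if half.sum() * 2 != azimuths.size:
        azimuths = np.arange(0.0, 360.0, angular_step)

    rows = []
    eps_wall = 1.5 * max(sx, sy, sz)
    for psi_deg in azimuths:
        psi = math.radians(psi_deg)
        sl = _meridional_slice(vol, psi, center_xy, s_grid, z_grid)

        # wet state just inside the wall, per z plane
        s_inner = np.clip(wall - 2.0 * s_step, 0.0, s_grid[-1])
        cols = np.clip(s_inner / s_step, 0, len(s_grid) - 1)
        wet = sl[np.arange(nz), np.round(cols).astype(int)] > 0.5
        if not wet.any():
            rows.append({"azimuth_deg": psi_deg, "theta_deg": np.nan})
            continue
        zi = np.flatnonzero(wet)
        z_c = z_grid[zi[0]] if side == "bottom" else z_grid[zi[-1]]
        s_c = float(_wall_s(geometry, z_c, z_origin))
        anchor = np.array([s_c, z_c])

        contours = skmeasure.find_contours(sl, 0.5)
        if not contours:
            rows.append({"azimuth_deg": psi_deg, "theta_deg": np.nan})
            continue
        pts = np.vstack(contours)  # (row=z index, col=s index)
        pts_phys = np.column_stack([pts[:, 1] * s_step, pts[:, 0] * sz])  # (s, z)
        dist_wall = np.abs(_wall_s(geometry, pts_phys[:, 1], z_origin) - pts_phys[:, 0])
        dist_anchor = np.linalg.norm(pts_phys - anchor, axis=1)
        sel = (dist_wall > eps_wall) & (dist_anchor <= handle_length) & (dist_anchor > s_step)
        if sel.sum() < 4:
            warnings.warn(
                f"no droplet boundary within the handle window at azimuth {psi_deg}"
            )
            rows.append({"azimuth_deg": psi_deg, "theta_deg": np.nan})
            continue
        surf_dir = _tangent_direction(pts_phys[sel], anchor, method)

        # wall tangent pointing along the wetted side of the wall
        if geometry.kind == "cylinder":
            wall_dir = np.array([0.0, 1.0])
        else:
            t = math.tan(geometry.alpha)
            wall_dir = np.array([t, 1.0]) / math.hypot(t, 1.0)
        if side == "top":
            wall_dir = -wall_dir
        cosang = float(np.clip(surf_dir @ wall_dir, -1.0, 1.0))
        rows.append({"azimuth_deg": psi_deg, "theta_deg": math.degrees(math.acos(cosang))})

    table = pd.DataFrame(rows)
    valid = table["theta_deg"].dropna()
    if len(valid) < 3:
        raise ValueError("fewer than 3 valid azimuths; cannot average the contact angle")
    return float(valid.mean()), table


# ---------------------------------------------------------------------------
# Middle axis and diameter
# ---------------------------------------------------------------------------


@dataclass
class MiddleAxis:
    """Open cubic B-spline middle axis with its arc length."""

    tck: tuple
    arc_length: float
    poles: np.ndarray  # (2, 3) physical xyz μm
    path_points: np.ndarray = field(repr=False, default=None)

    @property
    def control_points(self) -> np.ndarray:
        return np.asarray(self.tck[1]).T

    def point(self, u):
        return np.asarray(interpolate.splev(np.asarray(u, dtype=float), self.tck)).T

    def tangent(self, u):
        d = np.asarray(interpolate.splev(np.asarray(u, dtype=float), self.tck, der=1)).T
        return d / np.linalg.norm(d, axis=-1, keepdims=True)


_NEIGHBOR_SHIFTS = np.array(
    [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz, dy, dx) != (0, 0, 0)]
)


def _spline_arc_length(tck, n: int = 4001) -> float:
    u = np.linspace(0.0, 1.0, n)
    d = np.asarray(interpolate.splev(u, tck, der=1))
    speed = np.linalg.norm(d, axis=0)
    from scipy.integrate import simpson

    return float(simpson(speed, x=u))


def middle_axis_length(
    bm_mask: LabeledVolume,
    poles: Sequence[Sequence[float]],
    snap_radius: float = 5.0,
    smoothing: Optional[float] = None,
) -> MiddleAxis:
    """Middle-axis B-spline of a tubular mask and its arc length.

    The Euclidean distance transform (anisotropic spacing honoured) defines
    a directed voxel graph (26-neighborhood) whose edge into a node costs
    ``max(DT) - DT(node)``, so shortest paths ride the ridge of the tube.
    Dijkstra's shortest path between the voxels nearest the two annotated
    poles is fitted with an open cubic B-spline (smoothing grown until the
    maximal node deviation reaches one voxel diagonal) and the arc length is
    obtained by quadrature over the spline.
    """
    mask = bm_mask.data != 0
    if not mask.any():
        raise ValueError("empty mask")
    sz, sy, sx = bm_mask.spacing_zyx
    dt = ndi.distance_transform_edt(mask, sampling=(sz, sy, sx))
    idx = np.argwhere(mask)  # lexicographic -> deterministic node order
    n = len(idx)
    flat = np.full(mask.shape, -1, dtype=np.int64)
    flat[tuple(idx.T)] = np.arange(n)

    src_list, dst_list = [], []
    shape = np.array(mask.shape)
    for shift in _NEIGHBOR_SHIFTS:
        nbr = idx + shift
        ok = np.all((nbr >= 0) & (nbr < shape), axis=1)
        nbr_ids = np.full(n, -1, dtype=np.int64)
        nbr_ids[ok] = flat[tuple(nbr[ok].T)]
        has = nbr_ids >= 0
        src_list.append(np.flatnonzero(has))
        dst_list.append(nbr_ids[has])
    src = np.concatenate(src_list)
    dst = np.concatenate(dst_list)
    dt_flat = dt[tuple(idx.T)]
    w = dt_flat.max() - dt_flat[dst] + 1e-12  # cost of entering the target node
    graph = coo_matrix((w, (src, dst)), shape=(n, n)).tocsr()

    coords = np.column_stack([idx[:, 2] * sx, idx[:, 1] * sy, idx[:, 0] * sz])
    tree = cKDTree(coords)
    ends = []
    for p in np.asarray(poles, dtype=float):
        d, i = tree.query(p)
        if d > snap_radius:
            raise ValueError(f"pole {p} is {d:.1f} μm from the mask (> {snap_radius} μm)")
        ends.append(int(i))

    dist, pred = dijkstra(graph, indices=ends[0], return_predecessors=True)
    if not np.isfinite(dist[ends[1]]):
        raise ValueError("poles are not connected within the mask")
    path = [ends[1]]
    while path[-1] != ends[0]:
        path.append(int(pred[path[-1]]))
    path = np.array(path[::-1])
    pts = coords[path]

    diag = math.sqrt(sx * sx + sy * sy + sz * sz)

    def fit(s_value):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tck, u = interpolate.splprep(pts.T, s=s_value, k=3)
        dev = np.max(np.linalg.norm(np.asarray(interpolate.splev(u, tck)).T - pts, axis=1))
        return tck, dev

    if smoothing is None:
        # grow smoothing until the node deviation hits one voxel diagonal
        s_lo, s_hi = 0.0, len(pts) * diag**2 * 100.0
        tck, dev0 = fit(s_lo)
        for _ in range(40):
            s_try = 0.5 * (s_lo + s_hi)
            tck_try, dev = fit(s_try)
            if dev <= diag:
                s_lo, tck = s_try, tck_try
            else:
                s_hi = s_try
    else:
        tck, _ = fit(smoothing)

    return MiddleAxis(
        tck=tck,
        arc_length=_spline_arc_length(tck),
        poles=np.asarray(poles, dtype=float),
        path_points=pts,
    )


def diameter_at(
    bm_mask: LabeledVolume,
    axis: MiddleAxis,
    landmarks: Sequence[Sequence[float]],
) -> float:
    """Area-equivalent diameter of the cross-section nearest two landmarks.

    The cutting plane is orthogonal to the middle axis and minimizes the
    summed squared distance to the landmark points; the mask's intersection
    with the plane gives the cross-sectional area A and the diameter
    ``2 sqrt(A / pi)`` of the area-equivalent circle.
    """
    lm = np.asarray(landmarks, dtype=float)
    u_grid = np.linspace(0.0, 1.0, 801)
    p = axis.point(u_grid)
    t = axis.tangent(u_grid)
    cost = np.sum(((lm[None, :, :] - p[:, None, :]) * t[:, None, :]).sum(-1) ** 2, axis=1)
    u0 = u_grid[int(np.argmin(cost))]

    center = axis.point(u0)
    normal = axis.tangent(u0)
    # in-plane orthonormal basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)

    sx, sy, sz = bm_mask.spacing
    px = min(sx, sy, sz)
    half = 0.75 * max(np.array(bm_mask.data.shape) * np.array(bm_mask.spacing_zyx))
    g = np.arange(-half, half, px)
    U, W = np.meshgrid(g, g)
    pts = center[None, None, :] + U[..., None] * e1[None, None, :] + W[..., None] * e2[None, None, :]
    zi = pts[..., 2] / sz
    yi = pts[..., 1] / sy
    xi = pts[..., 0] / sx
    vals = ndi.map_coordinates(
        (bm_mask.data != 0).astype(np.float32),
        np.stack([zi.ravel(), yi.ravel(), xi.ravel()]),
        order=1,
        mode="constant",
        cval=0.0,
    ).reshape(U.shape)
    area = float((vals > 0.5).sum()) * px * px
    if area == 0.0:
        raise ValueError("the cutting plane does not intersect the mask")
    return 2.0 * math.sqrt(area / math.pi)


# ---------------------------------------------------------------------------
# Lengths, kymographs, cell shape, counts
# ---------------------------------------------------------------------------


def embryo_length(
    nuclei: pd.DataFrame,
    axis=(0.0, 0.0, 1.0),
    lineage_a: str = "TB",
    lineage_b: str = "pTE",
) -> float:
    """Axial distance between the outermost nuclei of two lineages.

    ``nuclei`` columns: lineage, x_um, y_um, z_um.  The length is the span
    between the extreme axial projections of the two named lineages (lateral
    offsets do not contribute).
    """
    d = np.asarray(axis, dtype=float)
    d /= np.linalg.norm(d)
    proj = {}
    for name in (lineage_a, lineage_b):
        sub = nuclei[nuclei["lineage"] == name]
        if sub.empty:
            raise ValueError(f"no nuclei with lineage {name!r}")
        proj[name] = sub[["x_um", "y_um", "z_um"]].to_numpy() @ d
    a, b = proj[lineage_a], proj[lineage_b]
    return float(max(a.max() - b.min(), b.max() - a.min()))


def kymograph_fronts(
    profiles: np.ndarray,
    positions: np.ndarray,
    times: np.ndarray,
    threshold: str = "half_max",
) -> pd.DataFrame:
    """Front displacement from kymograph line profiles.

    ``profiles[line, frame, position]`` are intensity profiles along lines
    parallel to the crypt axis (three lines per Z-slice at three Z
    locations, nine in total, in the published setup).  Per line and frame
    the edge is the first half-maximum crossing of the 3-point
    median-filtered profile; the per-frame front is the average over lines,
    and displacements are reported relative to the starting coordinate.

    Returns a tidy frame with columns t_h, front_um, displacement_um, n_lines.
    """
    profiles = np.asarray(profiles, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n_lines, n_frames, _ = profiles.shape
    edges = np.full((n_lines, n_frames), np.nan)
    for i in range(n_lines):
        for j in range(n_frames):
            prof = ndi.median_filter(profiles[i, j], size=3, mode="nearest")
            hi = prof.max()
            if hi <= 0:
                continue
            level = 0.5 * hi
            above = prof >= level
            if not above.any() or above.all():
                continue
            # sustained rising crossing: below -> above for >= 2 samples,
            # which isolated residual impulses cannot fake
            cand = np.flatnonzero(~above[:-2] & above[1:-1] & above[2:]) + 1
            if cand.size == 0:
                continue
            k = int(cand[0])
            p0, p1 = prof[k - 1], prof[k]
            frac = (level - p0) / (p1 - p0) if p1 != p0 else 0.5
            edges[i, j] = positions[k - 1] + frac * (positions[k] - positions[k - 1])
    front = np.nanmean(edges, axis=0)
    n_valid = np.sum(~np.isnan(edges), axis=0)
    return pd.DataFrame(
        {
            "t_h": np.asarray(times, dtype=float),
            "front_um": front,
            "displacement_um": front - front[0],
            "n_lines": n_valid,
        }
    )


def front_speed(kymo: pd.DataFrame) -> float:
    """OLS slope (μm/h) of the front displacement."""
    d = kymo.dropna(subset=["displacement_um"])
    coef = np.polyfit(d["t_h"], d["displacement_um"], 1)
    return float(coef[0])


def aspect_ratio(
    cells: LabeledVolume,
    height_axis=(0.0, 0.0, 1.0),
) -> pd.DataFrame:
    """Width-to-height aspect ratio per labelled cell.

    Height is the extent along the apicobasal direction (defaults to the
    crypt axis, the array's z axis); width is the maximal extent along the
    two orthogonal frame directions.  Columnarization shows as ratios
    dropping below 1.
    """
    d = np.asarray(height_axis, dtype=float)
    d /= np.linalg.norm(d)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    steps = np.array(cells.spacing)  # (sx, sy, sz)

    rows = []
    for lab in np.unique(cells.data):
        if lab == 0:
            continue
        coords = cells.voxel_coords_um(cells.data == lab)
        if coords.size == 0:
            warnings.warn(f"label {lab} is empty; skipped")
            continue

        def extent(direction):
            proj = coords @ direction
            vox = float(np.abs(direction) @ steps)
            return float(proj.max() - proj.min()) + vox

        height = extent(d)
        width = max(extent(e1), extent(e2))
        rows.append({"label": int(lab), "width_um": width, "height_um": height,
                     "aspect_ratio": width / height})
    return pd.DataFrame(rows)


def count_labels(labels, lineage_mask: Optional[np.ndarray] = None) -> int:
    """Number of distinct nonzero labels in a volume or point table."""
    if isinstance(labels, LabeledVolume):
        data = labels.data
        if lineage_mask is not None:
            data = np.where(lineage_mask, data, 0)
        vals = np.unique(data)
        return int(np.sum(vals != 0))
    if isinstance(labels, pd.DataFrame):
        sub = labels if lineage_mask is None else labels[lineage_mask]
        return int(sub["label"].nunique()) if "label" in sub else int(len(sub))
    vals = np.unique(np.asarray(labels))
    return int(np.sum(vals != 0))


def tissue_volume(mask: LabeledVolume) -> float:
    """Tissue volume in μm³: voxel count times voxel volume."""
    return float(np.count_nonzero(mask.data)) * mask.voxel_volume
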