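"""Local trabecular morphometry: grid BV/TV, MIL fabric/DA, and
sphere-fitting thickness.

Bone volume fraction and fabric are sampled on a background grid of
overlapping spherical volumes of interest (VOIs) laid over the inner
(trabecular) mask: a 2.5 mm lattice of nodes, each carrying a 5 mm
diameter sphere.  Fabric is the mean-intercept-length (MIL) ellipsoid:
parallel test-line families are cast through the VOI in a quasi-uniform
set of directions, the mean intercept length per direction is total
in-mask line length over the number of marrow-to-bone crossings, and the
ellipsoid 1/MIL^2(w) = w' H w is fitted by least squares.  The MIL
eigenvalues lambda_i = 1/sqrt(eig_i(H)) define the degree of anisotropy
DA = 1 - lambda_min/lambda_max, bounded on [0, 1] with 0 isotropic.

Trabecular thickness and separation follow the maximal-inscribed-sphere
(sphere-fitting) definition: the local thickness of a foreground voxel is
the diameter of the largest sphere fully contained in the phase that
covers it, computed by the morphological-opening formulation (erosion =
distance-transform threshold, dilation by the same radius, radii swept
descending).  Tb.Th and Tb.Sp are phase means of those maps and
Tb.N = 1/(Tb.Th + Tb.Sp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import VoxelVolume

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit directions on the upper hemisphere
    (component along axis 0 positive).  Seed-free and deterministic; MIL
    is even in the direction, so a hemisphere suffices."""
    i = np.arange(n)
    z = (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    phi = i * GOLDEN_ANGLE
    return np.column_stack([z, r * np.cos(phi), r * np.sin(phi)])


def _orthobasis(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(helper, w))) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(w, u)


# ---------------------------------------------------------------------------
# background grid
# ---------------------------------------------------------------------------

@dataclass
class BackgroundGrid:
    """Axis-aligned node lattice over the inner mask.

    ``nodes`` are physical coordinates in mm (voxel centre of index i is
    at ``i * voxel_size``), anchored at the inner mask's bounding-box
    minimum corner, retained where at least ``min_mask_fraction`` of the
    VOI sphere lies inside the mask.
    """

    spacing: float
    voi_diameter: float
    nodes: np.ndarray  # (N, 3) mm
    min_mask_fraction: float = 0.1


def _sphere_bool(radius_vox: float) -> np.ndarray:
    r = int(np.ceil(radius_vox))
    ax = np.arange(-r, r + 1)
    Z, Y, X = np.meshgrid(ax, ax, ax, indexing="ij")
    return (Z * Z + Y * Y + X * X) <= radius_vox * radius_vox


def _voi_counts(mask: np.ndarray, center_vox: np.ndarray,
                radius_vox: float,
                other: np.ndarray | None = None) -> tuple[int, int, int]:
    """(mask voxels, other&mask voxels, sphere voxels) inside the VOI."""
    ball = _sphere_bool(radius_vox)
    r = ball.shape[0] // 2
    c = np.rint(center_vox).astype(int)
    sl_v, sl_b = [], []
    for ax in range(3):
        lo, hi = c[ax] - r, c[ax] + r + 1
        blo = max(0, -lo)
        bhi = ball.shape[ax] - max(0, hi - mask.shape[ax])
        sl_v.append(slice(max(lo, 0), min(hi, mask.shape[ax])))
        sl_b.append(slice(blo, bhi))
    bsub = ball[tuple(sl_b)]
    msub = mask[tuple(sl_v)]
    n_mask = int(np.count_nonzero(msub & bsub))
    n_other = 0
    if other is not None:
        osub = other[tuple(sl_v)]
        n_other = int(np.count_nonzero(osub & msub & bsub))
    return n_mask, n_other, int(ball.sum())


def build_grid(
    inner_mask: VoxelVolume,
    spacing: float = 2.5,
    voi_diameter: float = 5.0,
    min_mask_fraction: float = 0.1,
) -> BackgroundGrid:
    """Superimpose the background grid on the inner mask.

    Nodes form an axis-aligned lattice with the given ``spacing`` (mm),
    anchored at the mask bounding box's minimum corner; a node is kept iff
    at least ``min_mask_fraction`` of its VOI sphere lies inside the
    mask.  Deterministic given mask and spacing.
    """
    mask = inner_mask.as_bool()
    if not mask.any():
        raise ValueError("empty inner mask")
    vs = inner_mask.voxel_size
    idx = np.nonzero(mask)
    lo = np.array([a.min() for a in idx], dtype=float) * vs
    hi = np.array([a.max() for a in idx], dtype=float) * vs
    radius_vox = 0.5 * voi_diameter / vs

    axes = [np.arange(lo[a], hi[a] + 1e-9, spacing) for a in range(3)]
    # degenerate extents still get one node at the corner
    axes = [ax if ax.size else np.array([lo[a]]) for a, ax in enumerate(axes)]
    nodes = []
    for z in axes[0]:
        for y in axes[1]:
            for x in axes[2]:
                c = np.array([z, y, x]) / vs
                n_mask, _, n_sphere = _voi_counts(mask, c, radius_vox)
                if n_mask >= min_mask_fraction * n_sphere:
                    nodes.append([z, y, x])
    return BackgroundGrid(spacing=spacing, voi_diameter=voi_diameter,
                          nodes=np.asarray(nodes, dtype=float).reshape(-1, 3),
                          min_mask_fraction=min_mask_fraction)


# ---------------------------------------------------------------------------
# BV/TV sampling
# ---------------------------------------------------------------------------

def sample_bvtv(
    trabecular_bone: VoxelVolume,
    inner_mask: VoxelVolume,
    node: np.ndarray,
    voi_diameter: float = 5.0,
) -> float:
    """Bone volume fraction within one spherical VOI.

    Bone voxels over inner-mask voxels inside the sphere centred at
    ``node`` (mm).  Returns NaN when the sphere contains no inner-mask
    voxels (caller flags the sample invalid).
    """
    vs = inner_mask.voxel_size
    c = np.asarray(node, dtype=float) / vs
    n_mask, n_bone, _ = _voi_counts(inner_mask.as_bool(), c,
                                    0.5 * voi_diameter / vs,
                                    other=trabecular_bone.as_bool())
    if n_mask == 0:
        return math.nan
    return n_bone / n_mask


# ---------------------------------------------------------------------------
# MIL fabric
# ---------------------------------------------------------------------------

@dataclass
class FabricResult:
    """MIL fabric-tensor fit for one VOI.

    ``eigenvalues`` are the MIL ellipsoid semi-axes sorted descending
    (lambda1 >= lambda2 >= lambda3 > 0), ``eigenvectors`` the matching
    orthonormal columns, ``da = 1 - lambda3/lambda1`` in [0, 1].
    ``valid`` is False (with ``diagnostic``) when the fit failed: a
    direction family saw no phase crossings, or the fitted form was not
    positive definite.
    """

    mil_tensor: np.ndarray | None
    eigenvalues: np.ndarray | None
    eigenvectors: np.ndarray | None
    da: float
    valid: bool
    diagnostic: str = ""


@dataclass
class VOISample:
    """Per-grid-node result: BV/TV, fabric, and validity."""

    node: np.ndarray
    bvtv: float
    fabric: FabricResult | None
    n_bone_voxels: int
    valid: bool


def mil_directional(
    bone: np.ndarray,
    mask: np.ndarray,
    center_vox: np.ndarray,
    radius_vox: float,
    directions: np.ndarray,
    line_spacing: float = 1.0,
    step: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directed-secant MIL through a spherical VOI (voxel units).

    For each unit direction, a family of parallel test lines (spaced
    ``line_spacing`` voxels apart in the orthogonal plane) is sampled at
    ``step``-voxel intervals with nearest-voxel lookup, restricted to the
    sphere of ``radius_vox`` about ``center_vox`` intersected with
    ``mask``.  Returns per-direction arrays ``(mil, crossings, length)``:
    the number of marrow-to-bone transitions between consecutive valid
    samples, the total valid line length (in voxels, measured over
    consecutive-sample pairs), and their ratio (NaN when no crossing).
    """
    bone = np.ascontiguousarray(bone, dtype=bool)
    mask = np.ascontiguousarray(mask, dtype=bool)
    nz, ny, nx = bone.shape
    bone_f = bone.ravel()
    mask_f = mask.ravel()
    c = np.asarray(center_vox, dtype=float)
    R = float(radius_vox)

    n_off = int(math.floor(2.0 * R / line_spacing)) + 1
    offs = (np.arange(n_off) - (n_off - 1) / 2.0) * line_spacing
    A, B = np.meshgrid(offs, offs, indexing="ij")
    keep = (A * A + B * B) <= R * R
    a, b = A[keep], B[keep]
    n_t = int(math.floor(2.0 * R / step)) + 1
    t = (np.arange(n_t) - (n_t - 1) / 2.0) * step
    r2 = a[:, None] ** 2 + b[:, None] ** 2 + t[None, :] ** 2
    in_sphere = r2 <= R * R

    n_dir = directions.shape[0]
    mil = np.full(n_dir, np.nan)
    crossings = np.zeros(n_dir, dtype=np.int64)
    lengths = np.zeros(n_dir)

    for d in range(n_dir):
        w = directions[d]
        u, v = _orthobasis(w)
        o0 = c[0] + a * u[0] + b * v[0]
        o1 = c[1] + a * u[1] + b * v[1]
        o2 = c[2] + a * u[2] + b * v[2]
        i0 = np.rint(o0[:, None] + t[None, :] * w[0]).astype(np.int64)
        i1 = np.rint(o1[:, None] + t[None, :] * w[1]).astype(np.int64)
        i2 = np.rint(o2[:, None] + t[None, :] * w[2]).astype(np.int64)
        inb = ((i0 >= 0) & (i0 < nz) & (i1 >= 0) & (i1 < ny)
               & (i2 >= 0) & (i2 < nx))
        lin = (i0 * ny + i1) * nx + i2
        lin[~inb] = 0
        valid = inb & in_sphere & mask_f[lin]
        bn = bone_f[lin]
        pair = valid[:, :-1] & valid[:, 1:]
        cr = pair & ~bn[:, :-1] & bn[:, 1:]
        n_pair = int(np.count_nonzero(pair))
        crossings[d] = int(np.count_nonzero(cr))
        lengths[d] = n_pair * step
        if crossings[d] > 0:
            mil[d] = lengths[d] / crossings[d]
    return mil, crossings, lengths


def _fit_mil_ellipsoid(directions: np.ndarray,
                       mil: np.ndarray) -> np.ndarray:
    """Least-squares fit of 1/MIL^2(w) = w' H w; returns symmetric H.

    Directions whose line family saw no crossing carry MIL = inf, i.e.
    1/MIL^2 = 0 — the continuum limit for test lines parallel to a
    strongly oriented structure."""
    w = directions
    X = np.column_stack([
        w[:, 0] ** 2, w[:, 1] ** 2, w[:, 2] ** 2,
        2 * w[:, 0] * w[:, 1], 2 * w[:, 0] * w[:, 2], 2 * w[:, 1] * w[:, 2],
    ])
    g = np.where(np.isfinite(mil), 1.0 / (mil * mil), 0.0)
    h, *_ = np.linalg.lstsq(X, g, rcond=None)
    return np.array([[h[0], h[3], h[4]],
                     [h[3], h[1], h[5]],
                     [h[4], h[5], h[2]]])


def mil_fabric(
    trabecular_bone: VoxelVolume,
    inner_mask: VoxelVolume,
    node: np.ndarray,
    voi_diameter: float = 5.0,
    n_directions: int = 128,
    line_spacing: float = 1.0,
) -> FabricResult:
    """MIL fabric tensor and degree of anisotropy for one VOI.

    Casts ``n_directions`` quasi-uniform (Fibonacci hemisphere) test-line
    families through the VOI at ``line_spacing`` voxels, fits the MIL
    ellipsoid and returns eigenvalues/eigenvectors and
    ``da = 1 - lambda_min/lambda_max``.  Directions that see no crossing
    enter the fit at the continuum limit 1/MIL^2 = 0.  Invalid-flagged
    (never raises) when no direction sees a crossing — a single-phase
    VOI — or when the fitted form is not positive definite.
    """
    vs = inner_mask.voxel_size
    bone = trabecular_bone.as_bool()
    mask = inner_mask.as_bool()
    c = np.asarray(node, dtype=float) / vs
    R = 0.5 * voi_diameter / vs
    dirs = fibonacci_hemisphere(n_directions)
    mil, crossings, _ = mil_directional(bone, mask, c, R, dirs,
                                        line_spacing=line_spacing)
    if np.all(crossings == 0):
        return FabricResult(None, None, None, math.nan, False,
                            "no phase crossings in any direction "
                            "(single-phase or near-empty VOI)")
    H = _fit_mil_ellipsoid(dirs, mil * vs)
    evals, evecs = np.linalg.eigh(H)  # ascending
    if evals[2] <= 0 or evals[0] < -0.05 * evals[2]:
        return FabricResult(H, None, None, math.nan, False,
                            f"indefinite MIL fit (eigenvalues {evals})")
    # small negative eigenvalues are the degenerate planar limit
    # (in-plane 1/MIL^2 -> 0 for parallel plates): clamp to zero
    ev = np.clip(evals, 0.0, None)
    with np.errstate(divide="ignore"):
        lam = 1.0 / np.sqrt(ev)  # descending; inf in the planar limit
    da = 1.0 - math.sqrt(ev[0] / ev[2])
    return FabricResult(mil_tensor=H, eigenvalues=lam, eigenvectors=evecs,
                        da=float(da), valid=True)


def sample_grid(
    trabecular_bone: VoxelVolume,
    inner_mask: VoxelVolume,
    grid: BackgroundGrid,
    compute_fabric: bool = True,
    n_directions: int = 128,
    line_spacing: float = 1.0,
    min_bone_voxels: int = 50,
) -> list[VOISample]:
    """Evaluate BV/TV (and optionally MIL fabric) at every grid node.

    A sample is valid when at least ``grid.min_mask_fraction`` of the VOI
    sphere lies in the inner mask and the VOI holds at least
    ``min_bone_voxels`` bone voxels (fabric fits are unstable below
    that).
    """
    vs = inner_mask.voxel_size
    mask = inner_mask.as_bool()
    bone = trabecular_bone.as_bool()
    radius_vox = 0.5 * grid.voi_diameter / vs
    out: list[VOISample] = []
    for node in grid.nodes:
        c = node / vs
        n_mask, n_bone, n_sphere = _voi_counts(mask, c, radius_vox,
                                               other=bone)
        bvtv = math.nan if n_mask == 0 else n_bone / n_mask
        valid = (n_mask >= grid.min_mask_fraction * n_sphere
                 and n_bone >= min_bone_voxels and n_bone < n_mask)
        fabric = None
        if valid and compute_fabric:
            fabric = mil_fabric(trabecular_bone, inner_mask, node,
                                grid.voi_diameter, n_directions,
                                line_spacing)
        out.append(VOISample(node=node, bvtv=bvtv, fabric=fabric,
                             n_bone_voxels=n_bone, valid=valid))
    return out


# ---------------------------------------------------------------------------
# sphere-fitting local thickness
# ---------------------------------------------------------------------------

def local_thickness_map(
    phase: VoxelVolume,
    pad_mode: str = "wrap",
    bin_width: float = 0.5,
) -> VoxelVolume:
    """Sphere-fitting local thickness of a binary phase, in mm.

    Every foreground voxel receives the diameter of the largest sphere
    fully contained in the phase that covers it.  Implemented as a sweep
    of morphological openings over descending radii: for radius r the
    sphere centres are the voxels with Euclidean distance transform >= r,
    and the voxels they cover (within r of a centre) have local thickness
    at least 2r.  Radii are swept on a ``bin_width``-voxel lattice, so
    values are exact to within one voxel on the diameter.

    The volume is padded by the maximal radius before the transform
    (``pad_mode``: any :func:`numpy.pad` mode; 'wrap' is exact for
    periodic phantoms and inert when the phase does not touch the volume
    boundary).  An empty phase yields an all-zero map.
    """
    bw = phase.as_bool()
    if not bw.any():
        return phase.like(np.zeros(bw.shape, dtype=np.float32))
    dt0 = ndimage.distance_transform_edt(bw)
    rmax = float(dt0.max())
    pad = int(np.ceil(rmax)) + 1
    bwp = np.pad(bw, pad, mode=pad_mode)
    dt = ndimage.distance_transform_edt(bwp)
    rmax = float(dt[pad:-pad, pad:-pad, pad:-pad].max())

    lt = np.zeros(bwp.shape, dtype=np.float32)
    unassigned = bwp.copy()
    radii = np.arange(bin_width, rmax + bin_width, bin_width)[::-1]
    for r in radii:
        if not unassigned.any():
            break
        # restrict work to the unassigned voxels' bounding box, expanded
        # by r: any sphere centre covering an unassigned voxel lies there
        grow = int(np.ceil(r)) + 1
        sub = []
        for ax in range(3):
            other = tuple(a for a in range(3) if a != ax)
            prof = unassigned.any(axis=other)
            nzi = np.nonzero(prof)[0]
            sub.append(slice(max(int(nzi[0]) - grow, 0),
                             min(int(nzi[-1]) + grow + 1, bwp.shape[ax])))
        sub = tuple(sub)
        seeds = dt[sub] >= r
        if not seeds.any():
            continue
        cover = ndimage.distance_transform_edt(~seeds) <= r + 1e-9
        newly = cover & unassigned[sub]
        lt[sub][newly] = 2.0 * r
        unassigned[sub][newly] = False
    # sub-bin thin voxels: fall back to twice their own distance value
    thin = bwp & (lt == 0)
    lt[thin] = (2.0 * dt[thin]).astype(np.float32)
    core = lt[pad:-pad, pad:-pad, pad:-pad]
    return phase.like((core * phase.voxel_size).astype(np.float32))


@dataclass
class ThicknessSummary:
    """Regional thickness metrics (mm / mm^-1): Tb.Th, Tb.Sp, and
    Tb.N = 1/(Tb.Th + Tb.Sp) exactly as computed."""

    tb_th: float
    tb_sp: float
    tb_n: float = field(init=False)

    def __post_init__(self) -> None:
        self.tb_n = 1.0 / (self.tb_th + self.tb_sp)


def region_thickness(
    trabecular_bone: VoxelVolume,
    inner_mask: VoxelVolume,
    region: np.ndarray | None = None,
    pad_mode: str = "wrap",
) -> ThicknessSummary:
    """Mean sphere-fitting thickness metrics over a region.

    Tb.Th is the mean local thickness of the bone phase over bone voxels
    in ``region`` (default: everywhere); Tb.Sp the same on the marrow
    phase (inner mask minus bone); Tb.N = 1/(Tb.Th + Tb.Sp).  Raises
    ``ValueError`` naming the missing phase when the region holds only
    one phase.
    """
    bone = trabecular_bone.as_bool()
    mask = inner_mask.as_bool()
    if region is None:
        region = np.ones(bone.shape, dtype=bool)
    bone_sel = bone & mask & region
    marrow_sel = mask & ~bone & region
    if not bone_sel.any():
        raise ValueError("region contains no bone phase")
    if not marrow_sel.any():
        raise ValueError("region contains no marrow phase")
    lt_bone = local_thickness_map(
        trabecular_bone.like((bone & mask).astype(np.uint8)),
        pad_mode=pad_mode)
    lt_marrow = local_thickness_map(
        trabecular_bone.like((mask & ~bone).astype(np.uint8)),
        pad_mode=pad_mode)
    tb_th = float(lt_bone.data[bone_sel].mean())
    tb_sp = float(lt_marrow.data[marrow_sel].mean())
    return ThicknessSummary(tb_th=tb_th, tb_sp=tb_sp)
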