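"""Synthetic inputs: test phantoms with closed-form ground truth and
metacarpal-like ontogenetic specimens.

Two tiers of synthetic data are provided.

**Phantoms** (:func:`make_phantom`) are periodic or random binary
microstructures — parallel plates, square rod lattices, isotropic foams,
plus solid/empty degenerate cases — whose morphometric parameters are known
in closed form, so the estimators (BV/TV, MIL fabric, sphere-fitting
thickness) can be validated against analytic truth.

**Synthetic metacarpals** (:func:`make_synthetic_metacarpal`,
:func:`make_cohort`) are miniature whole-bone volumes with a cortical
shell, trabecular fill in the base and distal end, a hollow mid-shaft, an
optional unfused growth-plate gap, and an epiphyseal dorsopalmar BV/TV
gradient that shifts from palmar-high in infants to dorsal-high in adults —
the spatial and statistical structure of an ontogenetic series of ape
metacarpals, at a reduced scale that keeps a full image-to-statistics run
tractable.  The trabecular fill is a quantile-thresholded Gaussian random
field, so regional BV/TV is realised exactly by construction; thickness and
spacing of the fill follow the age trajectory only qualitatively (no closed
form exists for a thresholded random field), which is why thickness truth
values stored per region are the trajectory's nominal means.

:func:`make_cohort_table` is the fast path: it draws per-specimen regional
summary values directly from the age trajectory (no image synthesis), for
statistical simulations that need hundreds of cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import VoxelVolume

LABEL_BACKGROUND = 0
LABEL_CORTEX = 1
LABEL_TRABECULAR = 2
LABEL_MARROW = 3

#: morphometric parameters, in the column order used throughout the package
PARAMS = ("bvtv", "da", "tb_th", "tb_sp", "tb_n")
#: analysed anatomical regions (the shaft carries no trabeculae and is skipped)
REGIONS = ("base", "metaphysis", "epiphysis")
#: ontogenetic age categories, youngest first
CATEGORIES = ("Neonate", "Infant1", "Infant2", "Juvenile", "Adult")

PHANTOM_KINDS = ("plate", "rod", "sphere_foam", "solid", "empty")


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Specification of a binary test phantom.

    ``axis`` is the structural symmetry axis: the plate *normal* for plate
    phantoms and the rod direction for rod phantoms (ignored for the other
    kinds).  Lengths are in mm.
    """

    kind: str
    voxel_size: float
    dims: tuple[int, int, int] = (128, 128, 128)
    thickness: float = 0.25      # plate: bone slab thickness t
    period: float = 1.0          # plate: repeat period p (t < p)
    rod_radius: float = 0.15
    rod_spacing: float = 1.0     # square lattice pitch s (2r < s)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    target_bvtv: float = 0.3     # foam fill fraction
    smoothing: float = 0.15      # foam feature scale (Gaussian sigma, mm)
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if any(d < 8 for d in self.dims):
            raise ValueError("dims too small for a meaningful phantom")
        extent = min(self.dims) * self.voxel_size
        if self.kind == "plate":
            if not self.thickness < self.period:
                raise ValueError("plate requires thickness < period")
            if extent < self.period:
                raise ValueError("dims too small to contain one plate period")
        if self.kind == "rod":
            if not 2 * self.rod_radius < self.rod_spacing:
                raise ValueError("rod requires 2*radius < spacing")
            if extent < self.rod_spacing:
                raise ValueError("dims too small to contain one rod cell")
        if self.kind == "sphere_foam" and not 0.0 < self.target_bvtv < 1.0:
            raise ValueError("target_bvtv must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Closed-form morphometric truth for a phantom or specimen region.

    NaN marks parameters without a defined value (e.g. Tb.Sp of a solid
    block, thickness of a random foam).  ``principal_axis`` is the
    structural symmetry axis; ``da_class`` classifies the expected degree
    of anisotropy as 'high' (plates, rods) or 'low' (foams).
    """

    bvtv: float
    tb_th: float = math.nan
    tb_sp: float = math.nan
    tb_n: float = math.nan
    principal_axis: np.ndarray | None = None
    da_class: str | None = None


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("axis must be a nonzero vector")
    return v / n


def make_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Generate a binary phantom and its analytic ground truth.

    Plates: bone where the coordinate along the normal falls in the first
    ``thickness`` of each ``period``; BV/TV = t/p, Tb.Th = t,
    Tb.Sp = p - t, Tb.N = 1/p.  Rods: circular cylinders of radius r on a
    square lattice of pitch s along ``axis``; BV/TV = pi r^2 / s^2,
    Tb.Th = 2r.  Foams: level set of a Gaussian random field thresholded
    at the exact ``target_bvtv`` quantile — statistically isotropic with
    the fill fraction matched by construction.
    """
    spec.validate()
    nz, ny, nx = spec.dims
    vs = spec.voxel_size
    # sample the continuum field at voxel centres offset by half a voxel:
    # keeps phase boundaries off the sampling lattice (no systematic
    # inclusion of boundary voxels through floating-point rounding)
    coords = [(np.arange(n) + 0.5) * vs for n in spec.dims]

    if spec.kind == "solid":
        data = np.ones(spec.dims, dtype=np.uint8)
        truth = GroundTruth(bvtv=1.0, tb_th=math.nan, tb_sp=math.nan,
                            tb_n=math.nan, da_class=None)
    elif spec.kind == "empty":
        data = np.zeros(spec.dims, dtype=np.uint8)
        truth = GroundTruth(bvtv=0.0)
    elif spec.kind == "plate":
        n = _unit(spec.axis)
        proj = (coords[0][:, None, None] * n[0]
                + coords[1][None, :, None] * n[1]
                + coords[2][None, None, :] * n[2])
        data = (np.mod(proj, spec.period) < spec.thickness).astype(np.uint8)
        t, p = spec.thickness, spec.period
        truth = GroundTruth(bvtv=t / p, tb_th=t, tb_sp=p - t, tb_n=1.0 / p,
                            principal_axis=n, da_class="high")
    elif spec.kind == "rod":
        n = _unit(spec.axis)
        # orthonormal in-plane basis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, n)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = _unit(np.cross(n, helper))
        v = np.cross(n, u)
        Z = coords[0][:, None, None]
        Y = coords[1][None, :, None]
        X = coords[2][None, None, :]
        a = Z * u[0] + Y * u[1] + X * u[2]
        b = Z * v[0] + Y * v[1] + X * v[2]
        s, r = spec.rod_spacing, spec.rod_radius
        da_ = np.mod(a, s) - s / 2.0
        db_ = np.mod(b, s) - s / 2.0
        data = (da_ * da_ + db_ * db_ <= r * r).astype(np.uint8)
        bvtv = math.pi * r * r / (s * s)
        tb_th = 2.0 * r
        tb_sp = 2.0 * (s / math.sqrt(2.0) - r)  # nominal: widest marrow sphere
        truth = GroundTruth(bvtv=bvtv, tb_th=tb_th, tb_sp=tb_sp,
                            tb_n=1.0 / (tb_th + tb_sp),
                            principal_axis=n, da_class="high")
    else:  # sphere_foam
        rng = np.random.default_rng(spec.seed)
        noise = rng.standard_normal(spec.dims)
        sigma_vox = max(spec.smoothing / vs, 1.0)
        fld = ndimage.gaussian_filter(noise, sigma_vox, mode="wrap")
        thr = np.quantile(fld, 1.0 - spec.target_bvtv)
        data = (fld > thr).astype(np.uint8)
        truth = GroundTruth(bvtv=spec.target_bvtv, da_class="low")

    return VoxelVolume(data, vs), truth


# ---------------------------------------------------------------------------
# ontogenetic trajectories
# ---------------------------------------------------------------------------

@dataclass
class AgeTrajectory:
    """Per-age-category regional means/SDs of the trabecular parameters.

    ``means[region][param]`` and ``sds[region][param]`` are 5-vectors in
    the order of :data:`CATEGORIES`.  ``epiphysis_present`` gives, per
    category, the probability that a secondary ossification centre has
    formed; ``gradient`` gives the signed dorsopalmar BV/TV ramp amplitude
    in the epiphysis (positive = palmar-high, negative = dorsal-high,
    matching the infant-to-adult distopalmar-to-distodorsal shift).
    ``fusion_age_months`` is the age at which the growth plate fuses and
    the gap disappears.
    """

    means: dict[str, dict[str, np.ndarray]]
    sds: dict[str, dict[str, np.ndarray]]
    epiphysis_present: np.ndarray
    gradient: np.ndarray
    fusion_age_months: float = 126.0  # fusion commences around 10-11 years

    def category_index(self, age_months: float) -> int:
        from .stats import assign_age_category
        return CATEGORIES.index(assign_age_category(age_months))


def default_trajectory(age_effect: bool = True,
                       species_offset: float = 0.0) -> AgeTrajectory:
    """Default gorilla-like ontogenetic trajectory.

    Qualitative shape: BV/TV and Tb.Th lowest at birth and increasing with
    age (with a slight adult dip in the distal regions), Tb.Sp
    near-constant with a small adult increase, Tb.N therefore decreasing,
    DA near-constant.  With ``age_effect=False`` every category shares the
    middle (Infant2) values — the null configuration for type-I-error
    simulations.  ``species_offset`` shifts all BV/TV means additively
    (default 0: no species effect, matching the minimal interspecific
    differences reported for gorillas).
    """
    bvtv = {
        "base":       np.array([0.22, 0.25, 0.30, 0.36, 0.42]),
        "metaphysis": np.array([0.25, 0.28, 0.33, 0.38, 0.36]),
        "epiphysis":  np.array([0.20, 0.20, 0.24, 0.30, 0.28]),
    }
    tb_th = {
        "base":       np.array([0.13, 0.16, 0.20, 0.26, 0.32]),
        "metaphysis": np.array([0.13, 0.16, 0.20, 0.26, 0.31]),
        "epiphysis":  np.array([0.12, 0.14, 0.18, 0.24, 0.29]),
    }
    tb_sp = {
        "base":       np.array([0.55, 0.55, 0.55, 0.57, 0.65]),
        "metaphysis": np.array([0.55, 0.55, 0.55, 0.57, 0.66]),
        "epiphysis":  np.array([0.52, 0.52, 0.53, 0.55, 0.62]),
    }
    da = {
        "base":       np.array([0.33, 0.33, 0.34, 0.34, 0.35]),
        "metaphysis": np.array([0.34, 0.34, 0.34, 0.35, 0.36]),
        "epiphysis":  np.array([0.32, 0.32, 0.33, 0.33, 0.34]),
    }
    means: dict[str, dict[str, np.ndarray]] = {}
    sds: dict[str, dict[str, np.ndarray]] = {}
    for region in REGIONS:
        m_bv = bvtv[region] + species_offset
        m_th = tb_th[region]
        m_sp = tb_sp[region]
        if not age_effect:
            m_bv = np.full(5, m_bv[2])
            m_th = np.full(5, m_th[2])
            m_sp = np.full(5, m_sp[2])
        m_da = da[region] if age_effect else np.full(5, da[region][2])
        means[region] = {
            "bvtv": m_bv, "tb_th": m_th, "tb_sp": m_sp,
            "tb_n": 1.0 / (m_th + m_sp), "da": m_da,
        }
        sds[region] = {
            "bvtv": np.full(5, 0.035), "tb_th": np.full(5, 0.02),
            "tb_sp": np.full(5, 0.05), "tb_n": np.full(5, 0.0),
            "da": np.full(5, 0.04),
        }
    return AgeTrajectory(
        means=means,
        sds=sds,
        epiphysis_present=np.array([0.0, 0.11, 0.5, 0.78, 1.0]),
        gradient=np.array([0.35, 0.35, 0.25, 0.0, -0.35]),
    )


# ---------------------------------------------------------------------------
# synthetic metacarpals
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpecimen:
    """A synthetic whole-bone volume with voxel-level phase truth.

    ``volume`` is the 8-bit greyscale image (blurred, noisy), ``labels``
    the co-registered phase truth (0 background, 1 cortex, 2 trabecular
    bone, 3 marrow).  ``truth`` maps region name to its
    :class:`GroundTruth`; BV/TV there is exact by construction, thickness
    values are the trajectory's nominal means.  ``region_slices`` are the
    generator's half-open proximodistal slice intervals; ``gap_center``
    the growth-plate slice for unfused specimens (None when fused or
    epiphysis absent).
    """

    volume: VoxelVolume
    labels: VoxelVolume
    truth: dict[str, GroundTruth]
    metadata: dict
    region_slices: dict[str, tuple[int, int]]
    gap_center: int | None
    epiphysis_present: bool
    gradient: float


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _graded_fill(field: np.ndarray, interior: np.ndarray, target: float,
                 gradient: float, n_slabs: int = 6) -> np.ndarray:
    """Threshold `field` inside `interior` so the fill fraction equals
    `target` overall, with a linear dorsopalmar ramp of relative amplitude
    `gradient` (positive = palmar-high; axis 1 index increases palmarly)."""
    fill = np.zeros_like(interior, dtype=bool)
    idx = np.nonzero(interior)
    if idx[0].size == 0:
        return fill
    if abs(gradient) < 1e-12:
        vals = field[idx]
        thr = np.quantile(vals, 1.0 - target)
        fill[idx] = field[idx] > thr
        return fill
    y = idx[1].astype(float)
    ylo, yhi = y.min(), y.max()
    span = max(yhi - ylo, 1.0)
    edges = np.linspace(ylo, yhi + 1e-9, n_slabs + 1)
    slab = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, n_slabs - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    s = 2.0 * (centers - ylo) / span - 1.0  # [-1, 1], increasing palmarly
    counts = np.bincount(slab, minlength=n_slabs).astype(float)
    # weighted de-mean so the region-wide fraction stays exactly `target`
    used = counts > 0
    s_mean = np.average(s[used], weights=counts[used])
    targets = np.clip(target * (1.0 + gradient * (s - s_mean)), 0.01, 0.98)
    # renormalise after clipping
    achieved = np.average(targets[used], weights=counts[used])
    targets = np.clip(targets * (target / achieved), 0.01, 0.98)
    for k in range(n_slabs):
        sel = slab == k
        if not sel.any():
            continue
        vals = field[idx[0][sel], idx[1][sel], idx[2][sel]]
        thr = np.quantile(vals, 1.0 - targets[k])
        fill[idx[0][sel], idx[1][sel], idx[2][sel]] = vals > thr
    return fill


def make_synthetic_metacarpal(
    age_months: float,
    params: AgeTrajectory | None = None,
    seed: int = 0,
    voxel_size: float | None = None,
    targets: dict[str, dict[str, float]] | None = None,
    blur_sigma: float = 0.7,
    noise_sd: float = 6.0,
    gap_halfwidth: int = 1,
) -> SyntheticSpecimen:
    """Generate a miniature metacarpal-like volume for one specimen.

    The bone is an elongated solid of revolution-like shape (elliptical
    cross-sections, flared base and head, narrow shaft) with a cortical
    shell, trabecular fill in the base, metaphysis and (when ossified)
    epiphysis, and marrow only in the mid-shaft.  Below the fusion age the
    growth plate is an unossified transverse gap of ``2*gap_halfwidth+1``
    slices.  Greyscale is produced from the phase labels by Gaussian blur
    (``blur_sigma`` voxels, emulating partial-volume effects) plus
    additive Gaussian noise.

    ``targets`` optionally overrides the per-region parameter targets
    (otherwise the trajectory means for the specimen's age category are
    used); :func:`make_cohort` uses this to inject between-individual
    noise.  ``voxel_size`` defaults to a size-scaled resolution (smaller
    bones imaged at finer voxels, as scan protocols do), keeping the
    finest structures resolvable at every age.  Deterministic given
    ``seed``.
    """
    if age_months < 0:
        raise ValueError("age_months must be >= 0")
    if params is None:
        params = default_trajectory()
    if voxel_size is None:
        voxel_size = 0.05 + 0.03 * min(age_months, 144.0) / 144.0
    rng = np.random.default_rng(seed)
    cat = params.category_index(age_months)

    if targets is None:
        targets = {r: {p: float(params.means[r][p][cat]) for p in PARAMS}
                   for r in REGIONS}

    p_epi = float(params.epiphysis_present[cat])
    epiphysis_present = bool(rng.random() < p_epi) if 0.0 < p_epi < 1.0 \
        else bool(p_epi >= 1.0)
    fused = age_months >= params.fusion_age_months
    gradient = float(params.gradient[cat])

    # -- geometry (mm), scaled-down whole bone --------------------------------
    length = 10.0 + 6.0 * min(age_months, 144.0) / 144.0
    nz = int(round(length / voxel_size))
    base_r, shaft_r, head_r = 0.21 * length, 0.115 * length, 0.185 * length
    z = (np.arange(nz) + 0.5) / nz
    r_of_z = (shaft_r
              + (base_r - shaft_r) * _logistic((0.22 - z) / 0.05)
              + (head_r - shaft_r) * _logistic((z - 0.70) / 0.05))
    semi_dp = r_of_z * 1.10   # dorsopalmar semi-axis
    cortex = 0.30 + 0.30 * _logistic((z - 0.30) / 0.04) * _logistic((0.62 - z) / 0.04)

    margin = 3
    n1 = 2 * (int(np.ceil(semi_dp.max() / voxel_size)) + margin)
    n2 = 2 * (int(np.ceil(r_of_z.max() * 0.92 / voxel_size)) + margin)
    cy, cx = n1 / 2.0, n2 / 2.0
    Y = (np.arange(n1) - cy)[None, :, None] * voxel_size
    X = (np.arange(n2) - cx)[None, None, :] * voxel_size
    a1 = semi_dp[:, None, None]
    a2 = (r_of_z * 0.92)[:, None, None]
    outer = (Y / a1) ** 2 + (X / a2) ** 2 <= 1.0
    c = cortex[:, None, None]
    in1 = np.maximum(a1 - c, 0.3 * voxel_size)
    in2 = np.maximum(a2 - c, 0.3 * voxel_size)
    interior = (Y / in1) ** 2 + (X / in2) ** 2 <= 1.0
    cortex_mask = outer & ~interior

    # -- region layout along the proximodistal axis ---------------------------
    # without an ossified secondary centre the bone ends at the growth plate
    base_end = int(round(0.25 * nz))
    meta_start = int(round(0.70 * nz))
    gp = int(round(0.84 * nz))
    region_slices: dict[str, tuple[int, int]] = {
        "base": (0, base_end),
        "shaft": (base_end, meta_start),
    }
    if epiphysis_present:
        region_slices["metaphysis"] = (meta_start, gp)
        region_slices["epiphysis"] = (gp, nz)
    else:
        region_slices["metaphysis"] = (meta_start, gp)

    # -- trabecular fill ------------------------------------------------------
    tb_mean = np.mean([targets[r]["tb_th"] for r in REGIONS])
    sig_vox = max(1.2, 0.55 * tb_mean / voxel_size)
    fld = ndimage.gaussian_filter(rng.standard_normal((nz, n1, n2)), sig_vox)

    fill = np.zeros((nz, n1, n2), dtype=bool)
    zi = np.arange(nz)[:, None, None]
    for region in REGIONS:
        if region not in region_slices:
            continue
        lo, hi = region_slices[region]
        sel = interior & (zi >= lo) & (zi < hi)
        g = gradient if region == "epiphysis" else 0.0
        fill |= _graded_fill(fld, sel, targets[region]["bvtv"], g)

    labels = np.zeros((nz, n1, n2), dtype=np.uint8)
    labels[cortex_mask] = LABEL_CORTEX
    labels[interior & fill] = LABEL_TRABECULAR
    labels[interior & ~fill] = LABEL_MARROW

    # growth-plate gap / missing epiphysis
    gap_center: int | None = None
    if epiphysis_present and not fused:
        gap_center = gp
        labels[gp - gap_halfwidth: gp + gap_halfwidth + 1] = LABEL_BACKGROUND
    elif not epiphysis_present:
        labels[gp:] = LABEL_BACKGROUND  # unossified: nothing distal of the plate

    # -- greyscale ------------------------------------------------------------
    intensity = np.array([25.0, 205.0, 205.0, 80.0])[labels]
    grey = ndimage.gaussian_filter(intensity, blur_sigma)
    grey = grey + rng.normal(0.0, noise_sd, grey.shape)
    grey = np.clip(grey, 0, 255).astype(np.uint8)

    truth = {}
    for region in REGIONS:
        if region == "epiphysis" and not epiphysis_present:
            continue
        t = targets[region]
        truth[region] = GroundTruth(
            bvtv=t["bvtv"], tb_th=t["tb_th"], tb_sp=t["tb_sp"],
            tb_n=1.0 / (t["tb_th"] + t["tb_sp"]), da_class="low")

    meta = {"species": "Ggg", "age_months": float(age_months),
            "sex": "unknown", "seed": int(seed)}
    return SyntheticSpecimen(
        volume=VoxelVolume(grey, voxel_size),
        labels=VoxelVolume(labels, voxel_size),
        truth=truth,
        metadata=meta,
        region_slices=region_slices,
        gap_center=gap_center,
        epiphysis_present=epiphysis_present,
        gradient=gradient,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: per-category sample sizes mirroring the study sample structure
DEFAULT_N_PER_CATEGORY = {"Neonate": 4, "Infant1": 9, "Infant2": 12,
                          "Juvenile": 9, "Adult": 18}

_AGE_RANGES = {"Neonate": (0.0, 6.0), "Infant1": (7.0, 35.0),
               "Infant2": (36.0, 71.0), "Juvenile": (72.0, 143.0),
               "Adult": (144.0, 360.0)}


def _draw_targets(params: AgeTrajectory, cat: int,
                  rng: np.random.Generator) -> dict[str, dict[str, float]]:
    """Per-specimen regional targets: Gaussian noise around trajectory
    means, truncated to valid ranges; Tb.N kept exactly 1/(Tb.Th+Tb.Sp)."""
    out: dict[str, dict[str, float]] = {}
    for region in REGIONS:
        m, s = params.means[region], params.sds[region]
        bv = float(np.clip(rng.normal(m["bvtv"][cat], s["bvtv"][cat]), 0.02, 0.9))
        th = float(np.clip(rng.normal(m["tb_th"][cat], s["tb_th"][cat]), 0.04, 2.0))
        sp = float(np.clip(rng.normal(m["tb_sp"][cat], s["tb_sp"][cat]), 0.05, 5.0))
        da = float(np.clip(rng.normal(m["da"][cat], s["da"][cat]), 0.0, 1.0))
        out[region] = {"bvtv": bv, "tb_th": th, "tb_sp": sp,
                       "tb_n": 1.0 / (th + sp), "da": da}
    return out


def make_cohort(
    n_per_category: dict[str, int] | int | None = None,
    trajectories: dict[str, AgeTrajectory] | None = None,
    seed: int = 0,
    voxel_size: float | None = None,
) -> list[SyntheticSpecimen]:
    """Generate an image-level ontogenetic cohort.

    Specimens are drawn per age category with Gaussian between-individual
    noise around the trajectory means (truncated to valid ranges); species
    alternate between the two tags in ``trajectories`` (default: 'Ggg' and
    'Gbb' sharing one trajectory, i.e. no species effect).  Reproducible
    by ``seed``.
    """
    if n_per_category is None:
        n_per_category = dict(DEFAULT_N_PER_CATEGORY)
    elif isinstance(n_per_category, int):
        n_per_category = {c: n_per_category for c in CATEGORIES}
    if trajectories is None:
        traj = default_trajectory()
        trajectories = {"Ggg": traj, "Gbb": traj}
    species_tags = list(trajectories)

    rng = np.random.default_rng(seed)
    specimens: list[SyntheticSpecimen] = []
    i = 0
    for ci, cat_name in enumerate(CATEGORIES):
        n = int(n_per_category.get(cat_name, 0))
        lo, hi = _AGE_RANGES[cat_name]
        for _ in range(n):
            sp_tag = species_tags[i % len(species_tags)]
            params = trajectories[sp_tag]
            age = float(rng.uniform(lo, hi))
            targets = _draw_targets(params, ci, rng)
            spec_seed = int(rng.integers(0, 2**31 - 1))
            spec = make_synthetic_metacarpal(
                age, params, seed=spec_seed, voxel_size=voxel_size,
                targets=targets)
            spec.metadata["species"] = sp_tag
            spec.metadata["sex"] = "f" if i % 2 == 0 else "m"
            spec.metadata["specimen_id"] = f"SYN{i:03d}"
            specimens.append(spec)
            i += 1
    return specimens


def make_cohort_table(
    n_per_category: dict[str, int] | int | None = None,
    trajectories: dict[str, AgeTrajectory] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a cohort of per-specimen regional summaries, no images.

    Columns: specimen_id, species, sex, age_months, age_category, then
    ``{param}_{region}`` for the five parameters in the three regions.
    Epiphysis columns are NaN when the secondary centre has not ossified
    (probability per category from the trajectory).  This is the fast path
    for statistical simulations needing many cohorts.
    """
    from .stats import assign_age_category

    if n_per_category is None:
        n_per_category = dict(DEFAULT_N_PER_CATEGORY)
    elif isinstance(n_per_category, int):
        n_per_category = {c: n_per_category for c in CATEGORIES}
    if trajectories is None:
        traj = default_trajectory()
        trajectories = {"Ggg": traj, "Gbb": traj}
    species_tags = list(trajectories)

    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for ci, cat_name in enumerate(CATEGORIES):
        n = int(n_per_category.get(cat_name, 0))
        lo, hi = _AGE_RANGES[cat_name]
        for _ in range(n):
            sp_tag = species_tags[i % len(species_tags)]
            params = trajectories[sp_tag]
            age = float(rng.uniform(lo, hi))
            targets = _draw_targets(params, ci, rng)
            p_epi = float(params.epiphysis_present[ci])
            has_epi = rng.random() < p_epi
            row = {"specimen_id": f"SYN{i:03d}", "species": sp_tag,
                   "sex": "f" if i % 2 == 0 else "m",
                   "age_months": age,
                   "age_category": assign_age_category(age)}
            for region in REGIONS:
                for p in PARAMS:
                    val = targets[region][p]
                    if region == "epiphysis" and not has_epi:
                        val = math.nan
                    row[f"{p}_{region}"] = val
            rows.append(row)
            i += 1
    return pd.DataFrame(rows)
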