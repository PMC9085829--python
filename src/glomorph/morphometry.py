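"""Per-glomerulus 3D morphometry from a triangular surface mesh.

A glomerulus is modelled as a round head on a vascular neck.  Three anchor
points define its geometry: the *central base point* (centre of the
attachment where the instance was cut from its parent vessel), the volume
*centroid* of the closed mesh, and the *tip* (the mesh vertex farthest
from the base).  The orientation axis runs from base to centroid.  Mesh
vertices are binned into steps of fixed height along this axis; each
step's cross-section is summarized by the max/min Feret (caliper) width of
its vertices projected onto the plane normal to the axis.  From the
stepped profile come:

* ``L``     — arc length of the polyline through the step centres;
* ``hMax``/``hMin`` — max/min Feret diameter of the thickest step in the
  centroid-to-tip (head) span;
* ``nMax``  — largest step diameter in the neck span between the base and
  the head onset (the narrowest "waist" step below the thickest one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from . import meshing
from .types import SurfaceMesh

__all__ = [
    "AnchorPoints",
    "ProfileStep",
    "SteppedProfile",
    "FeatureRecord",
    "extract_anchor_points",
    "compute_orientation",
    "guess_base_reference",
    "stepped_profile",
    "curve_length_L",
    "head_diameters",
    "neck_diameter_nMax",
    "glomerulus_features",
    "feret_diameters_2d",
]


@dataclass
class AnchorPoints:
    central_base_point: np.ndarray
    centroid: np.ndarray
    tip: np.ndarray

    def __post_init__(self):
        self.central_base_point = np.asarray(self.central_base_point, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.tip = np.asarray(self.tip, dtype=float)


@dataclass
class ProfileStep:
    index: int
    n_vertices: int
    center: np.ndarray          # mean of the step's vertices (µm); NaN if empty
    t_center: float             # projection of the centre onto the axis
    max_diameter: float         # max Feret width of the projected vertices
    min_diameter: float


@dataclass
class SteppedProfile:
    step_height: float
    origin: np.ndarray          # central base point
    axis: np.ndarray            # unit orientation vector
    steps: list[ProfileStep] = field(default_factory=list)

    def nonempty(self) -> list[ProfileStep]:
        return [s for s in self.steps if s.n_vertices > 0]


@dataclass
class FeatureRecord:
    """Morphometry output for one glomerulus (lengths µm, volume µm³)."""

    glomerulus_id: int
    volume_um3: float
    hmax_um: float
    hmin_um: float
    nmax_um: float
    L_um: float
    orientation: np.ndarray
    anchors: AnchorPoints

    def to_dict(self) -> dict:
        return {
            "id": self.glomerulus_id,
            "volume_um3": self.volume_um3,
            "hmax_um": self.hmax_um,
            "hmin_um": self.hmin_um,
            "nmax_um": self.nmax_um,
            "L_um": self.L_um,
            "orientation_z": float(self.orientation[0]),
            "orientation_y": float(self.orientation[1]),
            "orientation_x": float(self.orientation[2]),
        }


# ---------------------------------------------------------------------------
# anchor points and orientation
# ---------------------------------------------------------------------------

def extract_anchor_points(mesh: SurfaceMesh, base_reference=None) -> AnchorPoints:
    """Locate the central base point, volume centroid and tip of a mesh.

    For an *open* mesh (a head cut from its neck attachment) the base is
    the centroid of the longest open boundary loop.  For a closed mesh a
    ``base_reference`` point is required; the base is then the
    area-weighted centre of the face set nearest that reference.
    """
    loops = meshing.boundary_loops(mesh)
    if loops:
        perims = []
        for loop in loops:
            pts = mesh.vertices[loop]
            perims.append(np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1).sum())
        base = mesh.vertices[loops[int(np.argmax(perims))]].mean(axis=0)
        closed = meshing.ensure_closed(mesh)
    else:
        if base_reference is None:
            raise ValueError(
                "mesh is closed and no base reference was supplied; "
                "pass base_reference to locate the central base point"
            )
        closed = mesh if mesh.is_watertight() else meshing.ensure_closed(mesh)
        base = _nearest_face_patch_center(mesh, np.asarray(base_reference, dtype=float))
    centroid = meshing.mesh_volume_centroid(closed)
    d = np.linalg.norm(mesh.vertices - base, axis=1)
    tip = mesh.vertices[int(np.argmax(d))]
    return AnchorPoints(base, centroid, tip)


def _nearest_face_patch_center(mesh: SurfaceMesh, ref: np.ndarray) -> np.ndarray:
    fc = mesh.vertices[mesh.faces].mean(axis=1)
    dist = np.linalg.norm(fc - ref, axis=1)
    edge = mesh.vertices[mesh.faces[:, 0]] - mesh.vertices[mesh.faces[:, 1]]
    tol = np.linalg.norm(edge, axis=1).mean()
    near = dist <= dist.min() + tol
    areas = mesh.triangle_areas()[near]
    if areas.sum() <= 0:
        return fc[near].mean(axis=0)
    return (fc[near] * areas[:, None]).sum(axis=0) / areas.sum()


def guess_base_reference(mesh: SurfaceMesh) -> np.ndarray:
    """Heuristic base point for a closed mesh with no attachment record.

    Takes the mesh's first principal axis and compares the radial spread
    of the vertices in the two end slabs (outer 15% of the axial span);
    the thinner end — for a head-on-neck shape, the neck stump — is taken
    as the base and its vertex centroid returned.
    """
    v = mesh.vertices
    c = v.mean(axis=0)
    d = v - c
    cov = d.T @ d / len(v)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    t = d @ axis
    lo, hi = np.quantile(t, [0.15, 0.85])
    sel_lo, sel_hi = t <= lo, t >= hi
    r_lo = np.linalg.norm(d[sel_lo] - np.outer(t[sel_lo], axis), axis=1).mean()
    r_hi = np.linalg.norm(d[sel_hi] - np.outer(t[sel_hi], axis), axis=1).mean()
    sel = sel_lo if r_lo <= r_hi else sel_hi
    return v[sel].mean(axis=0)


def compute_orientation(anchors: AnchorPoints) -> np.ndarray:
    """Unit vector from the central base point to the centroid."""
    d = anchors.centroid - anchors.central_base_point
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise ValueError("central base point and centroid coincide; orientation undefined")
    return d / n


# ---------------------------------------------------------------------------
# cross-sectional width: exact Feret calipers in 2D
# ---------------------------------------------------------------------------

def feret_diameters_2d(points: np.ndarray) -> tuple[float, float]:
    """(max, min) Feret widths of a 2D point set.

    Max width is the largest pairwise distance between convex-hull
    vertices; min width is the smallest distance between parallel
    supporting lines, attained on a hull edge (rotating calipers).
    Degenerate sets: a single point has widths (0, 0); collinear points
    have min width 0.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0, 0.0
    try:
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except QhullError:  # collinear
        d = pts - pts.mean(axis=0)
        span = np.linalg.norm(d, axis=1)
        i, j = np.argmax(span), np.argmin(-span)
        dmax = float(np.max(np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1))) \
            if len(pts) <= 400 else float(2 * span.max())
        return dmax, 0.0
    diff = hp[:, None, :] - hp[None, :, :]
    dmax = float(np.sqrt((diff**2).sum(axis=-1)).max())
    n = len(hp)
    width = math.inf
    for i in range(n):
        a, b = hp[i], hp[(i + 1) % n]
        e = b - a
        elen = np.linalg.norm(e)
        if elen < 1e-12:
            continue
        normal = np.array([-e[1], e[0]]) / elen
        w = np.abs((hp - a) @ normal).max()
        width = min(width, w)
    if not math.isfinite(width):
        width = 0.0
    return dmax, float(width)


def _plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


# ---------------------------------------------------------------------------
# stepped profile and scalar features
# ---------------------------------------------------------------------------

def stepped_profile(
    mesh: SurfaceMesh,
    orientation: np.ndarray,
    anchors: AnchorPoints,
    step_height: float,
) -> SteppedProfile:
    """Bin mesh vertices into steps along the orientation axis.

    Vertices are projected onto the axis (origin at the central base
    point) and assigned to contiguous bins of ``step_height`` µm.  Each
    non-empty step records its vertex mean and the max/min Feret width of
    the vertices projected onto the plane normal to the axis.  Empty steps
    are kept as explicit gaps.
    """
    axis = np.asarray(orientation, dtype=float)
    axis = axis / np.linalg.norm(axis)
    base = anchors.central_base_point
    extent = float((anchors.tip - base) @ axis)
    if step_height <= 0:
        raise ValueError("step_height must be positive")
    if extent <= 0:
        raise ValueError("tip does not project beyond the base along the orientation")
    if step_height >= extent * (1 + 1e-9) and step_height > extent:
        # a single step covering the whole extent is allowed (degenerate binning)
        pass
    t = (mesh.vertices - base) @ axis
    e1, e2 = _plane_basis(axis)
    uv = np.stack([(mesh.vertices - base) @ e1, (mesh.vertices - base) @ e2], axis=1)
    idx = np.floor(t / step_height).astype(int)
    lo, hi = int(idx.min()), int(idx.max())
    steps: list[ProfileStep] = []
    for k in range(lo, hi + 1):
        sel = idx == k
        n = int(sel.sum())
        if n == 0:
            steps.append(ProfileStep(k, 0, np.full(3, np.nan), math.nan, math.nan, math.nan))
            continue
        center = mesh.vertices[sel].mean(axis=0)
        dmax, dmin = feret_diameters_2d(uv[sel])
        steps.append(ProfileStep(k, n, center, float((center - base) @ axis), dmax, dmin))
    return SteppedProfile(step_height, base, axis, steps)


def curve_length_L(profile: SteppedProfile) -> float:
    """Arc length of the polyline through consecutive non-empty step centres."""
    centers = [s.center for s in profile.nonempty()]
    if len(centers) < 2:
        raise ValueError("curve length needs at least two non-empty steps")
    centers = np.asarray(centers)
    return float(np.linalg.norm(np.diff(centers, axis=0), axis=1).sum())


def _span_steps(profile: SteppedProfile, t_lo: float, t_hi: float) -> list[ProfileStep]:
    return [s for s in profile.nonempty() if t_lo <= s.t_center <= t_hi]


def _thickest_step(steps: list[ProfileStep], t_pref: float) -> ProfileStep:
    """Largest-max-diameter step; ties broken toward ``t_pref``."""
    best = None
    for s in steps:
        if best is None or s.max_diameter > best.max_diameter + 1e-12:
            best = s
        elif abs(s.max_diameter - best.max_diameter) <= 1e-12:
            if abs(s.t_center - t_pref) < abs(best.t_center - t_pref):
                best = s
    return best


def head_diameters(
    profile: SteppedProfile,
    anchors: AnchorPoints,
    orientation: np.ndarray,
    mode: str = "single_step",
) -> tuple[float, float]:
    """(hMin, hMax): diameters of the thickest part of the head span.

    The head span runs from the centroid projection to the tip projection.
    Default mode takes the max and min Feret width of the single thickest
    cross-section; ``mode="span_minmax"`` instead reports the largest max
    width and the smallest min width over the whole span.
    """
    axis = np.asarray(orientation, float)
    t_c = float((anchors.centroid - anchors.central_base_point) @ axis)
    t_t = float((anchors.tip - anchors.central_base_point) @ axis)
    half = 0.5 * profile.step_height
    steps = _span_steps(profile, min(t_c, t_t) - half, max(t_c, t_t) + half)
    if not steps:
        raise ValueError("no non-empty steps in the centroid-to-tip (head) span")
    if mode == "span_minmax":
        return (min(s.min_diameter for s in steps), max(s.max_diameter for s in steps))
    if mode != "single_step":
        raise ValueError(f"unknown head mode {mode!r}")
    best = _thickest_step(steps, t_c)
    return best.min_diameter, best.max_diameter


def neck_diameter_nMax(
    profile: SteppedProfile,
    anchors: AnchorPoints,
    orientation: np.ndarray,
    mode: str = "waist",
    fraction: float = 0.8,
) -> float:
    """Maximum cross-section diameter of the neck span.

    The neck runs from the central base point up to the head onset.  In
    the default ``"waist"`` mode the head onset is the narrowest step
    strictly below the thickest head step — robust when the head is large
    relative to the neck, as for glomeruli.  ``mode="fraction"`` instead
    ends the neck at ``fraction`` × the centroid projection.
    """
    axis = np.asarray(orientation, float)
    t_c = float((anchors.centroid - anchors.central_base_point) @ axis)
    steps = profile.nonempty()
    if not steps:
        raise ValueError("profile has no non-empty steps")
    if mode == "fraction":
        neck = [s for s in steps if s.t_center <= fraction * t_c]
        if not neck:
            raise ValueError("no non-empty steps in the base-to-head (neck) span")
        return max(s.max_diameter for s in neck)
    if mode != "waist":
        raise ValueError(f"unknown neck mode {mode!r}")
    t_t = float((anchors.tip - anchors.central_base_point) @ axis)
    half = 0.5 * profile.step_height
    head_steps = _span_steps(profile, min(t_c, t_t) - half, max(t_c, t_t) + half)
    thickest = _thickest_step(head_steps, t_c) if head_steps else _thickest_step(steps, t_c)
    # neck candidates lie between the base (t >= 0; anything behind the base
    # is the closure cap, not neck) and the thickest head step; steps with
    # fewer than 3 vertices are slivers of the cap and are ignored.
    below = [s for s in steps
             if 0.0 <= s.t_center < thickest.t_center and s.n_vertices >= 3]
    if not below:
        raise ValueError("no non-empty steps below the head; neck span is empty")
    wmin = min(s.max_diameter for s in below)
    # treat widths within 5% of the minimum as ties so the waist sits at the
    # head end of a (noisy) constant-width neck
    waist_t = max(s.t_center for s in below if s.max_diameter <= wmin * 1.05)
    neck = [s for s in below if s.t_center <= waist_t + 1e-12]
    return max(s.max_diameter for s in neck)


# ---------------------------------------------------------------------------
# composite feature extraction
# ---------------------------------------------------------------------------

def glomerulus_features(
    mesh: SurfaceMesh,
    base_reference=None,
    step_height: float = 2.0,
    glomerulus_id: int = 0,
    head_mode: str = "single_step",
    neck_mode: str = "waist",
    neck_fraction: float = 0.8,
    smooth_iterations: int = 0,
    smooth_step: float = 0.1,
) -> FeatureRecord:
    """Full morphometry of one glomerulus mesh.

    Composes hole closing, volume, anchor points, orientation, the stepped
    profile and the head/neck diameters into one record.  Any stage
    failure is re-raised with the stage name prefixed.
    """
    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - surface with stage name
            raise RuntimeError(f"{name}: {exc}") from exc

    anchors = stage("extract_anchor_points", extract_anchor_points, mesh, base_reference)
    closed = mesh if mesh.is_watertight() else stage("ensure_closed", meshing.ensure_closed, mesh)
    if smooth_iterations > 0:
        closed = stage("smooth_curvature_flow", meshing.smooth_curvature_flow,
                       closed, smooth_iterations, smooth_step)
        anchors = AnchorPoints(anchors.central_base_point,
                               meshing.mesh_volume_centroid(closed),
                               anchors.tip)
    volume = stage("mesh_volume", meshing.mesh_volume, closed)
    orientation = stage("compute_orientation", compute_orientation, anchors)
    profile = stage("stepped_profile", stepped_profile, closed, orientation, anchors, step_height)
    hmin, hmax = stage("head_diameters", head_diameters, profile, anchors, orientation, head_mode)
    nmax = stage("neck_diameter_nMax", neck_diameter_nMax, profile, anchors, orientation,
                 neck_mode, neck_fraction)
    L = stage("curve_length_L", curve_length_L, profile)
    return FeatureRecord(glomerulus_id, volume, hmax, hmin, nmax, L, orientation, anchors)
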