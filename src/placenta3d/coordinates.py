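"""Anatomical half-dome frame and (0,1) coordinate normalization.

An implantation site is modeled as a half dome: the decidua occupies the
shell between an inner boundary fitted to the outer edge of the junctional
zone (the placental border, depth 0) and an outer boundary fitted to the
outer edge of the myometrium (depth 1), on the antimesometrial side of a
cutoff plane anchored at the inter-implantation-site luminal epithelium.
Depth is the linear ray parameter between the two fitted surfaces and
continues past 1 into the myometrium on the same axis, so that myometrial
invaders remain on one continuous scale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .errors import EmptyInputError, FrameFitError
from .io import ReferentSet, SpotTable

log = logging.getLogger(__name__)

REGIONS = ("decidua", "myometrium", "outside")


class SphereBoundary:
    """Spherical cap boundary: constant radius in every direction."""

    kind = "sphere"

    def __init__(self, radius: float):
        self.radius = float(radius)

    def __call__(self, frame_dirs: np.ndarray) -> np.ndarray:
        return np.full(len(frame_dirs), self.radius)


class EllipsoidBoundary:
    """Axis-aligned ellipsoidal cap in frame coordinates (axis, e1, e2)."""

    kind = "ellipsoid"

    def __init__(self, semiaxes: np.ndarray):
        self.semiaxes = np.asarray(semiaxes, float)

    def __call__(self, frame_dirs: np.ndarray) -> np.ndarray:
        q = np.sum((frame_dirs / self.semiaxes) ** 2, axis=1)
        return 1.0 / np.sqrt(q)


@dataclass
class HalfDomeFrame:
    """Fitted anatomical frame mapping raw um coordinates to normalized ones.

    ``axis`` points mesometrial -> antimesometrial (toward the dome apex);
    ``e1`` (unit, orthogonal to axis) fixes azimuth zero on the front plane;
    ``e2 = axis x e1``. ``origin`` is the shared center of the fitted caps.
    The mesometrial cutoff plane passes through ``meso_point`` with normal
    ``axis``; spots on its mesometrial side are excluded by filtering.
    """

    origin: np.ndarray
    axis: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    jz_boundary: SphereBoundary | EllipsoidBoundary
    myo_boundary: SphereBoundary | EllipsoidBoundary
    meso_point: np.ndarray
    d_max_allowed: float = 1.5
    residuals: dict = field(default_factory=dict)

    def frame_dirs(self, xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Radial distance and unit direction (in frame coordinates) of points."""
        v = np.atleast_2d(xyz) - self.origin
        r = np.linalg.norm(v, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = v / r[:, None]
        basis = np.stack([self.axis, self.e1, self.e2], axis=1)  # world -> frame
        return r, u @ basis

    def boundary_radii(self, frame_dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.jz_boundary(frame_dirs), self.myo_boundary(frame_dirs)

    def depth(self, xyz: np.ndarray) -> np.ndarray:
        """Normalized depth d: 0 on the junctional-zone surface, 1 on the
        myometrium outer surface, linear along each ray from the origin."""
        r, fd = self.frame_dirs(xyz)
        r_jz, r_myo = self.boundary_radii(fd)
        return (r - r_jz) / (r_myo - r_jz)

    def shell_thickness(self, xyz: np.ndarray) -> np.ndarray:
        """Local decidual shell thickness (um) along each point's ray."""
        _, fd = self.frame_dirs(xyz)
        r_jz, r_myo = self.boundary_radii(fd)
        return r_myo - r_jz

    def mesometrial_side(self, xyz: np.ndarray) -> np.ndarray:
        """True for points on the mesometrial side of the cutoff plane."""
        return (np.atleast_2d(xyz) - self.meso_point) @ self.axis < 0

    def surface_points(
        self, which: str, n: int = 2000, rng_dirs: np.ndarray | None = None
    ) -> np.ndarray:
        """Sample points on a fitted boundary surface over the half dome.

        Uses a Fibonacci lattice on the upper (antimesometrial) hemisphere
        unless explicit frame-coordinate directions are supplied.
        """
        if rng_dirs is None:
            k = np.arange(n)
            cos_t = 1.0 - k / max(n - 1, 1)  # upper hemisphere: cos in (0, 1]
            sin_t = np.sqrt(np.clip(1 - cos_t**2, 0, 1))
            phi = np.pi * (3 - np.sqrt(5)) * k
            rng_dirs = np.stack(
                [cos_t, sin_t * np.cos(phi), sin_t * np.sin(phi)], axis=1
            )
        boundary = self.jz_boundary if which == "jz" else self.myo_boundary
        radii = boundary(rng_dirs)
        world = (
            rng_dirs[:, 0:1] * self.axis
            + rng_dirs[:, 1:2] * self.e1
            + rng_dirs[:, 2:3] * self.e2
        )
        return self.origin + world * radii[:, None]


def _fit_shared_center(
    jz: np.ndarray, myo: np.ndarray, model: str
) -> tuple[np.ndarray, object, object, dict]:
    """Least-squares fit of two concentric caps (shared center) to the
    boundary referents. Returns center, inner boundary, outer boundary,
    and residual report."""
    # algebraic sphere-fit initialisation on the outer (myometrium) points:
    # |p|^2 - 2 p.c = r^2 - |c|^2 is linear in (c, t)
    A = np.hstack([2 * myo, np.ones((len(myo), 1))])
    b = np.sum(myo**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:3]
    r_jz0 = float(np.mean(np.linalg.norm(jz - c0, axis=1)))
    r_myo0 = float(np.mean(np.linalg.norm(myo - c0, axis=1)))

    def sphere_resid(params):
        c, r1, r2 = params[:3], params[3], params[4]
        return np.concatenate(
            [np.linalg.norm(jz - c, axis=1) - r1, np.linalg.norm(myo - c, axis=1) - r2]
        )

    fit = least_squares(sphere_resid, np.r_[c0, r_jz0, r_myo0], method="lm")
    center = fit.x[:3]
    if model == "sphere":
        inner = SphereBoundary(fit.x[3])
        outer = SphereBoundary(fit.x[4])
        res = sphere_resid(fit.x)
    else:
        raise ValueError(f"unknown boundary model {model!r}")
    report = {
        "max_residual_um": float(np.max(np.abs(res))),
        "rms_residual_um": float(np.sqrt(np.mean(res**2))),
    }
    return center, inner, outer, report


def _fit_ellipsoid_boundaries(
    jz: np.ndarray, myo: np.ndarray, center: np.ndarray, basis: np.ndarray
) -> tuple[np.ndarray, EllipsoidBoundary, EllipsoidBoundary, dict]:
    """Refine a shared-center fit with independent axis-aligned ellipsoids."""

    def resid(params):
        c = params[:3]
        a = params[3:6]
        b = params[6:9]
        out = []
        for pts, semi in ((jz, a), (myo, b)):
            v = (pts - c) @ basis
            r = np.linalg.norm(v, axis=1)
            u = v / r[:, None]
            model_r = 1.0 / np.sqrt(np.sum((u / semi) ** 2, axis=1))
            out.append(r - model_r)
        return np.concatenate(out)

    r1 = float(np.mean(np.linalg.norm(jz - center, axis=1)))
    r2 = float(np.mean(np.linalg.norm(myo - center, axis=1)))
    x0 = np.r_[center, [r1] * 3, [r2] * 3]
    fit = least_squares(resid, x0, method="lm")
    res = resid(fit.x)
    report = {
        "max_residual_um": float(np.max(np.abs(res))),
        "rms_residual_um": float(np.sqrt(np.mean(res**2))),
    }
    return fit.x[:3], EllipsoidBoundary(fit.x[3:6]), EllipsoidBoundary(fit.x[6:9]), report


def fit_half_dome_frame(
    referents: ReferentSet,
    boundary_model: str = "sphere",
    d_max_allowed: float = 1.5,
) -> HalfDomeFrame:
    """Fit the half-dome anatomical frame from labelled referents.

    The dome axis runs from the centroid of the luminal-epithelium referents
    (mesometrial side) through the centroid of the junctional-zone referents;
    front/back referents fix azimuth zero; boundary caps are least-squares
    fits with a shared center. Deterministic for fixed input.
    """
    jz = referents.points("junctional_zone_outer")
    myo = referents.points("myometrium_outer")
    lum = referents.points("luminal_epithelium")
    front = referents.points("front")
    back = referents.points("back")

    axis = jz.mean(axis=0) - lum.mean(axis=0)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise FrameFitError("luminal-epithelium and junctional-zone centroids coincide")
    axis = axis / norm

    center, inner, outer, report = _fit_shared_center(jz, myo, "sphere")

    # front direction orthogonal to the axis, from front/back referents
    f = front.mean(axis=0) - center
    f = f - (f @ axis) * axis
    fn = np.linalg.norm(f)
    if fn < 1e-9:
        # fall back on the front-back chord if front sits on the axis
        f = front.mean(axis=0) - back.mean(axis=0)
        f = f - (f @ axis) * axis
        fn = np.linalg.norm(f)
        if fn < 1e-9:
            raise FrameFitError("front/back referents do not define an azimuth plane")
    e1 = f / fn
    e2 = np.cross(axis, e1)
    basis = np.stack([axis, e1, e2], axis=1)

    if boundary_model == "ellipsoid":
        center, inner, outer, report = _fit_ellipsoid_boundaries(jz, myo, center, basis)
    elif boundary_model != "sphere":
        raise ValueError(f"boundary_model must be 'sphere' or 'ellipsoid', got {boundary_model!r}")

    frame = HalfDomeFrame(
        origin=np.asarray(center, float),
        axis=axis,
        e1=e1,
        e2=e2,
        jz_boundary=inner,
        myo_boundary=outer,
        meso_point=lum.mean(axis=0),
        d_max_allowed=d_max_allowed,
        residuals=report,
    )

    # outer boundary must enclose the inner one over the half dome
    probe = frame.surface_points("jz", n=500)
    _, fd = frame.frame_dirs(probe)
    r_in, r_out = frame.boundary_radii(fd)
    if not np.all(r_out > r_in) or np.any(r_in < 0):
        raise FrameFitError(
            "degenerate geometry: outer boundary does not enclose inner boundary "
            f"(residual report: {report})"
        )
    return frame


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`filter_spots`."""

    n_input: int
    n_removed_volume: int
    n_removed_mesometrial: int
    n_retained: int
    min_volume_um3: float
    volume_filter_applied: bool


def filter_spots(
    spots: SpotTable, min_volume: float, frame: HalfDomeFrame
) -> tuple[SpotTable, FilterReport]:
    """Remove sub-resolution spots and mesometrial spots.

    A spot is kept iff its volume is >= ``min_volume`` (inclusive floor;
    spots with no recorded volume pass with a warning) and it lies on the
    antimesometrial side of the mesometrial cutoff plane. A spot failing
    both rules is counted under the volume rule.
    """
    if min_volume < 0:
        raise ValueError("min_volume must be >= 0")
    df = spots.data
    vol = df["volume"]
    has_volume = vol.notna().any()
    if not has_volume:
        log.warning("no volume information: volume filter is a no-op")
        vol_ok = pd.Series(True, index=df.index)
    else:
        vol_ok = vol.isna() | (vol >= min_volume)
    meso = pd.Series(frame.mesometrial_side(df[["x", "y", "z"]].to_numpy(float)), index=df.index)
    keep = vol_ok & ~meso
    report = FilterReport(
        n_input=len(df),
        n_removed_volume=int((~vol_ok).sum()),
        n_removed_mesometrial=int((vol_ok & meso).sum()),
        n_retained=int(keep.sum()),
        min_volume_um3=float(min_volume),
        volume_filter_applied=bool(has_volume),
    )
    if report.n_retained == 0:
        log.warning("filter_spots removed every spot (%s)", report)
    return SpotTable(df.loc[keep].reset_index(drop=True), spots.rejected), report


@dataclass
class NormalizedPoints:
    """Spots mapped into the half-dome frame.

    ``data`` columns: spot_id, channel, x/y/z (raw um, carried over),
    depth d (0 = junctional-zone outer edge, 1 = myometrium outer edge),
    azimuth u in [0,1) with u = 0 on the front plane, polar v (0 apex ->
    1 equator), and a region flag in {decidua, myometrium, outside}.
    Points whose direction was undefined (at the frame origin) are in
    ``excluded`` with a diagnostic.
    """

    data: pd.DataFrame
    frame: HalfDomeFrame
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.data)

    def channel(self, channel: str) -> "NormalizedPoints":
        return NormalizedPoints(
            self.data[self.data["channel"] == channel].reset_index(drop=True), self.frame
        )

    def in_domain(self) -> pd.DataFrame:
        return self.data[self.data["region"].isin(("decidua", "myometrium"))]

    def coords(self) -> np.ndarray:
        return self.data[["x", "y", "z"]].to_numpy(float)

    def dome_coords(self, regions=("decidua", "myometrium")) -> np.ndarray:
        """Normalized Cartesian embedding for density estimation.

        Each in-domain point maps to ``unit_direction * (1 + depth)`` so the
        junctional-zone surface becomes the unit hemisphere and the
        myometrium outer surface radius 2; angular structure is preserved
        while radial extent is normalized across sites.
        """
        df = self.data[self.data["region"].isin(regions)]
        xyz = df[["x", "y", "z"]].to_numpy(float)
        _, fd = self.frame.frame_dirs(xyz)
        return fd * (1.0 + df["depth"].to_numpy(float))[:, None]


def normalize_points(spots: SpotTable, frame: HalfDomeFrame) -> NormalizedPoints:
    """Map filtered spots to normalized half-dome coordinates.

    depth d = (r - r_jz(dir)) / (r_myo(dir) - r_jz(dir)) along the point's
    ray from the origin. Region flags: decidua for 0 <= d < 1, myometrium
    for 1 <= d <= d_max_allowed (the tie at exactly 1 is myometrial), both
    requiring the point to lie inside the half-dome solid angle; everything
    else is "outside". Flags are exhaustive and mutually exclusive.
    """
    df = spots.data
    xyz = df[["x", "y", "z"]].to_numpy(float)
    r, fd = frame.frame_dirs(xyz)

    at_origin = r == 0
    excluded = df.loc[at_origin].copy()
    if len(excluded):
        excluded["reason"] = "point at frame origin: direction undefined"
        log.warning("normalize_points: excluded %d point(s) at the frame origin", len(excluded))
    ok = ~at_origin
    df = df.loc[ok].reset_index(drop=True)
    r, fd = r[ok], fd[ok]

    r_jz, r_myo = frame.boundary_radii(fd)
    d = (r - r_jz) / (r_myo - r_jz)
    cos_t = np.clip(fd[:, 0], -1.0, 1.0)
    u = np.mod(np.arctan2(fd[:, 2], fd[:, 1]) / (2 * np.pi), 1.0)
    v = np.arccos(cos_t) / (np.pi / 2)

    in_cap = cos_t >= 0
    region = np.full(len(df), "outside", dtype=object)
    region[in_cap & (d >= 0) & (d < 1)] = "decidua"
    region[in_cap & (d >= 1) & (d <= frame.d_max_allowed)] = "myometrium"

    out = pd.DataFrame(
        {
            "spot_id": df["spot_id"].to_numpy(),
            "channel": df["channel"].to_numpy(),
            "x": df["x"].to_numpy(float),
            "y": df["y"].to_numpy(float),
            "z": df["z"].to_numpy(float),
            "depth": d,
            "azimuth": u,
            "polar": v,
            "region": region,
        }
    )
    return NormalizedPoints(out, frame, excluded)


@dataclass
class Depth2DResult:
    """Relative depths of objects in one planar section."""

    depths: np.ndarray  # per object, clipped to [0, 1]
    n_clipped: int
    scale_um: float  # the distance normalized to 1


def relative_depth_2d(
    objects: np.ndarray, border: np.ndarray, myometrium: np.ndarray
) -> Depth2DResult:
    """Relative depth of objects in a planar section.

    depth = (minimum distance to the placental-border point set) divided by
    the maximum over myometrium points of their minimum distance to the
    border (the farthest placenta-to-myometrium separation defines 1).
    Values beyond 1 are clipped and reported.
    """
    objects = np.atleast_2d(np.asarray(objects, float))
    border = np.atleast_2d(np.asarray(border, float))
    myometrium = np.atleast_2d(np.asarray(myometrium, float))
    if border.size == 0 or myometrium.size == 0:
        raise EmptyInputError("border and myometrium reference sets must be non-empty")
    d_obj = cdist(objects, border).min(axis=1)
    scale = cdist(myometrium, border).min(axis=1).max()
    if scale == 0:
        raise EmptyInputError("degenerate section: myometrium coincides with border")
    depths = d_obj / scale
    n_clipped = int((depths > 1).sum())
    return Depth2DResult(np.clip(depths, 0.0, 1.0), n_clipped, float(scale))
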