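"""Trophoblast localization, invasion depth, artery metrics, and the
virtual 2D-section vs 3D comparison.

Localization classes follow the four-way rule used for light-sheet
quantification: a trophoblast in the decidua (depth < 1) is
"spiral_artery_adjacent" when within an adjacency radius of an artery and
"interstitial" otherwise; one in the myometrium (depth >= 1) is
"myometrial_artery_adjacent" or "myometrial_stromal" by the same distance
rule. Artery metrics operate on centerline trees resampled at uniform arc
length.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .coordinates import HalfDomeFrame, NormalizedPoints, relative_depth_2d
from .errors import EmptyInputError
from .io import CenterlineTree

log = logging.getLogger(__name__)

CATEGORIES = (
    "spiral_artery_adjacent",
    "interstitial",
    "myometrial_stromal",
    "myometrial_artery_adjacent",
)


@dataclass
class LocalizationBreakdown:
    """Counts and fractions of trophoblasts per localization category.

    Fractions are over classified (in-domain) trophoblasts and sum to 1.
    ``labels`` carries the per-point category, indexed like the classified
    subset of the input, for downstream tests and reports.
    """

    counts: dict[str, int]
    fractions: dict[str, float]
    n_classified: int
    n_outside: int
    r_adj_um: float
    site_id: str = "site"
    labels: pd.Series = field(default_factory=lambda: pd.Series(dtype=object), repr=False)

    def to_rows(self) -> list[dict]:
        return [
            {
                "category": c,
                "count": self.counts[c],
                "fraction": self.fractions[c],
                "r_adj_um": self.r_adj_um,
                "site_id": self.site_id,
            }
            for c in CATEGORIES
        ]


def classify_trophoblasts(
    trophoblasts: NormalizedPoints,
    artery_points_um: np.ndarray,
    r_adj: float = 20.0,
    site_id: str = "site",
) -> LocalizationBreakdown:
    """Four-way exhaustive classification of in-domain trophoblasts.

    Region comes from the normalized depth flag (decidua d < 1, myometrium
    1 <= d <= d_max); artery adjacency is a raw-um Euclidean distance of at
    most ``r_adj`` to any artery reference point (centerline samples or
    artery spots). With no artery points, everything falls in the
    non-adjacent categories with a warning.
    """
    if r_adj <= 0:
        raise ValueError("r_adj must be > 0")
    df = trophoblasts.in_domain()
    artery_points_um = np.atleast_2d(np.asarray(artery_points_um, float))
    if artery_points_um.size == 0:
        log.warning("classify_trophoblasts: no artery points; all classed non-adjacent")
        adjacent = np.zeros(len(df), bool)
    else:
        tree = cKDTree(artery_points_um)
        dist, _ = tree.query(df[["x", "y", "z"]].to_numpy(float), k=1)
        adjacent = dist <= r_adj
    in_myo = (df["region"] == "myometrium").to_numpy()

    labels = np.where(
        in_myo,
        np.where(adjacent, "myometrial_artery_adjacent", "myometrial_stromal"),
        np.where(adjacent, "spiral_artery_adjacent", "interstitial"),
    )
    labels = pd.Series(labels, index=df.index, name="category")
    counts = {c: int((labels == c).sum()) for c in CATEGORIES}
    n = len(labels)
    fractions = {c: (counts[c] / n if n else 0.0) for c in CATEGORIES}
    n_outside = len(trophoblasts) - n
    return LocalizationBreakdown(
        counts=counts,
        fractions=fractions,
        n_classified=n,
        n_outside=n_outside,
        r_adj_um=float(r_adj),
        site_id=site_id,
        labels=labels,
    )


@dataclass
class InvasionSummary:
    """Per-site summary of trophoblast invasion depth."""

    depths: np.ndarray  # per classified trophoblast, normalized
    max_depth: float
    myometrial_fraction: float  # fraction with depth >= 1
    n: int
    site_id: str = "site"
    empty: bool = False


def invasion_summary(trophoblasts: NormalizedPoints, site_id: str = "site") -> InvasionSummary:
    """Maximum normalized invasion depth and myometrial-invader fraction.

    Zero in-domain trophoblasts yield an explicit empty marker rather than
    a zero summary.
    """
    d = trophoblasts.in_domain()["depth"].to_numpy(float)
    if len(d) == 0:
        return InvasionSummary(
            depths=d, max_depth=float("nan"), myometrial_fraction=float("nan"),
            n=0, site_id=site_id, empty=True,
        )
    return InvasionSummary(
        depths=d,
        max_depth=float(d.max()),
        myometrial_fraction=float((d >= 1).mean()),
        n=len(d),
        site_id=site_id,
    )


def resample_centerline(tree: CenterlineTree, step: float = 10.0) -> np.ndarray:
    """Sample a tree's polyline edges at ~uniform arc-length spacing (um).

    Each parent->child segment is subdivided into ceil(len/step) pieces;
    segment endpoints are included once. Distances measured point-to-sample
    downstream are therefore accurate to about step/2.
    """
    xyz = tree.node_xyz()
    samples = [xyz[tree.root_id]]
    for p, c in tree.edges():
        a, b = xyz[p], xyz[c]
        length = float(np.linalg.norm(b - a))
        k = max(int(np.ceil(length / step)), 1)
        t = np.arange(1, k + 1) / k
        samples.extend(a + (b - a) * ti for ti in t)
    return np.asarray(samples, float)


def count_decidual_branches(trees: list[CenterlineTree], frame: HalfDomeFrame) -> int:
    """Count artery branches entering the decidua from the myometrium.

    A branch entry is an edge whose parent sits at depth >= 1 and whose
    child at depth < 1, counted only when no ancestor edge already entered
    (multiple crossings of one path count once; a myometrial bifurcation
    descending twice counts twice). A tree entirely inside the decidua has
    no myometrial anchor and contributes 0 with a warning.
    """
    total = 0
    for tree in trees:
        depth = dict(zip(tree.nodes["node_id"].astype(int), frame.depth(tree.coords())))
        if all(v < 1 for v in depth.values()):
            log.warning("tree %s lies entirely inside the decidua (no myometrial anchor)", tree.tree_id)
            continue
        children = tree.children()
        # DFS tracking whether an ancestor edge already crossed inward
        stack = [(tree.root_id, False)]
        while stack:
            node, crossed = stack.pop()
            for child in children[node]:
                entering = depth[node] >= 1 > depth[child]
                if entering and not crossed:
                    total += 1
                stack.append((child, crossed or entering))
    return total


@dataclass
class ArteryMetrics:
    """Branch, envelopment, and placental-connection metrics for one site."""

    n_branches_entering_decidua: int
    n_enveloped: int
    n_arteries_with_decidual_segment: int
    envelopment_fractions: dict[str, float]  # per artery (tree_id)
    n_connected_to_placenta: int
    r_env_um: float
    coverage_threshold: float
    connection_tolerance_um: float
    excluded_trees: list[str] = field(default_factory=list)
    site_id: str = "site"


def envelopment(
    trees: list[CenterlineTree],
    trophoblast_points_um: np.ndarray,
    frame: HalfDomeFrame,
    r_env: float = 20.0,
    coverage_threshold: float = 0.5,
    step: float = 10.0,
) -> tuple[dict[str, float], int, list[str]]:
    """Per-artery trophoblast envelopment along the decidual centerline.

    envelopment_fraction = fraction of an artery's decidual centerline
    samples with at least one trophoblast within ``r_env``; an artery is
    enveloped when the fraction reaches ``coverage_threshold`` ("through
    most of its length" reads as one half by default). Arteries with no
    decidual segment are excluded from the denominator.
    Returns (per-artery fractions, n_enveloped, excluded tree ids).
    """
    if r_env <= 0:
        raise ValueError("r_env must be > 0")
    if not 0 < coverage_threshold <= 1:
        raise ValueError("coverage_threshold must be in (0, 1]")
    trophoblast_points_um = np.atleast_2d(np.asarray(trophoblast_points_um, float))
    ttree = cKDTree(trophoblast_points_um) if trophoblast_points_um.size else None
    fractions: dict[str, float] = {}
    excluded: list[str] = []
    n_env = 0
    for tree in trees:
        samples = resample_centerline(tree, step)
        d = frame.depth(samples)
        decidual = samples[(d >= 0) & (d < 1)]
        if len(decidual) == 0:
            excluded.append(tree.tree_id)
            continue
        if ttree is None:
            frac = 0.0
        else:
            dist, _ = ttree.query(decidual, k=1)
            frac = float((dist <= r_env).mean())
        fractions[tree.tree_id] = frac
        if frac >= coverage_threshold:
            n_env += 1
    return fractions, n_env, excluded


def count_placenta_connected(
    trees: list[CenterlineTree], frame: HalfDomeFrame, tolerance: float = 25.0
) -> int:
    """Count arteries reaching the placental (junctional-zone) surface.

    A tree is connected when at least one terminal node's normalized depth
    is <= tolerance / (local shell thickness), i.e. within ``tolerance`` um
    of depth 0 along its own ray.
    """
    count = 0
    for tree in trees:
        children = tree.children()
        leaf_ids = [i for i, ch in children.items() if not ch and i != tree.root_id]
        if not leaf_ids:
            leaf_ids = [tree.root_id]
        xyz = tree.node_xyz()
        pts = np.array([xyz[i] for i in leaf_ids])
        d = frame.depth(pts)
        thick = frame.shell_thickness(pts)
        if np.any(d <= tolerance / thick):
            count += 1
    return count


def artery_metrics(
    trees: list[CenterlineTree],
    trophoblast_points_um: np.ndarray,
    frame: HalfDomeFrame,
    r_env: float = 20.0,
    coverage_threshold: float = 0.5,
    step: float = 10.0,
    connection_tolerance: float = 25.0,
    site_id: str = "site",
) -> ArteryMetrics:
    """Bundle branch counting, envelopment, and connection counting."""
    fractions, n_env, excluded = envelopment(
        trees, trophoblast_points_um, frame, r_env, coverage_threshold, step
    )
    return ArteryMetrics(
        n_branches_entering_decidua=count_decidual_branches(trees, frame),
        n_enveloped=n_env,
        n_arteries_with_decidual_segment=len(fractions),
        envelopment_fractions=fractions,
        n_connected_to_placenta=count_placenta_connected(trees, frame, connection_tolerance),
        r_env_um=float(r_env),
        coverage_threshold=float(coverage_threshold),
        connection_tolerance_um=float(connection_tolerance),
        excluded_trees=excluded,
        site_id=site_id,
    )


@dataclass
class SectionComparison:
    """Virtual 2D sections against the full 3D invasion depth.

    ``section_max_depths`` holds one relative 2D max depth per offset (NaN
    for empty slabs); the discrepancy ratio is 3D max depth / mean 2D max
    depth, reported only when at least ``min_sections`` sections held a
    trophoblast.
    """

    section_offsets_um: np.ndarray
    section_max_depths: np.ndarray
    slab_thickness_um: float
    max_depth_3d: float
    mean_2d: float
    discrepancy_ratio: float
    n_nonempty: int
    reason: str = ""


def virtual_sections(
    trophoblasts: NormalizedPoints,
    frame: HalfDomeFrame,
    slab_thickness: float = 70.0,
    offsets=(-240.0, -120.0, 0.0, 120.0, 240.0),
    min_sections: int = 3,
    n_surface_samples: int = 4000,
) -> SectionComparison:
    """Emulate midline histological sectioning of the implantation site.

    The midline plane contains the dome axis and the front-back axis; each
    virtual section is a slab of the given thickness offset along the
    plane normal. Objects in a slab are projected into the plane and their
    relative 2D depth computed against the fitted placental-border and
    myometrium surfaces intersected with the slab, mirroring how tissue
    sections are quantified. The 3D reference is the maximum normalized
    invasion depth over the whole site.
    """
    if slab_thickness <= 0:
        raise ValueError("slab_thickness must be > 0")
    summary = invasion_summary(trophoblasts)
    if summary.empty:
        raise EmptyInputError("no in-domain trophoblasts to section")
    df = trophoblasts.in_domain()
    xyz = df[["x", "y", "z"]].to_numpy(float)
    rel = xyz - frame.origin
    coords_n = rel @ frame.e2  # offset along the plane normal
    coords_a = rel @ frame.axis
    coords_b = rel @ frame.e1

    jz_surface = frame.surface_points("jz", n=n_surface_samples)
    myo_surface = frame.surface_points("myo", n=n_surface_samples)

    def in_plane(points: np.ndarray, offset: float):
        rp = points - frame.origin
        off = rp @ frame.e2
        keep = np.abs(off - offset) <= slab_thickness / 2
        return np.stack([rp[keep] @ frame.axis, rp[keep] @ frame.e1], axis=1)

    offsets = np.asarray(offsets, float)
    maxima = np.full(len(offsets), np.nan)
    for k, off in enumerate(offsets):
        keep = np.abs(coords_n - off) <= slab_thickness / 2
        if not keep.any():
            continue
        border2d = in_plane(jz_surface, off)
        myo2d = in_plane(myo_surface, off)
        if len(border2d) == 0 or len(myo2d) == 0:
            continue
        objects2d = np.stack([coords_a[keep], coords_b[keep]], axis=1)
        res = relative_depth_2d(objects2d, border2d, myo2d)
        maxima[k] = float(res.depths.max())

    nonempty = np.isfinite(maxima)
    n_nonempty = int(nonempty.sum())
    if n_nonempty == 0:
        raise EmptyInputError("every virtual section was empty")
    if n_nonempty >= min_sections:
        mean_2d = float(np.nanmean(maxima))
        ratio = float(summary.max_depth / mean_2d)
        reason = ""
    else:
        mean_2d = float("nan")
        ratio = float("nan")
        reason = f"only {n_nonempty} non-empty section(s); {min_sections} required"
    return SectionComparison(
        section_offsets_um=offsets,
        section_max_depths=maxima,
        slab_thickness_um=float(slab_thickness),
        max_depth_3d=float(summary.max_depth),
        mean_2d=mean_2d,
        discrepancy_ratio=ratio,
        n_nonempty=n_nonempty,
        reason=reason,
    )
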