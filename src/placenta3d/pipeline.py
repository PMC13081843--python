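"""End-to-end orchestration: read -> filter -> normalize -> density overlap
-> localization/artery metrics -> virtual sections -> group statistics,
with a run manifest for provenance.

Every omitted result block carries an explicit reason; re-running with the
same inputs, config, and seed reproduces every number bit-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .coordinates import (
    FilterReport,
    HalfDomeFrame,
    NormalizedPoints,
    filter_spots,
    fit_half_dome_frame,
    normalize_points,
)
from .density import OverlapResult, bootstrap_overlap
from .errors import ConfigError, EmptyInputError, Placenta3DError
from .io import (
    CenterlineTree,
    ReferentSet,
    SpotTable,
    read_centerline_trees,
    read_referents,
    read_spot_table,
)
from .metrics import (
    ArteryMetrics,
    InvasionSummary,
    LocalizationBreakdown,
    SectionComparison,
    artery_metrics,
    classify_trophoblasts,
    invasion_summary,
    resample_centerline,
    virtual_sections,
)
from .stats import GroupCompareReport, group_compare

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable analysis parameters, logged into every result."""

    boundary_model: str = "sphere"  # or "ellipsoid"
    min_volume_um3: float = 100.0
    d_max_allowed: float = 1.5
    bandwidth: object = "scott"
    grid_shape: tuple = (50, 50, 50)
    n_boot: int = 1000
    ci_level: float = 0.95
    r_adj_um: float = 20.0
    r_env_um: float = 20.0
    coverage_threshold: float = 0.5
    centerline_step_um: float = 10.0
    slab_thickness_um: float = 70.0
    section_offsets_um: tuple = (-240.0, -120.0, 0.0, 120.0, 240.0)
    min_sections: int = 3
    connection_tolerance_um: float = 25.0
    group_method: str = "mannwhitney_pairwise"
    correction: str = "bonferroni"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("grid_shape", "section_offsets_um"):
            if key in payload and isinstance(payload[key], list):
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """Provenance record: config snapshot, seeds, input digests, counts."""

    config: dict
    seed: int
    software_version: str
    input_digests: dict[str, str]
    stage_counts: dict[str, int]
    timestamp: float


@dataclass
class SiteReport:
    """All per-site result blocks; omitted blocks carry a reason string."""

    site_id: str
    group: str
    overlap: OverlapResult | None
    localization: LocalizationBreakdown | None
    invasion: InvasionSummary | None
    arteries: ArteryMetrics | None
    sections: SectionComparison | None
    filter_report: FilterReport
    manifest: RunManifest
    omitted: dict[str, str] = field(default_factory=dict)

    def summary(self) -> dict:
        """Scalar summary used for JSON reports and group comparisons.

        Deterministic: carries no timestamps."""
        out: dict = {"site_id": self.site_id, "group": self.group, "omitted": self.omitted}
        if self.overlap is not None:
            out["bc_point"] = self.overlap.bc_point
            out["bc_median"] = self.overlap.bootstrap_median
            out["bc_ci"] = [self.overlap.ci_low, self.overlap.ci_high]
        if self.localization is not None:
            out["localization_counts"] = self.localization.counts
            out["localization_fractions"] = self.localization.fractions
        if self.invasion is not None and not self.invasion.empty:
            out["max_depth_3d"] = self.invasion.max_depth
            out["myometrial_fraction"] = self.invasion.myometrial_fraction
        if self.arteries is not None:
            out["n_branches_entering_decidua"] = self.arteries.n_branches_entering_decidua
            out["n_enveloped"] = self.arteries.n_enveloped
            out["n_connected_to_placenta"] = self.arteries.n_connected_to_placenta
        if self.sections is not None:
            out["section_max_depths"] = [
                None if not np.isfinite(v) else float(v)
                for v in self.sections.section_max_depths
            ]
            out["discrepancy_ratio"] = (
                None if not np.isfinite(self.sections.discrepancy_ratio)
                else self.sections.discrepancy_ratio
            )
        return out


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_site(
    spots: "SpotTable | str | Path",
    referents: "ReferentSet | str | Path",
    trees: "list[CenterlineTree] | str | Path | None" = None,
    config: PipelineConfig | None = None,
    site_id: str = "site",
    group: str = "na",
) -> SiteReport:
    """Run the full per-site analysis.

    Accepts in-memory objects or file paths (spot table, referent file,
    optional SWC centerline file). Stage errors propagate with the stage
    name and site id; optional inputs degrade to omitted blocks with an
    explicit reason.
    """
    config = config or PipelineConfig()
    digests: dict[str, str] = {}
    if not isinstance(spots, SpotTable):
        digests["spots"] = _digest(spots)
        spots = read_spot_table(spots, site_id=site_id, group=group)
    if not isinstance(referents, ReferentSet):
        digests["referents"] = _digest(referents)
        referents = read_referents(referents, site_id=site_id)
    if trees is not None and not isinstance(trees, list):
        digests["trees"] = _digest(trees)
        trees = read_centerline_trees(trees, site_id=site_id)

    omitted: dict[str, str] = {}

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Placenta3DError as exc:
            raise type(exc)(f"[site {site_id}, stage {name}] {exc}") from exc

    frame = stage("fit_frame", fit_half_dome_frame, referents,
                  config.boundary_model, config.d_max_allowed)
    filtered, filt_report = stage("filter", filter_spots, spots,
                                  config.min_volume_um3, frame)
    norm = stage("normalize", normalize_points, filtered, frame)
    troph = norm.channel("trophoblast")
    artery = norm.channel("artery")

    # density overlap of the two channels in normalized dome coordinates
    overlap = None
    a_pts = artery.dome_coords()
    t_pts = troph.dome_coords()
    if len(a_pts) < 2 or len(t_pts) < 2:
        omitted["overlap"] = (
            f"needs >= 2 in-domain points per channel (artery {len(a_pts)}, "
            f"trophoblast {len(t_pts)})"
        )
    else:
        overlap = stage(
            "overlap", bootstrap_overlap, a_pts, t_pts,
            n_boot=config.n_boot, seed=config.seed, bandwidth=config.bandwidth,
            grid_shape=config.grid_shape, ci_level=config.ci_level,
        )

    # artery reference geometry: centerline samples when traced, else spots
    if trees:
        artery_ref = np.vstack(
            [resample_centerline(t, config.centerline_step_um) for t in trees]
        )
    else:
        artery_ref = artery.in_domain()[["x", "y", "z"]].to_numpy(float)

    localization = None
    invasion = None
    sections = None
    if len(troph.in_domain()) == 0:
        omitted["localization"] = "no in-domain trophoblasts"
        omitted["invasion"] = "no in-domain trophoblasts"
        omitted["sections"] = "no in-domain trophoblasts"
    else:
        localization = stage(
            "classify", classify_trophoblasts, troph, artery_ref,
            config.r_adj_um, site_id,
        )
        invasion = stage("invasion", invasion_summary, troph, site_id)
        try:
            sections = virtual_sections(
                troph, frame, config.slab_thickness_um,
                config.section_offsets_um, config.min_sections,
            )
        except EmptyInputError as exc:
            omitted["sections"] = str(exc)

    arteries = None
    if trees:
        troph_um = troph.in_domain()[["x", "y", "z"]].to_numpy(float)
        arteries = stage(
            "artery_metrics", artery_metrics, trees, troph_um, frame,
            config.r_env_um, config.coverage_threshold,
            config.centerline_step_um, config.connection_tolerance_um, site_id,
        )
    else:
        omitted["arteries"] = "no centerline trees provided"

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        software_version=__version__,
        input_digests=digests,
        stage_counts={
            "input_spots": filt_report.n_input,
            "retained_spots": filt_report.n_retained,
            "normalized": len(norm),
            "trophoblasts_in_domain": len(troph.in_domain()),
            "artery_spots_in_domain": len(artery.in_domain()),
            "trees": len(trees) if trees else 0,
        },
        timestamp=time.time(),
    )
    return SiteReport(
        site_id=site_id, group=group, overlap=overlap, localization=localization,
        invasion=invasion, arteries=arteries, sections=sections,
        filter_report=filt_report, manifest=manifest, omitted=omitted,
    )


#: per-site scalar metrics compared across groups in run_cohort
COHORT_METRICS = (
    "bc_median",
    "max_depth_3d",
    "myometrial_fraction",
    "n_branches_entering_decidua",
    "n_connected_to_placenta",
    "n_enveloped",
)


@dataclass
class CohortReport:
    site_reports: list[SiteReport]
    group_tables: dict[str, GroupCompareReport]
    notices: list[str]

    def summary(self) -> dict:
        return {
            "sites": [r.summary() for r in self.site_reports],
            "comparisons": {
                m: {
                    "method": rep.method,
                    "omnibus_p": rep.omnibus_p,
                    "pairwise": rep.to_rows(),
                    "n_per_group": rep.n_per_group,
                    "n_comparisons": rep.n_comparisons,
                }
                for m, rep in self.group_tables.items()
            },
            "notices": self.notices,
        }


def run_cohort(
    sites: "list",
    config: PipelineConfig | None = None,
) -> CohortReport:
    """Run per-site analyses and group-level statistics.

    ``sites`` holds either synthetic :class:`~placenta3d.synthetic.SiteData`
    objects or dicts of run_site keyword arguments (spots/referents/trees/
    site_id/group). With a single group, comparisons are skipped with a
    notice; a declared group with zero sites is an error.
    """
    config = config or PipelineConfig()
    reports: list[SiteReport] = []
    for k, site in enumerate(sites):
        site_cfg = dataclasses.replace(config, seed=int(config.seed + k))
        if hasattr(site, "spots"):  # SiteData
            reports.append(
                run_site(site.spots, site.referents, site.trees, site_cfg,
                         site_id=site.site_id, group=site.group)
            )
        else:
            reports.append(run_site(config=site_cfg, **site))

    groups = sorted({r.group for r in reports})
    for g in groups:
        if not any(r.group == g for r in reports):
            raise ConfigError(f"group {g!r} has zero sites")
    notices: list[str] = []
    tables: dict[str, GroupCompareReport] = {}
    if len(groups) < 2:
        notices.append("single group: comparative statistics skipped")
    else:
        for metric in COHORT_METRICS:
            samples = {}
            for g in groups:
                vals = [
                    r.summary().get(metric)
                    for r in reports
                    if r.group == g and r.summary().get(metric) is not None
                ]
                if len(vals) >= 2:
                    samples[g] = vals
            if len(samples) < 2:
                notices.append(f"metric {metric}: not enough sites per group to compare")
                continue
            try:
                tables[metric] = group_compare(samples, config.group_method, config.correction)
            except ConfigError as exc:
                notices.append(f"metric {metric}: {exc}")
    return CohortReport(reports, tables, notices)
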