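"""Synthetic implantation-site generator.

Emulates the measured structure of a mouse implantation site so that every
pipeline stage is testable without imaging data: a hemispherical decidua
between a junctional-zone cap (placental border) and a myometrial shell,
spiral-artery centerline trees descending helically from the myometrium
toward the ectoplacental cone, and trophoblast point patterns with
controllable invasion depth, azimuthal bias, perivascular fraction, and
myometrial-invasion fraction. Ground-truth labels and the generating
configuration are recorded for parameter-recovery tests.

Presets encode the reference phenotypes: at E12.5 a control site carries 16
spiral arteries, ~75% of them connected to the placenta, with 75% of
trophoblasts enveloping arteries and invasion capped just short of the
myometrium; the Cxcl12-knockout preset drops perivascular localization to
10%, sends 20% of trophoblasts into the myometrium (three-quarters of those
targeting myometrial arteries), biases invasion azimuthally, and leaves
only ~3 of 16 arteries connected.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import CenterlineTree, ReferentSet, SpotTable
from .metrics import resample_centerline

TRUE_CATEGORIES = (
    "spiral_artery_adjacent",
    "interstitial",
    "myometrial_stromal",
    "myometrial_artery_adjacent",
    "subresolution_artifact",
    "mesometrial_artifact",
)


@dataclass
class SyntheticConfig:
    """Generating parameters for one implantation site.

    Geometry is in um; the decidua is the shell between ``r_jz`` and
    ``r_myo``, the myometrium extends to ``r_outer``. ``p_env`` and
    ``m_myo`` are fractions of all in-domain trophoblasts (perivascular
    decidual and myometrial respectively; the remainder is interstitial),
    so presets state the reported localization splits directly.
    """

    # geometry
    r_jz: float = 900.0
    r_myo: float = 1500.0
    r_outer: float = 1800.0
    # arteries
    n_trees: int = 16
    coil_radius: float = 60.0
    coil_pitch: float = 150.0
    connected_fraction: float = 0.75
    eligible_artery_fraction: float = 1.0  # arteries perivascular points decorate
    artery_spot_spacing: float = 15.0
    artery_spot_jitter: float = 3.0
    centerline_node_spacing: float = 15.0
    centerline_step: float = 10.0  # shared with the analysis resampling
    # trophoblasts
    n_trophoblasts: int = 3000
    depth_alpha: float = 1.5
    depth_beta: float = 1.2
    d_cap: float = 0.95  # support bound: invasion reaches ~90-95% of the decidua
    p_env: float = 0.75
    kappa: float = 0.0  # von Mises azimuthal concentration (0 = isotropic)
    azimuth_center: float = 0.25  # in azimuth units u (0.25 = off-midline)
    m_myo: float = 0.0
    a_target: float = 0.75  # of myometrial invaders, fraction targeting arteries
    r_env: float = 20.0
    r_adj: float = 20.0
    # nuisance structure
    contaminant_fraction: float = 0.05  # sub-resolution spots below the volume floor
    mesometrial_fraction: float = 0.02
    landmark_jitter: float = 10.0
    volume_mean: float = 500.0  # um^3, log-normal location for true spots
    volume_sigma: float = 0.4
    min_volume: float = 100.0  # contaminants are drawn below this floor
    # referents
    n_boundary_referents: int = 40
    n_lumep_referents: int = 8
    # pose: apply a random rigid transform so nothing is axis-aligned
    random_pose: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.r_jz < self.r_myo < self.r_outer):
            raise ConfigError("radii must satisfy 0 < r_jz < r_myo < r_outer")
        for name in ("connected_fraction", "eligible_artery_fraction", "p_env",
                     "m_myo", "a_target", "contaminant_fraction", "mesometrial_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.p_env + self.m_myo > 1:
            raise ConfigError("p_env + m_myo must not exceed 1")
        if self.n_trees < 0:
            raise ConfigError("n_trees must be >= 0")
        if self.n_trees == 0 and self.p_env > 0:
            raise ConfigError("p_env > 0 requires at least one artery tree")
        if self.n_trees == 0 and self.m_myo > 0 and self.a_target > 0:
            raise ConfigError("artery-targeted myometrial invasion requires artery trees")


#: Presets for the reference developmental stages and perturbations.
PRESETS: dict[str, SyntheticConfig] = {
    # E6.5: ~8 nascent arteries, sparse trophoblasts ~10% into the decidua
    "wildtype_E6_5": SyntheticConfig(
        n_trees=8, connected_fraction=0.25, n_trophoblasts=150,
        depth_alpha=1.2, depth_beta=6.0, d_cap=0.15, p_env=0.2,
    ),
    # E8.5: ~10 arteries branching from the myometrium, invasion to ~25%
    "wildtype_E8_5": SyntheticConfig(
        n_trees=10, connected_fraction=0.5, n_trophoblasts=600,
        depth_alpha=1.3, depth_beta=4.0, d_cap=0.30, p_env=0.4,
    ),
    # E12.5 control: 16 arteries, 12 connected, 75/25 perivascular split,
    # perivascular trophoblasts decorating ~3/4 of the arteries so the
    # enveloped-artery fraction lands in the observed 50-75% band
    "wildtype_E12_5": SyntheticConfig(
        n_trees=16, connected_fraction=0.75, n_trophoblasts=3000,
        d_cap=0.95, p_env=0.75, m_myo=0.0, eligible_artery_fraction=0.75,
    ),
    # E12.5 Cxcl12 knockout: ~3/16 connected, 10/70/20 localization split,
    # azimuthally biased (peripheral) invasion, 75% of invaders artery-targeted
    "cxcl12_ko_E12_5": SyntheticConfig(
        n_trees=16, connected_fraction=3 / 16, n_trophoblasts=3000,
        d_cap=0.95, p_env=0.10, m_myo=0.20, a_target=0.75, kappa=4.0,
    ),
}


@dataclass
class GroundTruth:
    """Generator-side labels for parameter-recovery tests.

    ``spots`` is indexed by spot_id with the true category and depth of
    every generated spot (including artifacts); ``arteries`` records the
    per-tree connection and perivascular-eligibility status; ``config``
    echoes the generating parameters.
    """

    spots: pd.DataFrame
    arteries: pd.DataFrame
    config: SyntheticConfig
    seed: int


@dataclass
class SiteData:
    """One generated implantation site with its ground truth."""

    spots: SpotTable
    trees: list[CenterlineTree]
    referents: ReferentSet
    truth: GroundTruth
    site_id: str = "site"
    group: str = "na"


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic, even directions on the upper hemisphere (unit)."""
    k = np.arange(n)
    cos_t = 1.0 - k / max(n - 1, 1) * 0.98 - 0.01  # keep off apex/equator
    sin_t = np.sqrt(np.clip(1 - cos_t**2, 0, 1))
    phi = np.pi * (3 - np.sqrt(5)) * k
    return np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)


def _perp_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    p1 = np.cross(direction, helper)
    p1 /= np.linalg.norm(p1)
    return p1, np.cross(direction, p1)


def _make_tree(
    rng: np.random.Generator, cfg: SyntheticConfig, tree_id: str, connected: bool
) -> CenterlineTree:
    """One helical spiral-artery centerline descending toward the apex."""
    cos_t = rng.uniform(0.2, 0.95)
    phi = rng.uniform(0, 2 * np.pi)
    sin_t = np.sqrt(1 - cos_t**2)
    ray = np.array([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    p1, p2 = _perp_basis(ray)
    shell = cfg.r_myo - cfg.r_jz
    start = rng.uniform(cfg.r_myo + 0.15 * (cfg.r_outer - cfg.r_myo), cfg.r_outer - 20.0)
    if connected:
        end = cfg.r_jz
    else:
        end = cfg.r_jz + rng.uniform(0.25, 0.5) * shell
    n_nodes = max(int(np.ceil((start - end) / cfg.centerline_node_spacing)), 2)
    rad = np.linspace(start, end, n_nodes)
    # helix: constant coil radius, phase advancing with radial progress;
    # |pos| = sqrt(rad^2 + coil^2) is monotone, so depth crosses 1 exactly once
    phase0 = rng.uniform(0, 2 * np.pi)
    phase = phase0 + 2 * np.pi * (start - rad) / cfg.coil_pitch
    pos = (
        ray[None, :] * rad[:, None]
        + p1[None, :] * (cfg.coil_radius * np.cos(phase))[:, None]
        + p2[None, :] * (cfg.coil_radius * np.sin(phase))[:, None]
    )
    radius = np.linspace(12.0, 6.0, n_nodes)
    nodes = pd.DataFrame(
        {
            "node_id": np.arange(n_nodes),
            "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
            "radius": radius,
            "parent_id": np.r_[-1, np.arange(n_nodes - 1)],
        }
    )
    return CenterlineTree(nodes, tree_id=tree_id)


def _true_depth(xyz: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    r = np.linalg.norm(np.atleast_2d(xyz), axis=1)
    return (r - cfg.r_jz) / (cfg.r_myo - cfg.r_jz)


def _sample_azimuth(rng: np.random.Generator, n: int, cfg: SyntheticConfig) -> np.ndarray:
    if cfg.kappa > 0:
        return np.mod(rng.vonmises(2 * np.pi * cfg.azimuth_center, cfg.kappa, n), 2 * np.pi)
    return rng.uniform(0, 2 * np.pi, n)


def _spherical(r: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    sin_t = np.sqrt(np.clip(1 - cos_t**2, 0, 1))
    return np.stack([r * sin_t * np.cos(phi), r * sin_t * np.sin(phi), r * cos_t], axis=1)


def _random_offset(rng: np.random.Generator, n: int, max_norm: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * rng.uniform(0, max_norm, n)[:, None]


def generate_site(
    config: SyntheticConfig | None = None,
    seed: int = 0,
    site_id: str = "site",
    group: str = "na",
) -> SiteData:
    """Generate one implantation site: spots, centerline trees, referents,
    and ground truth. Fully reproducible from (config, seed)."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    shell = cfg.r_myo - cfg.r_jz

    # --- arteries -----------------------------------------------------------
    n_connected = int(round(cfg.connected_fraction * cfg.n_trees))
    connected_ids = set(rng.choice(cfg.n_trees, size=n_connected, replace=False)) \
        if cfg.n_trees else set()
    n_eligible = int(round(cfg.eligible_artery_fraction * cfg.n_trees))
    eligible_ids = set(rng.choice(cfg.n_trees, size=n_eligible, replace=False)) \
        if cfg.n_trees else set()
    trees = [
        _make_tree(rng, cfg, tree_id=f"{site_id}_a{k}", connected=(k in connected_ids))
        for k in range(cfg.n_trees)
    ]

    # centerline samples shared between placement and downstream geometry
    decid_samples, myo_samples = [], []
    for k, tree in enumerate(trees):
        s = resample_centerline(tree, cfg.centerline_step)
        d = _true_depth(s, cfg)
        if k in eligible_ids:
            decid_samples.append(s[(d >= 0.06) & (d <= 0.94)])
        myo_samples.append(s[(d >= 1.05) & (d <= 1.42)])
    decid_samples = np.vstack(decid_samples) if decid_samples else np.empty((0, 3))
    myo_samples = np.vstack(myo_samples) if myo_samples else np.empty((0, 3))
    if cfg.p_env > 0 and len(decid_samples) == 0:
        raise ConfigError("p_env > 0 but no eligible decidual centerline samples")

    spot_rows = []
    truth_rows = []

    def add_spot(sid, channel, xyz, volume, category):
        spot_rows.append(
            {"spot_id": sid, "x": xyz[0], "y": xyz[1], "z": xyz[2],
             "volume": volume, "channel": channel, "site_id": site_id, "group": group}
        )
        truth_rows.append(
            {"spot_id": sid, "channel": channel, "true_category": category,
             "true_depth": float(_true_depth(xyz, cfg)[0])}
        )

    # --- artery spot channel ------------------------------------------------
    sid = 0
    for tree in trees:
        s = resample_centerline(tree, cfg.artery_spot_spacing)
        s = s + rng.normal(0, cfg.artery_spot_jitter, s.shape)
        vols = np.exp(rng.normal(np.log(cfg.volume_mean), cfg.volume_sigma, len(s)))
        for xyz, v in zip(s, vols):
            add_spot(f"a{sid}", "artery", xyz, v, "artery_channel")
            sid += 1

    # --- trophoblasts -------------------------------------------------------
    n = cfg.n_trophoblasts
    cats = rng.choice(
        3, size=n, p=[cfg.m_myo, cfg.p_env, 1 - cfg.m_myo - cfg.p_env]
    )  # 0 = myometrial, 1 = perivascular decidual, 2 = interstitial
    vols = np.exp(rng.normal(np.log(cfg.volume_mean), cfg.volume_sigma, n))
    for i in range(n):
        if cats[i] == 1:
            base = decid_samples[rng.integers(len(decid_samples))]
            xyz = base + _random_offset(rng, 1, cfg.r_env)[0]
            cat = "spiral_artery_adjacent"
        elif cats[i] == 0:
            targeted = rng.random() < cfg.a_target and len(myo_samples)
            if targeted:
                base = myo_samples[rng.integers(len(myo_samples))]
                xyz = base + _random_offset(rng, 1, 0.9 * cfg.r_adj)[0]
                cat = "myometrial_artery_adjacent"
            else:
                d = rng.uniform(1.02, 1.45)
                xyz = _spherical(
                    np.array([cfg.r_jz + d * shell]),
                    np.array([rng.uniform(0.02, 0.98)]),
                    _sample_azimuth(rng, 1, cfg),
                )[0]
                cat = "myometrial_stromal"
        else:
            d = rng.beta(cfg.depth_alpha, cfg.depth_beta) * cfg.d_cap
            xyz = _spherical(
                np.array([cfg.r_jz + d * shell]),
                np.array([rng.uniform(0.02, 0.98)]),
                _sample_azimuth(rng, 1, cfg),
            )[0]
            cat = "interstitial"
        add_spot(f"t{i}", "trophoblast", xyz, vols[i], cat)

    # --- artifacts exercising the spot filter -------------------------------
    n_cont = int(round(cfg.contaminant_fraction * n))
    for j in range(n_cont):
        d = rng.uniform(0.05, 0.9)
        xyz = _spherical(
            np.array([cfg.r_jz + d * shell]),
            np.array([rng.uniform(0.02, 0.98)]),
            np.array([rng.uniform(0, 2 * np.pi)]),
        )[0]
        add_spot(f"c{j}", "trophoblast", xyz, rng.uniform(5.0, 0.9 * cfg.min_volume),
                 "subresolution_artifact")
    n_meso = int(round(cfg.mesometrial_fraction * n))
    for j in range(n_meso):
        rho = rng.uniform(200.0, 1400.0)
        ang = rng.uniform(0, 2 * np.pi)
        z = rng.uniform(-550.0, -320.0)
        xyz = np.array([rho * np.cos(ang), rho * np.sin(ang), z])
        vol = np.exp(rng.normal(np.log(cfg.volume_mean), cfg.volume_sigma))
        add_spot(f"m{j}", "trophoblast", xyz, vol, "mesometrial_artifact")

    # --- referents ----------------------------------------------------------
    ref_rows = []
    dirs = _fibonacci_hemisphere(cfg.n_boundary_referents)
    for label, radius in (("junctional_zone_outer", cfg.r_jz), ("myometrium_outer", cfg.r_myo)):
        pts = dirs * radius + rng.normal(0, cfg.landmark_jitter, (len(dirs), 3))
        ref_rows += [
            {"label": label, "x": p[0], "y": p[1], "z": p[2]} for p in pts
        ]
    ring = np.arange(cfg.n_lumep_referents) / cfg.n_lumep_referents * 2 * np.pi
    lum = np.stack([1200 * np.cos(ring), 1200 * np.sin(ring), np.full_like(ring, -250.0)], axis=1)
    lum += rng.normal(0, cfg.landmark_jitter, lum.shape)
    ref_rows += [{"label": "luminal_epithelium", "x": p[0], "y": p[1], "z": p[2]} for p in lum]
    fb_jitter = rng.normal(0, cfg.landmark_jitter, (2, 3))
    ref_rows.append({"label": "front", "x": 1600.0 + fb_jitter[0, 0],
                     "y": fb_jitter[0, 1], "z": -200.0 + fb_jitter[0, 2]})
    ref_rows.append({"label": "back", "x": -1600.0 + fb_jitter[1, 0],
                     "y": fb_jitter[1, 1], "z": -200.0 + fb_jitter[1, 2]})

    spots_df = pd.DataFrame(spot_rows)
    refs_df = pd.DataFrame(ref_rows)

    # --- random rigid pose --------------------------------------------------
    if cfg.random_pose:
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=np.random.RandomState(seed % 2**31)).as_matrix()
        T = rng.uniform(-2000, 2000, 3)
        for df in (spots_df, refs_df):
            if len(df):
                df[["x", "y", "z"]] = df[["x", "y", "z"]].to_numpy(float) @ R.T + T
        posed_trees = []
        for tree in trees:
            nodes = tree.nodes.copy()
            nodes[["x", "y", "z"]] = nodes[["x", "y", "z"]].to_numpy(float) @ R.T + T
            posed_trees.append(CenterlineTree(nodes, tree.tree_id, site_id))
        trees = posed_trees

    spots = SpotTable.from_dataframe(spots_df, site_id=site_id, group=group)
    referents = ReferentSet(refs_df, site_id=site_id)
    truth = GroundTruth(
        spots=pd.DataFrame(truth_rows).set_index("spot_id"),
        arteries=pd.DataFrame(
            {
                "tree_id": [t.tree_id for t in trees],
                "connected": [k in connected_ids for k in range(cfg.n_trees)],
                "eligible": [k in eligible_ids for k in range(cfg.n_trees)],
            }
        ),
        config=cfg,
        seed=int(seed),
    )
    return SiteData(spots, trees, referents, truth, site_id=site_id, group=group)


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Distinct deterministic sub-seeds (all < 2**31) from a master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n) % (2**31)


def generate_cohort(
    control_config: SyntheticConfig,
    perturbed_config: SyntheticConfig,
    n_sites_per_group: int,
    seed: int = 0,
    group_names: tuple[str, str] = ("control", "knockout"),
) -> list[SiteData]:
    """Independent sites with distinct derived seeds; deterministic given
    the master seed."""
    if n_sites_per_group < 1:
        raise ConfigError("n_sites_per_group must be >= 1")
    seeds = derive_seeds(seed, 2 * n_sites_per_group)
    sites = []
    for g, cfg in zip(group_names, (control_config, perturbed_config)):
        for k in range(n_sites_per_group):
            s = int(seeds[len(sites)])
            sites.append(
                generate_site(cfg, seed=s, site_id=f"{g}_{k}", group=g)
            )
    return sites


def generate_ct_table(
    n_per_group: int,
    effects: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_group: str = "control",
    baseline_delta_ct: float = 5.0,
):
    """Synthetic qPCR Ct table with known group effects (in cycles).

    Ct_housekeeping ~ Normal(20, noise); Ct_target = Ct_housekeeping +
    baseline dCt + group effect + Normal(0, noise). The reference group's
    effect is forced to 0, so its expected fold change is 1 and a +1 cycle
    effect halves expression.
    """
    from .stats import CtTable

    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    effects = dict(effects)
    effects[reference_group] = 0.0
    rng = np.random.default_rng(seed)
    rows = []
    for g, eff in effects.items():
        if not np.isfinite(eff):
            raise ConfigError(f"effect for group {g!r} must be finite")
        for k in range(n_per_group):
            hk = rng.normal(20.0, noise_sd) if noise_sd else 20.0
            tgt = hk + baseline_delta_ct + eff + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            rows.append(
                {"sample_id": f"{g}_{k}", "group": g, "ct_target": tgt, "ct_housekeeping": hk}
            )
    return CtTable(pd.DataFrame(rows), reference_group=reference_group)


def preset(name: str, **overrides) -> SyntheticConfig:
    """A copy of a named preset, optionally with field overrides."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return replace(cfg, **overrides) if overrides else dataclasses.replace(cfg)
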