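import numpy as np
import pandas as pd
import pytest

import placenta3d as p3
from placenta3d.io import ReferentSet, SpotTable


def make_exact_referents(r_jz=900.0, r_myo=1500.0, jitter=0.0, seed=0, n=40):
    """Referents sampled from two concentric hemispheres (canonical pose)."""
    rng = np.random.default_rng(seed)
    k = np.arange(n)
    cos_t = 1.0 - k / (n - 1) * 0.98 - 0.01
    sin_t = np.sqrt(1 - cos_t**2)
    phi = np.pi * (3 - np.sqrt(5)) * k
    dirs = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)
    rows = []
    for label, r in (("junctional_zone_outer", r_jz), ("myometrium_outer", r_myo)):
        pts = dirs * r + (rng.normal(0, jitter, (n, 3)) if jitter else 0.0)
        rows += [{"label": label, "x": p[0], "y": p[1], "z": p[2]} for p in pts]
    ring = np.arange(8) / 8 * 2 * np.pi
    for a in ring:
        rows.append({"label": "luminal_epithelium",
                     "x": 1200 * np.cos(a), "y": 1200 * np.sin(a), "z": -250.0})
    rows.append({"label": "front", "x": 1600.0, "y": 0.0, "z": -200.0})
    rows.append({"label": "back", "x": -1600.0, "y": 0.0, "z": -200.0})
    return ReferentSet(pd.DataFrame(rows))


def make_spots(xyz, channel="trophoblast", volume=500.0):
    xyz = np.atleast_2d(xyz)
    return SpotTable.from_dataframe(
        pd.DataFrame(
            {
                "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
                "volume": volume, "channel": channel,
            }
        )
    )


@pytest.fixture(scope="session")
def exact_frame():
    return p3.fit_half_dome_frame(make_exact_referents())


@pytest.fixture(scope="session")
def control_site():
    return p3.generate_site(p3.preset("wildtype_E12_5"), seed=11,
                            site_id="ctrl", group="control")


@pytest.fixture(scope="session")
def ko_site():
    return p3.generate_site(p3.preset("cxcl12_ko_E12_5"), seed=12,
                            site_id="ko", group="knockout")


@pytest.fixture(scope="session")
def control_frame(control_site):
    return p3.fit_half_dome_frame(control_site.referents)


@pytest.fixture(scope="session")
def control_norm(control_site, control_frame):
    filtered, _ = p3.filter_spots(control_site.spots, 100.0, control_frame)
    return p3.normalize_points(filtered, control_frame)


@pytest.fixture(scope="session")
def ko_norm(ko_site):
    frame = p3.fit_half_dome_frame(ko_site.referents)
    filtered, _ = p3.filter_spots(ko_site.spots, 100.0, frame)
    return p3.normalize_points(filtered, frame)
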