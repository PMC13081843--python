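"""Reading and writing of external data.

Spot tables (point detections exported from segmentation software),
anatomical referent landmarks, SWC-style artery centerline trees, and
tabular/JSON result records. All coordinates are carried in micrometres
(um), right-handed axes; nothing is recentred at read time.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, TableValidationError, TopologyError

log = logging.getLogger(__name__)

#: Closed set of spot channels.
CHANNELS = ("artery", "trophoblast")

#: Closed set of anatomical referent labels.
REFERENT_LABELS = (
    "luminal_epithelium",
    "myometrium_outer",
    "junctional_zone_outer",
    "front",
    "back",
)

#: Minimum number of landmark points required per referent label.
REFERENT_MIN_COUNTS = {
    "luminal_epithelium": 1,
    "myometrium_outer": 4,
    "junctional_zone_outer": 4,
    "front": 1,
    "back": 1,
}

SPOT_COLUMNS = ["spot_id", "x", "y", "z", "volume", "channel", "site_id", "group"]

ROOT_SENTINEL = -1


@dataclass
class SpotDialect:
    """How a delimited position export maps onto the canonical spot schema.

    ``column_map`` renames raw header names to canonical fields; the default
    matches common segmentation-software position exports ("Position X" etc.,
    in um). ``scale`` multiplies x/y/z (and is cubed for volume) so that
    exports in other length units can be brought to um.
    """

    column_map: dict[str, str] = field(
        default_factory=lambda: {
            "ID": "spot_id",
            "Position X": "x",
            "Position Y": "y",
            "Position Z": "z",
            "Volume": "volume",
            "Channel": "channel",
        }
    )
    delimiter: str | None = None  # None: infer from file
    scale: float = 1.0  # raw length unit -> um
    channel_map: dict[str, str] = field(default_factory=dict)


@dataclass
class SpotTable:
    """Validated point detections: one row per spot.

    ``data`` columns: spot_id, x, y, z (um), volume (um^3, NaN when the
    export carried no volume), channel in {artery, trophoblast}, site_id,
    group. ``rejected`` retains input rows that violated an invariant,
    with a ``reason`` column and the original row index, so that
    accepted + rejected account for every input row.
    """

    data: pd.DataFrame
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["reason"])
    )

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise TableValidationError(f"spot table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    def coords(self, channel: str | None = None) -> np.ndarray:
        """(n, 3) array of positions in um, optionally for one channel."""
        df = self.data if channel is None else self.data[self.data["channel"] == channel]
        return df[["x", "y", "z"]].to_numpy(float)

    def channel(self, channel: str) -> "SpotTable":
        if channel not in CHANNELS:
            raise TableValidationError(f"unknown channel {channel!r}; allowed: {CHANNELS}")
        return SpotTable(self.data[self.data["channel"] == channel].reset_index(drop=True))

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, site_id: str = "site", group: str = "na"
    ) -> "SpotTable":
        """Validate an arbitrary frame into a SpotTable.

        Rows violating an invariant (non-finite coordinate, negative volume,
        unknown channel, duplicated spot_id) are diverted into ``rejected``
        with a per-row reason instead of failing the whole table.
        """
        df = df.copy()
        if "site_id" not in df.columns:
            df["site_id"] = site_id
        if "group" not in df.columns:
            df["group"] = group
        if "volume" not in df.columns:
            df["volume"] = np.nan
        if "spot_id" not in df.columns:
            df["spot_id"] = [f"s{i}" for i in range(len(df))]
        missing = [c for c in ("x", "y", "z", "channel") if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {missing}")
        if len(df) == 0:
            raise EmptyInputError("spot table is empty")

        for c in ("x", "y", "z", "volume"):
            df[c] = pd.to_numeric(df[c], errors="coerce")
        df["spot_id"] = df["spot_id"].astype(str)

        reasons = pd.Series("", index=df.index, dtype=object)
        bad_coord = ~np.isfinite(df[["x", "y", "z"]]).all(axis=1)
        reasons[bad_coord] = "non-finite coordinate"
        bad_vol = df["volume"].notna() & (df["volume"] < 0)
        reasons[bad_vol & (reasons == "")] = "negative volume"
        bad_chan = ~df["channel"].isin(CHANNELS)
        reasons[bad_chan & (reasons == "")] = (
            f"channel not in {CHANNELS}"
        )
        dup = df["spot_id"].duplicated() & df.groupby(
            ["site_id", "spot_id"]
        )["spot_id"].transform("size").gt(1)
        reasons[dup & (reasons == "")] = "duplicate spot_id within site"

        bad = reasons != ""
        rejected = df.loc[bad].copy()
        rejected["reason"] = reasons[bad]
        accepted = df.loc[~bad, SPOT_COLUMNS].reset_index(drop=True)
        if bad.any():
            log.warning(
                "spot table: accepted %d rows, rejected %d (indices %s)",
                len(accepted), int(bad.sum()), list(rejected.index[:10]),
            )
        else:
            log.info("spot table: accepted all %d rows", len(accepted))
        return cls(accepted, rejected)


@dataclass
class ReferentSet:
    """Labelled anatomical landmark points (um) for one implantation site."""

    data: pd.DataFrame  # columns: label, x, y, z
    site_id: str = "site"

    def __post_init__(self) -> None:
        unknown = set(self.data["label"]) - set(REFERENT_LABELS)
        if unknown:
            raise FormatError(
                f"unknown referent label(s) {sorted(unknown)}; allowed: {list(REFERENT_LABELS)}"
            )
        counts = self.data["label"].value_counts()
        for label, need in REFERENT_MIN_COUNTS.items():
            have = int(counts.get(label, 0))
            if have < need:
                raise FormatError(
                    f"referent label {label!r} needs >= {need} point(s), found {have}"
                )
        if not np.isfinite(self.data[["x", "y", "z"]].to_numpy(float)).all():
            raise TableValidationError("referent coordinates must be finite")

    def points(self, label: str) -> np.ndarray:
        """(k, 3) positions for one label."""
        return self.data.loc[self.data["label"] == label, ["x", "y", "z"]].to_numpy(float)


@dataclass
class CenterlineTree:
    """Rooted polyline tree of one artery, SWC-style.

    ``nodes`` columns: node_id (int), x, y, z (um), radius (um),
    parent_id (int, -1 for the root). Exactly one root; parent references
    are cycle-free; radii strictly positive.
    """

    nodes: pd.DataFrame
    tree_id: str = "tree"
    site_id: str = "site"

    def __post_init__(self) -> None:
        n = self.nodes
        roots = n.loc[n["parent_id"] == ROOT_SENTINEL, "node_id"].tolist()
        if len(roots) != 1:
            raise TopologyError(f"tree {self.tree_id}: expected 1 root, found {len(roots)}")
        if (n["radius"] <= 0).any():
            bad = n.loc[n["radius"] <= 0, "node_id"].tolist()
            raise TopologyError(f"tree {self.tree_id}: non-positive radius at nodes {bad}")
        ids = set(n["node_id"].tolist())
        orphans = [
            (i, p) for i, p in zip(n["node_id"], n["parent_id"])
            if p != ROOT_SENTINEL and p not in ids
        ]
        if orphans:
            raise TopologyError(f"tree {self.tree_id}: orphan parent references {orphans}")
        g = nx.DiGraph()
        g.add_nodes_from(n["node_id"])
        g.add_edges_from(
            (p, i) for i, p in zip(n["node_id"], n["parent_id"]) if p != ROOT_SENTINEL
        )
        if not nx.is_arborescence(g):
            cyc = [c for c in nx.simple_cycles(g)]
            raise TopologyError(
                f"tree {self.tree_id}: parent references contain a cycle: {cyc}"
            )

    @property
    def root_id(self) -> int:
        return int(self.nodes.loc[self.nodes["parent_id"] == ROOT_SENTINEL, "node_id"].iloc[0])

    def coords(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy(float)

    def edges(self) -> list[tuple[int, int]]:
        """(parent_id, child_id) pairs."""
        n = self.nodes
        return [
            (int(p), int(i))
            for i, p in zip(n["node_id"], n["parent_id"])
            if p != ROOT_SENTINEL
        ]

    def children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {int(i): [] for i in self.nodes["node_id"]}
        for p, c in self.edges():
            out[p].append(c)
        return out

    def node_xyz(self) -> dict[int, np.ndarray]:
        return {
            int(i): np.array([x, y, z], float)
            for i, x, y, z in zip(
                self.nodes["node_id"], self.nodes["x"], self.nodes["y"], self.nodes["z"]
            )
        }


def _read_delimited(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        return pd.read_csv(path, sep=None, engine="python")
    return pd.read_csv(path, sep=delimiter)


def read_spot_table(
    path: str | Path,
    dialect: SpotDialect | None = None,
    site_id: str = "site",
    group: str = "na",
) -> SpotTable:
    """Read a delimited spot export into a validated :class:`SpotTable`.

    The dialect controls header renaming and unit scale. Rows violating
    invariants are kept in ``.rejected`` with row-indexed diagnostics;
    a missing volume column is permitted (downstream volume filtering then
    becomes a logged no-op).
    """
    dialect = dialect or SpotDialect()
    raw = _read_delimited(path, dialect.delimiter)
    if len(raw) == 0:
        raise EmptyInputError(f"{path}: spot table has no rows")
    df = raw.rename(columns=dialect.column_map)
    required = [c for c in ("x", "y", "z", "channel") if c not in df.columns]
    if required:
        raise FormatError(
            f"{path}: missing required column(s) {required} after applying dialect "
            f"(raw columns: {list(raw.columns)})"
        )
    if dialect.channel_map:
        df["channel"] = df["channel"].map(lambda v: dialect.channel_map.get(v, v))
    if dialect.scale != 1.0:
        for c in ("x", "y", "z"):
            df[c] = pd.to_numeric(df[c], errors="coerce") * dialect.scale
        if "volume" in df.columns:
            df["volume"] = pd.to_numeric(df["volume"], errors="coerce") * dialect.scale**3
    if "volume" not in df.columns:
        log.warning("%s: no volume column; volume-based filtering will be a no-op", path)
    return SpotTable.from_dataframe(df, site_id=site_id, group=group)


def read_referents(path: str | Path, site_id: str | None = None) -> ReferentSet:
    """Read anatomical referents from JSON or a delimited file with a
    ``label`` column. Fails loudly if any required label class is absent."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        if isinstance(payload, dict):
            points = payload.get("points", [])
            site_id = site_id or payload.get("site_id", "site")
        else:
            points = payload
        df = pd.DataFrame(points)
    else:
        df = _read_delimited(path, None)
    if "label" not in df.columns:
        raise FormatError(f"{path}: referent file must carry a 'label' column")
    for c in ("x", "y", "z"):
        if c not in df.columns:
            raise FormatError(f"{path}: referent file missing coordinate column {c!r}")
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return ReferentSet(df[["label", "x", "y", "z"]].copy(), site_id=site_id or "site")


def read_centerline_trees(path: str | Path, site_id: str = "site") -> list[CenterlineTree]:
    """Read an SWC-dialect centerline file into one tree per root.

    Columns: id, type, x, y, z, radius, parent (whitespace-delimited,
    ``#`` comments, parent -1 = root). A file may hold several roots; each
    connected component becomes its own :class:`CenterlineTree`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise FormatError(f"{path}:{ln}: expected 7 SWC columns, got {len(parts)}")
            try:
                rows.append(
                    (int(parts[0]), float(parts[2]), float(parts[3]), float(parts[4]),
                     float(parts[5]), int(parts[6]))
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: unparseable SWC record: {exc}") from exc
    if not rows:
        raise EmptyInputError(f"{path}: no centerline records")
    df = pd.DataFrame(rows, columns=["node_id", "x", "y", "z", "radius", "parent_id"])

    if df["node_id"].duplicated().any():
        dup = df.loc[df["node_id"].duplicated(), "node_id"].tolist()
        raise TopologyError(f"{path}: duplicate node ids {dup}")
    self_parent = df.loc[df["node_id"] == df["parent_id"], "node_id"].tolist()
    if self_parent:
        raise TopologyError(f"{path}: node(s) {self_parent} are their own parent (cycle)")

    # split into connected components rooted at parent == -1
    g = nx.Graph()
    g.add_nodes_from(df["node_id"])
    ids = set(df["node_id"])
    for i, p in zip(df["node_id"], df["parent_id"]):
        if p != ROOT_SENTINEL:
            if p not in ids:
                raise TopologyError(f"{path}: node {i} references missing parent {p}")
            g.add_edge(i, p)
    trees = []
    for k, comp in enumerate(nx.connected_components(g)):
        sub = df[df["node_id"].isin(comp)].reset_index(drop=True)
        trees.append(CenterlineTree(sub, tree_id=f"{path.stem}_{k}", site_id=site_id))
    return trees


class _ResultEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        return super().default(o)


def write_results(record, path: str | Path, format: str = "json") -> None:
    """Serialize a result record to JSON (lossless round-trip for numeric
    fields) or delimited text (one row per entry, stored precision).

    Tabular records may be a DataFrame, a list of dicts, or any object with
    a ``to_rows()`` method; other records are written as a single row.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(record, fh, cls=_ResultEncoder, indent=2)
        return
    if format != "delimited":
        raise ValueError(f"format must be 'json' or 'delimited', got {format!r}")
    if hasattr(record, "to_rows"):
        rows = record.to_rows()
    elif isinstance(record, pd.DataFrame):
        rows = record
    elif isinstance(record, list):
        rows = pd.DataFrame(record)
    elif dataclasses.is_dataclass(record) and not isinstance(record, type):
        rows = pd.DataFrame([dataclasses.asdict(record)])
    else:
        rows = pd.DataFrame([dict(record)])
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


# --- writers for the synthetic generator / CLI round trip -------------------

def write_spot_table(spots: SpotTable, path: str | Path) -> None:
    """Write a SpotTable in the default dialect (canonical column names)."""
    spots.data.to_csv(path, sep="\t", index=False, float_format="%.9g")


def write_referents(referents: ReferentSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "site_id": referents.site_id,
            "points": referents.data.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, cls=_ResultEncoder, indent=2)
    else:
        referents.data.to_csv(path, sep="\t", index=False, float_format="%.9g")


def write_centerline_trees(trees: list[CenterlineTree], path: str | Path) -> None:
    """Write trees into one SWC file, re-numbering nodes to stay unique."""
    offset = 0
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for tree in trees:
            n = tree.nodes
            remap = {int(i): int(i) + offset for i in n["node_id"]}
            for i, x, y, z, r, p in zip(
                n["node_id"], n["x"], n["y"], n["z"], n["radius"], n["parent_id"]
            ):
                pid = ROOT_SENTINEL if p == ROOT_SENTINEL else remap[int(p)]
                fh.write(f"{remap[int(i)]} 2 {x:.9g} {y:.9g} {z:.9g} {r:.9g} {pid}\n")
            offset += int(n["node_id"].max()) + 1
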