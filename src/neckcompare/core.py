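"""Domain types and file I/O for neuron skeletons, synapse tables and metadata.

Skeletons are SWC-dialect trees of 3-D nodes; synapses are tabular records of
(pre neuron, post neuron, location) with optional neuropil and cleft-score
columns. All coordinates are stored in nanometres internally; SWC files are
converted on read using a configurable unit scale (default 1 unit = 1 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, SkeletonStructureError, SwcParseError

ROOT_PARENT = -1

NEURON_CLASSES = ("DN", "AN", "SA", "MN", "SN", "IN")
SIDES = ("left", "right", "center")

SYNAPSE_REQUIRED_COLUMNS = ("pre_id", "post_id", "x", "y", "z")


@dataclass
class TreeSkeleton:
    """A rooted tree of 3-D nodes representing one reconstructed neuron.

    Parameters
    ----------
    neuron_id
        Identifier of the neuron this skeleton reconstructs.
    nodes
        DataFrame with columns ``node_id, parent_id, x, y, z, radius, label``;
        one row per node, ``parent_id == -1`` marks the single root.
    """

    neuron_id: str
    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        self.nodes = self.nodes.reset_index(drop=True)
        validate_skeleton(self)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def root_id(self) -> int:
        return int(self.nodes.loc[self.nodes["parent_id"] == ROOT_PARENT, "node_id"].iloc[0])

    def coords(self) -> np.ndarray:
        """Node coordinates as an (n, 3) float array in nm."""
        return self.nodes[["x", "y", "z"]].to_numpy(dtype=float)

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of every parent-child edge (nm)."""
        idx = {int(n): i for i, n in enumerate(self.nodes["node_id"])}
        xyz = self.coords()
        out = []
        for _, row in self.nodes.iterrows():
            p = int(row["parent_id"])
            if p == ROOT_PARENT:
                continue
            out.append(np.linalg.norm(xyz[idx[int(row["node_id"])]] - xyz[idx[p]]))
        return np.asarray(out, dtype=float)

    def cable_length(self) -> float:
        """Total cable length in nm."""
        return float(self.edge_lengths().sum())

    def children_map(self) -> dict[int, list[int]]:
        """node_id -> sorted list of child node_ids."""
        out: dict[int, list[int]] = {int(n): [] for n in self.nodes["node_id"]}
        for _, row in self.nodes.iterrows():
            p = int(row["parent_id"])
            if p != ROOT_PARENT:
                out[p].append(int(row["node_id"]))
        for v in out.values():
            v.sort()
        return out

    def leaf_ids(self) -> list[int]:
        ch = self.children_map()
        return sorted(n for n, c in ch.items() if not c)


def validate_skeleton(skel: TreeSkeleton) -> None:
    """Check every TreeSkeleton invariant, raising on the first violation.

    Raises
    ------
    SkeletonStructureError
        On duplicate ids, missing parents, multiple/absent roots, cycles,
        unreachable nodes or non-finite coordinates; the offending node id
        is attached where one exists.
    """
    nodes = skel.nodes
    required = {"node_id", "parent_id", "x", "y", "z", "radius", "label"}
    missing = required - set(nodes.columns)
    if missing:
        raise SchemaError(f"skeleton table missing columns: {sorted(missing)}")
    if len(nodes) == 0:
        raise SkeletonStructureError("skeleton has no nodes")

    ids = nodes["node_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        dup = int(pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0])
        raise SkeletonStructureError(f"duplicate node_id {dup}", node_id=dup)

    xyz = nodes[["x", "y", "z", "radius"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xyz[:, :3])):
        bad = int(nodes["node_id"].iloc[int(np.argwhere(~np.isfinite(xyz[:, :3]))[0][0])])
        raise SkeletonStructureError(f"non-finite coordinate at node {bad}", node_id=bad)

    parents = nodes["parent_id"].to_numpy()
    roots = ids[parents == ROOT_PARENT]
    if len(roots) == 0:
        raise SkeletonStructureError("skeleton has no root (no parent_id == -1)")
    if len(roots) > 1:
        raise SkeletonStructureError(
            f"multiple roots: nodes {sorted(int(r) for r in roots)}", node_id=int(roots[1])
        )
    id_set = set(int(i) for i in ids)
    for nid, pid in zip(ids, parents):
        pid = int(pid)
        if pid == ROOT_PARENT:
            continue
        if pid < 0:
            raise SkeletonStructureError(
                f"node {int(nid)} has invalid negative parent {pid}", node_id=int(nid)
            )
        if pid not in id_set:
            raise SkeletonStructureError(
                f"node {int(nid)} references missing parent {pid}", node_id=int(nid)
            )

    # cycle / reachability check by walking up from every node
    parent_of = {int(n): int(p) for n, p in zip(ids, parents)}
    root = int(roots[0])
    reached: dict[int, bool] = {root: True}
    for nid in parent_of:
        trail = []
        cur = nid
        while cur not in reached:
            trail.append(cur)
            cur = parent_of[cur]
            if cur == ROOT_PARENT:
                break
            if cur in trail:
                raise SkeletonStructureError(f"cycle involving node {cur}", node_id=cur)
        for t in trail:
            reached[t] = True
    unreachable = id_set - set(reached)
    if unreachable:
        bad = min(unreachable)
        raise SkeletonStructureError(f"node {bad} not reachable from root", node_id=bad)


def read_swc(path, unit_scale: float = 1.0) -> TreeSkeleton:
    """Read an SWC file into a validated :class:`TreeSkeleton`.

    Parameters
    ----------
    path
        SWC-dialect text file: 7 whitespace-separated columns
        (id, label, x, y, z, radius, parent), ``#`` comments.
    unit_scale
        Multiplier converting file coordinates to nm (default 1 nm/unit).
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcParseError(
                    f"expected 7 columns, got {len(parts)}", line_number=lineno
                )
            try:
                nid = int(parts[0])
                label = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SwcParseError(str(exc), line_number=lineno) from None
            rows.append((nid, parent, x * unit_scale, y * unit_scale,
                         z * unit_scale, r * unit_scale, label))
    nodes = pd.DataFrame(
        rows, columns=["node_id", "parent_id", "x", "y", "z", "radius", "label"]
    )
    import os

    neuron_id = os.path.splitext(os.path.basename(str(path)))[0]
    return TreeSkeleton(neuron_id=neuron_id, nodes=nodes)


def write_swc(skel: TreeSkeleton, path, unit_scale: float = 1.0) -> None:
    """Write a skeleton as SWC, root-first depth-first, children by node_id.

    Parents always precede children. ``unit_scale`` divides nm coordinates
    back to file units (inverse of :func:`read_swc`).
    """
    by_id = {int(r.node_id): r for r in skel.nodes.itertuples()}
    children = skel.children_map()
    order: list[int] = []
    stack = [skel.root_id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(reversed(children[nid]))
    with open(path, "w") as fh:
        fh.write("# id label x y z radius parent\n")
        for nid in order:
            r = by_id[nid]
            fh.write(
                f"{nid} {int(r.label)} {r.x / unit_scale:.6f} {r.y / unit_scale:.6f} "
                f"{r.z / unit_scale:.6f} {r.radius / unit_scale:.6f} {int(r.parent_id)}\n"
            )


def read_synapse_table(path, cleft_min: float | None = None) -> pd.DataFrame:
    """Read a synapse CSV/TSV, optionally applying a cleft-score filter.

    Required columns: ``pre_id, post_id, x, y, z``; optional ``neuropil`` and
    ``cleft_score``. Rows with ``cleft_score <= cleft_min`` are removed when
    ``cleft_min`` is given; rows with no cleft score always pass (only some
    datasets' synapse predictions carry cleft scores, so the filter is
    effectively applied per dataset).
    Row order is preserved and retained rows are unchanged.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    return filter_synapses(df, cleft_min=cleft_min)


def filter_synapses(df: pd.DataFrame, cleft_min: float | None = None) -> pd.DataFrame:
    """Validate synapse-table schema and apply the strict cleft-score filter."""
    for col in SYNAPSE_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"synapse table missing required column '{col}'")
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise SchemaError("synapse table contains non-finite coordinates")
    if cleft_min is not None and "cleft_score" in df.columns:
        score = pd.to_numeric(df["cleft_score"], errors="coerce")
        keep = score.isna() | (score > cleft_min)
        df = df.loc[keep]
    return df.reset_index(drop=True)


def read_metadata(path) -> pd.DataFrame:
    """Read a neuron-metadata CSV (neuron_id, dataset_id, side, neuron_class, ...)."""
    df = pd.read_csv(path, dtype={"neuron_id": str})
    for col in ("neuron_id", "dataset_id", "side", "neuron_class"):
        if col not in df.columns:
            raise SchemaError(f"metadata table missing required column '{col}'")
    bad = set(df["neuron_class"].dropna()) - set(NEURON_CLASSES)
    if bad:
        raise SchemaError(f"unknown neuron_class values: {sorted(bad)}")
    return df


def neuropil_counts(synapses: pd.DataFrame) -> pd.DataFrame:
    """Per-(neuron, neuropil) presynapse and postsynapse counts.

    ``pre_count`` counts rows where the neuron is presynaptic, ``post_count``
    where it is postsynaptic; rows without a neuropil label are tallied under
    ``"unassigned"``. Totals over neuropils equal the number of synapse rows
    the neuron participates in.
    """
    df = synapses.copy()
    if "neuropil" not in df.columns:
        df["neuropil"] = "unassigned"
    df["neuropil"] = df["neuropil"].fillna("unassigned")
    pre = (
        df.groupby(["pre_id", "neuropil"]).size().rename("pre_count").reset_index()
        .rename(columns={"pre_id": "neuron_id"})
    )
    post = (
        df.groupby(["post_id", "neuropil"]).size().rename("post_count").reset_index()
        .rename(columns={"post_id": "neuron_id"})
    )
    out = pre.merge(post, on=["neuron_id", "neuropil"], how="outer").fillna(0)
    out["pre_count"] = out["pre_count"].astype(int)
    out["post_count"] = out["post_count"].astype(int)
    return out.sort_values(["neuron_id", "neuropil"]).reset_index(drop=True)
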