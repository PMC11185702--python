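"""Synaptic-network construction and circuit analysis.

Adjacency matrices count presynapses per (pre, post) neuron pair. For
analysis they are converted to input percent of the receiving neuron and
averaged by type. Circuit extraction keeps partners above weight > 10 and
percent output > 0.5%, then augments with motor/sensory/sensory-ascending
neurons connected at weight > 5. Effective connectivity is the sum over
directed paths of products of input fractions (powers of the fraction
matrix). Information-flow ranking assigns each neuron the iteration at
which a spreading process from sensory seeds first reaches it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

DEFAULT_WEIGHT_MIN = 10
DEFAULT_OUT_FRAC_MIN = 0.5  # percent
DEFAULT_AUGMENT_WEIGHT_MIN = 5
DEFAULT_AUGMENT_CLASSES = frozenset({"MN", "SN", "SA"})
DEFAULT_THETA = 0.3
DEFAULT_MAX_ITER = 12
UNREACHED = np.nan


def build_adjacency(
    synapses: pd.DataFrame, neurons: set[str] | None = None
) -> pd.DataFrame:
    """Presynapse-count matrix (rows = pre, columns = post) from synapse rows.

    When ``neurons`` is given, both rows and columns are restricted to (and
    padded to) that id set.
    """
    df = synapses
    if neurons is not None:
        df = df[df["pre_id"].isin(neurons) & df["post_id"].isin(neurons)]
    if len(df) == 0:
        ids = sorted(neurons) if neurons else []
        return pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    adj = (
        df.groupby(["pre_id", "post_id"]).size().unstack(fill_value=0)
    )
    if neurons is not None:
        ids = sorted(neurons)
        adj = adj.reindex(index=ids, columns=ids, fill_value=0)
    else:
        ids = sorted(set(adj.index) | set(adj.columns))
        adj = adj.reindex(index=ids, columns=ids, fill_value=0)
    return adj.astype(int)


def input_fraction(
    adj: pd.DataFrame, percent: bool = False, exclude_autapses: bool = True
) -> pd.DataFrame:
    """Convert weights to each column's share of its neuron's total input.

    Autapses (diagonal entries) are excluded from both numerator and
    denominator by default so a neuron cannot inflate its own input.
    Zero-input columns stay all-zero.
    """
    w = adj.to_numpy(dtype=float).copy()
    if exclude_autapses and adj.shape[0] == adj.shape[1] and list(adj.index) == list(adj.columns):
        np.fill_diagonal(w, 0.0)
    colsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(colsum > 0, w / colsum, 0.0)
    if percent:
        frac = frac * 100.0
    return pd.DataFrame(frac, index=adj.index, columns=adj.columns)


def type_average(matrix: pd.DataFrame, type_map: dict[str, str]) -> pd.DataFrame:
    """Average a neuron-level input-percent matrix by type.

    Entry (S, T) = mean over post-neurons of type T of the summed input
    percent they receive from all pre-neurons of type S.
    """
    missing = [n for n in list(matrix.index) + list(matrix.columns) if n not in type_map]
    if missing:
        raise ValueError(f"neurons missing from type_map: {sorted(set(missing))[:5]}")
    pre_types = pd.Series([type_map[n] for n in matrix.index], index=matrix.index)
    post_types = pd.Series([type_map[n] for n in matrix.columns], index=matrix.columns)
    summed = matrix.groupby(pre_types).sum()  # sum over pre members
    averaged = summed.T.groupby(post_types).mean().T  # mean over post members
    return averaged.sort_index(axis=0).sort_index(axis=1)


def extract_circuit(
    adj: pd.DataFrame,
    seeds: set[str],
    classes: dict[str, str] | None = None,
    out_frac_min: float = DEFAULT_OUT_FRAC_MIN,
    weight_min: int = DEFAULT_WEIGHT_MIN,
    augment_weight_min: int = DEFAULT_AUGMENT_WEIGHT_MIN,
    augment_classes: frozenset[str] = DEFAULT_AUGMENT_CLASSES,
    display_input_min: float = 0.0,
    type_map: dict[str, str] | None = None,
) -> nx.DiGraph:
    """Extract the circuit around seed neurons with the two-stage thresholds.

    Stage 1 keeps partners (either direction) of a seed with weight strictly
    above ``weight_min`` AND share of the seed's total output (or input, for
    upstream partners) strictly above ``out_frac_min`` percent. Stage 2 adds
    motor/sensory/sensory-ascending neurons connected to any stage-1 node
    with weight strictly above ``augment_weight_min``. Edges among retained
    nodes are annotated with input percent (type-averaged when ``type_map``
    is given) and pruned below ``display_input_min`` percent.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("need at least one seed neuron")
    missing = seeds - set(adj.index)
    if missing:
        raise ValueError(f"seeds not in adjacency: {sorted(missing)}")
    classes = classes or {}

    out_totals = adj.sum(axis=1).astype(float)

    def qualifies(pre: str, w: float) -> bool:
        tot = float(out_totals[pre])
        return w > weight_min and tot > 0 and 100.0 * w / tot > out_frac_min

    keep = set(seeds)
    for s in seeds:
        for t, w in adj.loc[s].items():
            if qualifies(s, w):  # downstream partner: seed is presynaptic
                keep.add(t)
        for t, w in adj[s].items():
            if qualifies(t, w):  # upstream partner: partner is presynaptic
                keep.add(t)

    stage1 = set(keep)
    for n in adj.index:
        if n in keep or classes.get(n) not in augment_classes:
            continue
        to_stage1 = adj.loc[n, sorted(stage1 & set(adj.columns))]
        from_stage1 = adj.loc[sorted(stage1 & set(adj.index)), n]
        if (to_stage1 > augment_weight_min).any() or (from_stage1 > augment_weight_min).any():
            keep.add(n)

    nodes = sorted(keep)
    sub = adj.loc[nodes, nodes]
    pct = input_fraction(sub, percent=True)
    if type_map is not None:
        pct_t = type_average(pct, {n: type_map.get(n, n) for n in nodes})
    g = nx.DiGraph()
    for n in nodes:
        g.add_node(n, neuron_class=classes.get(n), is_seed=n in seeds)
    for i in nodes:
        for j in nodes:
            w = int(sub.loc[i, j])
            if w == 0:
                continue
            p = float(pct.loc[i, j])
            if type_map is not None:
                p = float(pct_t.loc[type_map.get(i, i), type_map.get(j, j)])
            if p >= display_input_min and p > 0:
                g.add_edge(i, j, weight=w, input_percent=p)
    return g


def effective_connectivity(
    frac: pd.DataFrame,
    sources: list[str],
    targets: list[str],
    max_hops: int = 3,
) -> pd.DataFrame:
    """Multi-hop influence: per (source, target, hop) path-product mass.

    Hop-h influence is the (source, target) entry of the h-th power of the
    input-fraction matrix (fractions as proportions), i.e. the sum over all
    directed h-step paths of the product of edge fractions. A ``cumulative``
    column sums hops 1..max_hops.
    """
    if max_hops < 1:
        raise ValueError("max_hops must be >= 1")
    F = frac.to_numpy(dtype=float)
    idx = {n: i for i, n in enumerate(frac.index)}
    rows = []
    power = np.eye(F.shape[0])
    hop_mats = []
    for _ in range(max_hops):
        power = power @ F
        hop_mats.append(power.copy())
    for s in sources:
        for t in targets:
            cum = 0.0
            for h, M in enumerate(hop_mats, start=1):
                v = float(M[idx[s], idx[t]])
                cum += v
                rows.append({"source": s, "target": t, "hop": h, "influence": v})
            rows.append({"source": s, "target": t, "hop": 0, "influence": cum})
    out = pd.DataFrame(rows)
    out["hop"] = out["hop"].replace(0, "cumulative")
    return out


def information_flow_rank(
    adj: pd.DataFrame,
    seed_sets: dict[str, set[str]],
    theta: float = DEFAULT_THETA,
    mode: str = "deterministic",
    n_runs: int = 100,
    max_iter: int = DEFAULT_MAX_ITER,
    rng_seed: int | None = None,
    exclude: set[str] | None = None,
    include_seeds: bool = False,
) -> pd.DataFrame:
    """Traversal distance of every neuron from each sensory seed set.

    Seeds start visited at distance 0. At iteration t, an unvisited neuron
    with fraction f of its total input weight coming from visited neurons
    becomes visited (deterministic mode: when f >= theta; stochastic mode:
    with probability min(1, f / theta)), receiving distance t. Stochastic
    distances are averaged over ``n_runs`` seeded replicates. Unreached
    neurons are NaN. Rows for seed neurons (unless ``include_seeds``) and
    for ``exclude`` ids are dropped.
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    if mode not in ("deterministic", "stochastic"):
        raise ValueError("mode must be 'deterministic' or 'stochastic'")
    ids = list(adj.index)
    n = len(ids)
    W = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    total_in = W.sum(axis=0)
    exclude = exclude or set()

    def one_pass(seed_mask: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
        visited = seed_mask.copy()
        distance = np.where(seed_mask, 0.0, np.nan)
        for t in range(1, max_iter + 1):
            if visited.all():
                break
            frac_in = np.where(
                total_in > 0, W[visited].sum(axis=0) / np.where(total_in > 0, total_in, 1), 0.0
            )
            if rng is None:
                newly = (~visited) & (frac_in >= theta)
            else:
                p = np.minimum(1.0, frac_in / theta)
                newly = (~visited) & (rng.random(n) < p)
            if not newly.any():
                if rng is None:
                    break
                continue
            distance[newly] = t
            visited |= newly
        return distance

    cols = {}
    id_index = {nid: i for i, nid in enumerate(ids)}
    for m_i, (modality, seeds) in enumerate(sorted(seed_sets.items())):
        if not seeds:
            raise ValueError(f"seed set for modality '{modality}' is empty")
        mask = np.zeros(n, dtype=bool)
        for s in seeds:
            if s in id_index:
                mask[id_index[s]] = True
        if mode == "deterministic":
            cols[modality] = one_pass(mask, None)
        else:
            acc = np.zeros(n)
            cnt = np.zeros(n)
            for r in range(n_runs):
                ss = None if rng_seed is None else (rng_seed + 7919 * m_i + r) % (2**31)
                rng = np.random.default_rng(ss)
                dist = one_pass(mask, rng)
                ok = ~np.isnan(dist)
                acc[ok] += dist[ok]
                cnt[ok] += 1
            with np.errstate(invalid="ignore"):
                mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
            cols[modality] = mean

    out = pd.DataFrame(cols, index=ids)
    drop = set(exclude)
    if not include_seeds:
        drop |= set().union(*seed_sets.values())
    return out.drop(index=[d for d in drop if d in out.index])


def rank_by_type(ranks: pd.DataFrame, type_map: dict[str, str]) -> pd.DataFrame:
    """Average a neuron-level rank table by type, ignoring unreached entries.

    A type whose members are all unreached for a modality stays unreached.
    """
    missing = [n for n in ranks.index if n not in type_map]
    if missing:
        raise ValueError(f"rows missing from type_map: {sorted(missing)[:5]}")
    types = pd.Series([type_map[n] for n in ranks.index], index=ranks.index)
    return ranks.groupby(types).mean().sort_index()  # pandas mean skips NaN


def cluster_by_rank(
    ranks: pd.DataFrame,
    method: str = "ward",
    cut_height: float = 5.0,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[pd.Series, np.ndarray]:
    """Hierarchically cluster type-level rank vectors and cut the dendrogram.

    Unreached entries are imputed to ``max_iter + 1`` before clustering.
    Returns flat cluster labels (by input order) and the linkage matrix.
    """
    if len(ranks) < 2:
        raise ValueError("need at least 2 rows to cluster")
    X = ranks.to_numpy(dtype=float).copy()
    X[np.isnan(X)] = max_iter + 1
    Z = linkage(X, method=method, metric="euclidean")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    return pd.Series(labels, index=ranks.index, name="cluster"), Z
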