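"""Primary-neuropil and longitudinal-tract assignment.

Brain rule: a single neuropil is assigned when it holds >= 80% of a neuron's
synapses; an ordered dual label (primary_secondary) when the top two jointly
reach 80% and each holds at least 5%; otherwise "multi".

VNC rule: a single two-letter abbreviation when one neuropil holds > 80% of
the relevant synapses (presynapses for DNs, postsynapses for ANs); "ut" when
the upper-tectulum group (NTct, WTct, HTct) jointly exceeds 80%; "xl" for
the leg-neuropil group; otherwise "xn". Neurons with no synapses in the
cord (soma/soma-tract only) are set aside as "XA".
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .core import TreeSkeleton
from .morphology import longest_neurite_from_point, to_dotprops
from .nblast import ScoreMatrix, nblast_allbyall

BRAIN_SINGLE_FRACTION = 0.80  # inclusive (">= 80%")
BRAIN_DUAL_EACH_MIN = 0.05
VNC_SINGLE_FRACTION = 0.80  # exclusive ("> 80%")

#: Two-letter VNC abbreviations; the neuropil list pairs with
#: nt, wt, ht, it, lt, fl, ml, hl, mv, ov, ad.
VNC_ABBREVIATIONS = {
    "NTct": "nt",
    "WTct": "wt",
    "HTct": "ht",
    "IntTct": "it",
    "LTct": "lt",
    "LegNpT1": "fl",
    "LegNpT2": "ml",
    "LegNpT3": "hl",
    "mVAC": "mv",
    "Ov": "ov",
    "ANm": "ad",
}

UT_SET = frozenset({"NTct", "WTct", "HTct"})
LEG_SET = frozenset({"LegNpT1", "LegNpT2", "LegNpT3"})

TRACT_VOCAB = (
    "DLT", "MDA", "MTD-I", "MTD-II", "MTD-III", "DMT", "ITD",
    "VLT", "DLV", "VTV", "CVL", "ADM", "none",
)


def assign_brain_neuropil(
    counts: dict[str, float],
    single_fraction: float = BRAIN_SINGLE_FRACTION,
    dual_each_min: float = BRAIN_DUAL_EACH_MIN,
) -> str:
    """Assign a brain neuropil label from one neuron's neuropil counts.

    The dual label tests only the top two neuropils by count (ordered
    primary first); anything else falls through to "multi".
    """
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValueError("brain neuropil assignment needs a positive synapse total")
    # sort by count desc, then name for determinism
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top_name, top_count = ranked[0]
    if top_count / total >= single_fraction:
        return top_name
    if len(ranked) >= 2:
        second_name, second_count = ranked[1]
        if (
            (top_count + second_count) / total >= single_fraction
            and top_count / total >= dual_each_min
            and second_count / total >= dual_each_min
        ):
            return f"{top_name}_{second_name}"
    return "multi"


def assign_vnc_neuropil(
    counts: dict[str, float],
    direction: str = "pre",
    vocab: dict[str, str] | None = None,
    ut_set: frozenset[str] = UT_SET,
    leg_set: frozenset[str] = LEG_SET,
    single_fraction: float = VNC_SINGLE_FRACTION,
) -> str:
    """Assign a VNC neuropil abbreviation from one neuron's counts.

    ``direction`` records which synapse role the counts tally (presynapses
    for DNs, postsynapses for ANs); the rule itself is direction-agnostic.
    Zero-synapse neurons are excluded from the analysis as "XA".
    """
    if direction not in ("pre", "post"):
        raise ValueError("direction must be 'pre' or 'post'")
    vocab = VNC_ABBREVIATIONS if vocab is None else vocab
    total = float(sum(counts.values()))
    if total <= 0:
        return "XA"
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top_name, top_count = ranked[0]
    if top_count / total > single_fraction:
        return vocab.get(top_name, top_name)
    ut_total = sum(v for k, v in counts.items() if k in ut_set)
    if ut_total / total > single_fraction:
        return "ut"
    leg_total = sum(v for k, v in counts.items() if k in leg_set)
    if leg_total / total > single_fraction:
        return "xl"
    return "xn"


def assign_group_neuropil(
    member_counts: list[dict[str, float]], assigner=assign_vnc_neuropil, **kwargs
) -> str:
    """Neuropil label for a pair/group of neurons.

    If the members' individual labels agree, that label stands; otherwise the
    assigner is re-applied to the element-wise mean of the counts.
    """
    if not member_counts:
        raise ValueError("group must be non-empty")
    labels = {assigner(c, **kwargs) for c in member_counts}
    if len(labels) == 1:
        return labels.pop()
    keys = sorted(set().union(*member_counts))
    mean_counts = {
        k: float(np.mean([c.get(k, 0.0) for c in member_counts])) for k in keys
    }
    return assigner(mean_counts, **kwargs)


def mean_point_distance(points: np.ndarray, centerline: np.ndarray) -> float:
    """Mean nearest distance from a point set to a reference centerline."""
    tree = cKDTree(np.atleast_2d(centerline))
    d, _ = tree.query(np.atleast_2d(points), k=1)
    return float(np.mean(d))


def assign_tract(
    skeletons: dict[str, TreeSkeleton],
    entries: dict[str, np.ndarray],
    references: dict[str, np.ndarray],
    scoring: ScoreMatrix | None = None,
    sigma_um: float = 3.0,
    linkage_cut: float = 0.75,
    tau_tract: float = 20_000.0,
    k: int = 5,
    spacing: float = 1000.0,
) -> dict[str, str]:
    """Assign each neuron a longitudinal tract label.

    Neurons are simplified to their longest neurite from the cord entry
    point, converted to dotprops and NBLAST-clustered (average linkage on
    1 - mean score, cut at ``linkage_cut``). Each cluster is labelled by
    the reference tract centerline with minimal mean point distance over
    cluster members, or "none" when that distance exceeds ``tau_tract`` (nm).
    """
    if not references:
        raise ValueError("need at least one reference tract centerline")
    ids = sorted(skeletons)
    neurites = {
        nid: longest_neurite_from_point(skeletons[nid], entries[nid]) for nid in ids
    }
    dps = {nid: to_dotprops(neurites[nid], k=k, spacing=spacing) for nid in ids}

    if len(ids) == 1:
        labels = np.array([1])
    else:
        score = nblast_allbyall([dps[i] for i in ids], scoring, sigma_um)
        dist = 1.0 - 0.5 * (score + score.T)
        np.fill_diagonal(dist, 0.0)
        dist = np.clip(dist, 0.0, None)
        Z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(Z, t=linkage_cut, criterion="distance")

    out: dict[str, str] = {}
    ref_names = sorted(references)
    for lab in np.unique(labels):
        members = [ids[i] for i in np.where(labels == lab)[0]]
        pts = np.vstack([dps[m].points for m in members])
        dists = {name: mean_point_distance(pts, references[name]) for name in ref_names}
        best = min(ref_names, key=lambda nme: (dists[nme], nme))
        label = best if dists[best] <= tau_tract else "none"
        for m in members:
            out[m] = label
    return out
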