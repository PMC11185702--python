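"""Left-right pairing within a dataset and cross-dataset type matching.

Within-dataset pairing mirrors one side onto the other, scores all pairs by
mean-of-directions NBLAST, and solves the optimal one-to-one assignment.
Cross-dataset matching transforms one dataset into the other's space,
combines morphology with connectivity cosine similarity, and accepts
mutual-best candidates above threshold. Accepted matches receive a 1-5
confidence from binning the combined score; confidence > 3 is "high".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import TreeSkeleton
from .morphology import (
    DotProps,
    LandmarkTransform,
    mirror_skeleton,
    to_dotprops,
    transform_skeleton,
)
from .nblast import ScoreMatrix, nblast_cross, nblast_normalized, nblast_raw

DEFAULT_TAU_PAIR = 0.3
DEFAULT_TAU_MATCH = 0.4
DEFAULT_WEIGHTS = (0.7, 0.3)
DEFAULT_CONFIDENCE_CUTS = (0.2, 0.4, 0.6, 0.8)


@dataclass
class MatchResult:
    """One scored candidate correspondence between two neurons or types."""

    query_id: str
    target_id: str | None
    forward_norm: float = float("nan")
    reverse_norm: float = float("nan")
    conn_cosine: float | None = None
    combined: float = float("nan")
    confidence: int | None = None
    status: str = "unmatched"  # matched | unmatched | ambiguous

    @property
    def mean_score(self) -> float:
        return 0.5 * (self.forward_norm + self.reverse_norm)

    @property
    def high_confidence(self) -> bool:
        return self.confidence is not None and self.confidence > 3


def matches_to_frame(matches: list[MatchResult]) -> pd.DataFrame:
    """Tabulate MatchResults for CSV output."""
    return pd.DataFrame(
        [
            {
                "query_id": m.query_id,
                "target_id": m.target_id,
                "forward_norm": m.forward_norm,
                "reverse_norm": m.reverse_norm,
                "mean_score": m.mean_score,
                "conn_cosine": m.conn_cosine,
                "combined": m.combined,
                "confidence": m.confidence,
                "status": m.status,
            }
            for m in matches
        ]
    )


def assign_confidence(
    match: MatchResult, cuts: tuple[float, float, float, float] = DEFAULT_CONFIDENCE_CUTS
) -> int:
    """Bin a matched result's combined score into confidence 1-5."""
    if match.status != "matched":
        raise ValueError("confidence is defined only for matched results")
    if list(cuts) != sorted(cuts):
        raise ValueError("confidence cuts must be increasing")
    return int(np.searchsorted(np.asarray(cuts), match.combined, side="left") + 1)


def connectivity_cosine(
    vec_a: dict[str, float],
    vec_b: dict[str, float],
    partner_correspondence: dict[str, str] | None = None,
) -> float | None:
    """Cosine similarity of two partner-weight vectors after alignment.

    ``partner_correspondence`` maps a-partner keys to b-partner keys;
    partners absent from the correspondence are dropped from both sides.
    Returns None when either aligned vector is all-zero (no evidence).
    """
    if partner_correspondence is None:
        keys = sorted(set(vec_a) | set(vec_b))
        a = np.array([vec_a.get(k, 0.0) for k in keys])
        b = np.array([vec_b.get(k, 0.0) for k in keys])
    else:
        pairs = sorted(partner_correspondence.items())
        a = np.array([vec_a.get(ka, 0.0) for ka, _ in pairs])
        b = np.array([vec_b.get(kb, 0.0) for _, kb in pairs])
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return None
    return float(a @ b / (na * nb))


def _dotprops_for(
    skeletons: dict[str, TreeSkeleton],
    ids: list[str],
    k: int,
    spacing: float,
    mirror_plane: tuple[str, float] | None = None,
    transform: LandmarkTransform | None = None,
) -> list[DotProps]:
    out = []
    for nid in ids:
        sk = skeletons[nid]
        if mirror_plane is not None:
            sk = mirror_skeleton(sk, *mirror_plane)
        if transform is not None:
            sk = transform_skeleton(transform, sk)
        out.append(to_dotprops(sk, k=k, spacing=spacing))
    return out


def _mirror_onto_left(
    skeletons: dict[str, TreeSkeleton],
    ids: list[str],
    k: int,
    spacing: float,
    plane: tuple[str, float],
    mirror_transform: LandmarkTransform | None,
) -> list[DotProps]:
    """Right-side dotprops flipped into left-side space.

    A fitted mirroring registration takes precedence over the plane: in a
    dataset whose native space is warped, the midline is no longer an
    axis-aligned plane and a landmark-based mirror transform is needed.
    """
    if mirror_transform is not None:
        return _dotprops_for(skeletons, ids, k, spacing, transform=mirror_transform)
    return _dotprops_for(skeletons, ids, k, spacing, mirror_plane=plane)


def pair_left_right(
    skeletons: dict[str, TreeSkeleton],
    meta: pd.DataFrame,
    plane_axis: str = "x",
    plane_position: float = 0.0,
    scoring: ScoreMatrix | None = None,
    sigma_um: float = 3.0,
    tau_pair: float = DEFAULT_TAU_PAIR,
    k: int = 5,
    spacing: float = 1000.0,
    confidence_cuts: tuple[float, float, float, float] = DEFAULT_CONFIDENCE_CUTS,
    mirror_transform: LandmarkTransform | None = None,
) -> list[MatchResult]:
    """Pair left and right neurons of one dataset by mirrored NBLAST.

    Right-side neurons are mirrored onto the left; the optimal one-to-one
    assignment maximizing total mean NBLAST score is solved; pairs scoring
    below ``tau_pair`` are reported unmatched, as are surplus neurons on the
    larger side. Ties are broken by lexicographic neuron_id through the
    sorted input order.
    """
    meta = meta.set_index("neuron_id") if "neuron_id" in meta.columns else meta
    left_ids = sorted(i for i in skeletons if meta.loc[i, "side"] == "left")
    right_ids = sorted(i for i in skeletons if meta.loc[i, "side"] == "right")
    results: list[MatchResult] = []
    if not left_ids or not right_ids:
        for nid in left_ids + right_ids:
            results.append(MatchResult(query_id=nid, target_id=None, status="unmatched"))
        return results

    dp_left = _dotprops_for(skeletons, left_ids, k, spacing)
    dp_right = _mirror_onto_left(
        skeletons, right_ids, k, spacing, (plane_axis, plane_position), mirror_transform
    )
    score = nblast_cross(dp_left, dp_right, scoring, sigma_um)
    rows, cols = linear_sum_assignment(-score)
    assigned_right = set()
    paired = {}
    for i, j in zip(rows, cols):
        paired[left_ids[i]] = (right_ids[j], i, j)
        assigned_right.add(right_ids[j])
    for li in left_ids:
        if li in paired:
            ri, i, j = paired[li]
            s = float(score[i, j])
            if s >= tau_pair:
                m = MatchResult(
                    query_id=li, target_id=ri, forward_norm=s, reverse_norm=s,
                    combined=s, status="matched",
                )
                m.confidence = assign_confidence(m, confidence_cuts)
                results.append(m)
                continue
        results.append(MatchResult(query_id=li, target_id=None, status="unmatched"))
    for ri in right_ids:
        if ri not in assigned_right:
            results.append(MatchResult(query_id=ri, target_id=None, status="unmatched"))
    return results


def match_across_datasets(
    skeletons_a: dict[str, TreeSkeleton],
    skeletons_b: dict[str, TreeSkeleton],
    transform: LandmarkTransform | None = None,
    conn_a: dict[str, dict[str, float]] | None = None,
    conn_b: dict[str, dict[str, float]] | None = None,
    partner_correspondence: dict[str, str] | None = None,
    scoring: ScoreMatrix | None = None,
    sigma_um: float = 3.0,
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
    tau_match: float = DEFAULT_TAU_MATCH,
    k: int = 5,
    spacing: float = 1000.0,
    group_a: dict[str, str] | None = None,
    group_b: dict[str, str] | None = None,
    confidence_cuts: tuple[float, float, float, float] = DEFAULT_CONFIDENCE_CUTS,
) -> list[MatchResult]:
    """Match units of dataset A onto dataset B after a landmark transform.

    Units are neurons, or groups/types when ``group_a``/``group_b`` map
    neuron ids to group labels (a group's morphology score against another
    group is the mean over its members of the best member-wise score).
    ``combined = w_morph * mean_nblast + w_conn * conn_cosine``; when the
    cosine is unavailable the weights renormalize onto morphology alone.
    Mutual-best pairs with combined >= ``tau_match`` are matched; units whose
    best score clears the threshold without being mutual-best are ambiguous;
    the rest are unmatched.
    """
    w_morph, w_conn = weights
    if not np.isclose(w_morph + w_conn, 1.0):
        raise ValueError("weights must sum to 1")

    ids_a = sorted(skeletons_a)
    ids_b = sorted(skeletons_b)
    dp_a = _dotprops_for(skeletons_a, ids_a, k, spacing, transform=transform)
    dp_b = _dotprops_for(skeletons_b, ids_b, k, spacing)
    neuron_score = nblast_cross(dp_a, dp_b, scoring, sigma_um)

    if group_a is None:
        group_a = {i: i for i in ids_a}
    if group_b is None:
        group_b = {i: i for i in ids_b}
    units_a = sorted(set(group_a[i] for i in ids_a))
    units_b = sorted(set(group_b[i] for i in ids_b))
    members_a = {u: [i for i in ids_a if group_a[i] == u] for u in units_a}
    members_b = {u: [i for i in ids_b if group_b[i] == u] for u in units_b}
    ia = {i: n for n, i in enumerate(ids_a)}
    ib = {i: n for n, i in enumerate(ids_b)}

    morph = np.empty((len(units_a), len(units_b)))
    for x, ua in enumerate(units_a):
        for y, ub in enumerate(units_b):
            block = neuron_score[np.ix_([ia[i] for i in members_a[ua]],
                                        [ib[j] for j in members_b[ub]])]
            # mean over members of each side's best member-wise score
            morph[x, y] = 0.5 * (block.max(axis=1).mean() + block.max(axis=0).mean())

    combined = np.empty_like(morph)
    cosines: dict[tuple[int, int], float | None] = {}
    for x, ua in enumerate(units_a):
        for y, ub in enumerate(units_b):
            cos = None
            if conn_a is not None and conn_b is not None:
                cos = connectivity_cosine(
                    conn_a.get(ua, {}), conn_b.get(ub, {}), partner_correspondence
                )
            cosines[(x, y)] = cos
            if cos is None:
                combined[x, y] = morph[x, y]
            else:
                combined[x, y] = w_morph * morph[x, y] + w_conn * cos

    best_for_a = combined.argmax(axis=1)
    best_for_b = combined.argmax(axis=0)
    results: list[MatchResult] = []
    for x, ua in enumerate(units_a):
        y = int(best_for_a[x])
        score = float(combined[x, y])
        m = MatchResult(
            query_id=ua,
            target_id=units_b[y],
            forward_norm=float(morph[x, y]),
            reverse_norm=float(morph[x, y]),
            conn_cosine=cosines[(x, y)],
            combined=score,
        )
        if score >= tau_match and int(best_for_b[y]) == x:
            m.status = "matched"
            m.confidence = assign_confidence(m, confidence_cuts)
        elif score >= tau_match:
            m.status = "ambiguous"
        else:
            m.status = "unmatched"
            m.target_id = None
        results.append(m)
    return results
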