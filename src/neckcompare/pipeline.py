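"""End-to-end comparative analysis of a paired female/male connectome.

Chains the stages the package implements: left-right pairing within each
dataset, landmark-transform fitting and cross-dataset type matching
(morphology + connectivity), neuropil annotation, information-flow ranking,
and dimorphism classification — and scores each stage against a synthetic
connectome's ground-truth manifest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import VNC_ABBREVIATIONS, assign_vnc_neuropil
from .connectivity import build_adjacency, information_flow_rank
from .core import neuropil_counts
from .dimorphism import TypeEvidence, classify_types
from .matching import MatchResult, match_across_datasets, pair_left_right
from .morphology import fit_landmark_transform
from .synthetic import SyntheticConnectome

MATCHABLE_CLASSES = ("DN", "AN")


def _matchable_ids(sc: SyntheticConnectome, ds: str) -> list[str]:
    m = sc.meta
    sel = (m["dataset_id"] == ds) & m["neuron_class"].isin(MATCHABLE_CLASSES)
    return sorted(m.loc[sel, "neuron_id"])


def run_lr_pairing(sc: SyntheticConnectome, ds: str, **kwargs) -> list[MatchResult]:
    """Pair left/right DN and AN neurons of one dataset.

    Uses the dataset's mirroring registration (fitted from its mirror
    landmark table) so pairing also works in a dataset whose native space
    is warped away from plane symmetry.
    """
    ids = _matchable_ids(sc, ds)
    skels = {i: sc.skeletons[ds][i] for i in ids}
    mt = None
    if ds in sc.mirror_landmarks:
        msrc, mdst = sc.mirror_landmarks[ds]
        mt = fit_landmark_transform(msrc, mdst)
    return pair_left_right(
        skels,
        sc.meta[sc.meta["dataset_id"] == ds],
        plane_axis=sc.config.mirror_axis,
        plane_position=sc.config.mirror_position,
        mirror_transform=mt,
        **kwargs,
    )


def scaffold_partner_vectors(sc: SyntheticConnectome, ds: str) -> dict[str, dict[str, float]]:
    """Per-group connectivity vectors over the shared scaffold types.

    Entries are total weights from sensory types ("in:SN_<modality>") and to
    motor types ("out:MN<k>"); the scaffold type names are shared between
    datasets, so the partner correspondence is the identity on these keys.
    """
    meta = sc.meta[sc.meta["dataset_id"] == ds]
    group_of = dict(zip(meta["neuron_id"], meta["group_id"]))
    cls_of = dict(zip(meta["neuron_id"], meta["neuron_class"]))
    # scaffold group "F-SN_visual" -> partner key "SN_visual"
    scaffold_key = {
        nid: group_of[nid].split("-", 1)[1]
        for nid in group_of
        if cls_of[nid] in ("SN", "MN")
    }
    out: dict[str, dict[str, float]] = {}
    for _, row in sc.synapses[ds].iterrows():
        pre, post = row["pre_id"], row["post_id"]
        if pre in scaffold_key and cls_of.get(post) in MATCHABLE_CLASSES:
            g = group_of[post]
            key = f"in:{scaffold_key[pre]}"
            out.setdefault(g, {})
            out[g][key] = out[g].get(key, 0.0) + 1.0
        elif post in scaffold_key and cls_of.get(pre) in MATCHABLE_CLASSES:
            g = group_of[pre]
            key = f"out:{scaffold_key[post]}"
            out.setdefault(g, {})
            out[g][key] = out[g].get(key, 0.0) + 1.0
    return out


def run_cross_matching(sc: SyntheticConnectome, **kwargs) -> list[MatchResult]:
    """Match female groups onto male groups: TPS transform + NBLAST + cosine."""
    src, dst = sc.landmarks
    transform = fit_landmark_transform(src, dst)
    ids_f = _matchable_ids(sc, "F")
    ids_m = _matchable_ids(sc, "M")
    meta = sc.meta.set_index("neuron_id")
    conn_f = scaffold_partner_vectors(sc, "F")
    conn_m = scaffold_partner_vectors(sc, "M")
    partner_keys = sorted(set().union(*conn_f.values(), *conn_m.values())) if conn_f else []
    correspondence = {k: k for k in partner_keys}
    return match_across_datasets(
        {i: sc.skeletons["F"][i] for i in ids_f},
        {i: sc.skeletons["M"][i] for i in ids_m},
        transform=transform,
        conn_a=conn_f,
        conn_b=conn_m,
        partner_correspondence=correspondence or None,
        group_a={i: meta.loc[i, "group_id"] for i in ids_f},
        group_b={i: meta.loc[i, "group_id"] for i in ids_m},
        **kwargs,
    )


def evaluate_lr_pairing(sc: SyntheticConnectome, ds: str, results: list[MatchResult]) -> dict:
    """Fraction of planted left-right pairs recovered, and their confidences."""
    truth = {tuple(p) for p in sc.manifest["lr_pairs"][ds]}
    found = {
        (m.query_id, m.target_id) for m in results if m.status == "matched"
    }
    found |= {(b, a) for a, b in found}
    hit = sum(1 for p in truth if p in found)
    matched = [m for m in results if m.status == "matched"]
    high = sum(1 for m in matched if m.high_confidence)
    return {
        "n_true_pairs": len(truth),
        "n_recovered": hit,
        "recovery_rate": hit / len(truth) if truth else float("nan"),
        "high_confidence_fraction": high / len(matched) if matched else float("nan"),
    }


def evaluate_cross_matching(sc: SyntheticConnectome, results: list[MatchResult]) -> dict:
    """Fraction of planted cross-dataset correspondences recovered."""
    truth = {a: b for a, b in sc.manifest["cross_pairs"]}
    by_query = {m.query_id: m for m in results}
    hit = 0
    high = 0
    for a, b in truth.items():
        m = by_query.get(a)
        if m is not None and m.status == "matched" and m.target_id == b:
            hit += 1
            if m.high_confidence:
                high += 1
    matched = [m for m in results if m.status == "matched"]
    n_high = sum(1 for m in matched if m.high_confidence)
    return {
        "n_true_pairs": len(truth),
        "n_recovered": hit,
        "recovery_rate": hit / len(truth) if truth else float("nan"),
        "high_confidence_fraction": n_high / len(matched) if matched else float("nan"),
    }


def build_type_evidence(
    sc: SyntheticConnectome,
    lr_f: list[MatchResult],
    lr_m: list[MatchResult],
    cross: list[MatchResult],
) -> list[TypeEvidence]:
    """Assemble the per-type evidence records the dimorphism classifier needs.

    Types are the union of within-dataset groups linked by the cross-dataset
    matching; left-right pairing supplies lr_paired/lr_score, the cross
    matching supplies status and morphology score, and member counts come
    from the metadata.
    """
    meta = sc.meta[sc.meta["neuron_class"].isin(MATCHABLE_CLASSES)]
    group_of = dict(zip(meta["neuron_id"], meta["group_id"]))
    sizes = meta.groupby("group_id").size().to_dict()
    flags = meta.groupby("group_id")[
        ["well_reconstructed", "peptidergic", "ahn", "abdominal_issue"]
    ].agg(
        {
            "well_reconstructed": "all",
            "peptidergic": "any",
            "ahn": "any",
            "abdominal_issue": "any",
        }
    )

    # group-level left-right evidence per dataset
    lr_by_group: dict[str, list[float]] = {}
    for res in (lr_f, lr_m):
        for m in res:
            g = group_of.get(m.query_id)
            if g is None:
                continue
            if m.status == "matched" and group_of.get(m.target_id) == g:
                lr_by_group.setdefault(g, []).append(m.combined)

    by_query = {m.query_id: m for m in cross}
    matched_targets = {
        m.target_id: m for m in cross if m.status == "matched"
    }
    groups_f = sorted(g for g in sizes if g.startswith("F-"))
    groups_m = sorted(g for g in sizes if g.startswith("M-"))

    evidence = []
    seen_m: set[str] = set()
    for g in groups_f:
        m = by_query.get(g)
        scores = list(lr_by_group.get(g, []))
        size_a = sizes.get(g, 0)
        if m is not None and m.status == "matched":
            tgt = m.target_id
            seen_m.add(tgt)
            scores += lr_by_group.get(tgt, [])
            size_b = sizes.get(tgt, 0)
            cross_status, cross_score = "matched", m.forward_norm
            fl = flags.loc[[g, tgt]].agg(
                {
                    "well_reconstructed": "all",
                    "peptidergic": "any",
                    "ahn": "any",
                    "abdominal_issue": "any",
                }
            )
        else:
            size_b = 0
            cross_status = m.status if m is not None else "unmatched"
            cross_score = m.forward_norm if m is not None else float("nan")
            fl = flags.loc[g]
        evidence.append(
            TypeEvidence(
                type_name=g,
                lr_paired=len(scores) > 0,
                lr_score=float(np.mean(scores)) if scores else float("nan"),
                cross_status=cross_status,
                cross_morph_score=float(cross_score),
                group_size_a=int(size_a),
                group_size_b=int(size_b),
                well_reconstructed=bool(fl["well_reconstructed"]),
                peptidergic=bool(fl["peptidergic"]),
                ahn=bool(fl["ahn"]),
                abdominal_issue=bool(fl["abdominal_issue"]),
            )
        )
    for g in groups_m:
        if g in seen_m:
            continue
        scores = lr_by_group.get(g, [])
        fl = flags.loc[g]
        evidence.append(
            TypeEvidence(
                type_name=g,
                lr_paired=len(scores) > 0,
                lr_score=float(np.mean(scores)) if scores else float("nan"),
                cross_status="unmatched",
                cross_morph_score=float("nan"),
                group_size_a=0,
                group_size_b=int(sizes.get(g, 0)),
                well_reconstructed=bool(fl["well_reconstructed"]),
                peptidergic=bool(fl["peptidergic"]),
                ahn=bool(fl["ahn"]),
                abdominal_issue=bool(fl["abdominal_issue"]),
            )
        )
    return evidence


def planted_dimorphism_labels(sc: SyntheticConnectome) -> dict[str, str]:
    """Ground-truth dimorphism label per within-dataset group id."""
    out = {}
    for tname, rec in sc.manifest["types"].items():
        for ds in rec["present_in"]:
            out[f"{ds}-{tname}"] = rec["dimorphism"]
    return out


def evaluate_dimorphism(sc: SyntheticConnectome, report: pd.DataFrame) -> dict:
    """Precision/recall of sex_specific and sexually_dimorphic labels.

    Both prediction and truth are collapsed to the planted type: a type
    present in both datasets counts once (through its female group), a
    sex-specific type counts through the group in its home dataset.
    """
    truth = planted_dimorphism_labels(sc)
    pred = dict(zip(report["type_name"], report["label"]))
    # collapse to planted types: prefer the female group when present
    rows = {}
    for tname, rec in sc.manifest["types"].items():
        ds = "F" if "F" in rec["present_in"] else "M"
        g = f"{ds}-{tname}"
        rows[tname] = (truth[g], pred.get(g, "missing"))
    out = {}
    for label in ("sex_specific", "sexually_dimorphic"):
        tp = sum(1 for t, p in rows.values() if t == label and p == label)
        fp = sum(1 for t, p in rows.values() if t != label and p == label)
        fn = sum(1 for t, p in rows.values() if t == label and p != label)
        out[f"{label}_precision"] = tp / (tp + fp) if tp + fp else float("nan")
        out[f"{label}_recall"] = tp / (tp + fn) if tp + fn else float("nan")
    return out


def evaluate_neuropil_assignment(sc: SyntheticConnectome, ds: str = "F") -> dict:
    """Agreement of the VNC neuropil assigner with the planted compartments.

    DNs are evaluated on presynapse counts, ANs on postsynapse counts, per
    the assignment rule's direction convention.
    """
    counts = neuropil_counts(sc.synapses[ds])
    meta = sc.meta[sc.meta["dataset_id"] == ds].set_index("neuron_id")
    truth = sc.manifest["neuropil_truth"]
    n_eval = 0
    n_agree = 0
    for nid, sub in counts.groupby("neuron_id"):
        if nid not in meta.index:
            continue
        cls = meta.loc[nid, "neuron_class"]
        if cls not in MATCHABLE_CLASSES:
            continue
        col = "pre_count" if cls == "DN" else "post_count"
        c = dict(zip(sub["neuropil"], sub[col].astype(float)))
        c = {k: v for k, v in c.items() if v > 0}
        if not c:
            continue
        label = assign_vnc_neuropil(c, direction="pre" if cls == "DN" else "post")
        expected = VNC_ABBREVIATIONS.get(truth[nid], truth[nid])
        n_eval += 1
        n_agree += int(label == expected)
    return {
        "n_evaluated": n_eval,
        "agreement_rate": n_agree / n_eval if n_eval else float("nan"),
    }


def rank_depth_profile(
    sc: SyntheticConnectome,
    ds: str = "F",
    mode: str = "deterministic",
    n_runs: int = 100,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Mean information-flow rank by planted layer depth (AN=1, DN=2, MN=3)."""
    adj = build_adjacency(sc.synapses[ds])
    seeds = {
        mod: set(rec[ds])
        for mod, rec in sc.manifest["modal_seeds"].items()
        if ds in rec
    }
    ranks = information_flow_rank(
        adj, seeds, mode=mode, n_runs=n_runs, rng_seed=rng_seed
    )
    layer_of = {}
    for coll in ("types", "scaffold"):
        for tname, rec in sc.manifest[coll].items():
            if ds not in rec["members"]:
                continue
            for side in ("left", "right"):
                for nid in rec["members"][ds][side]:
                    layer_of[nid] = rec["layer"]
    mean_rank = ranks.mean(axis=1)
    df = pd.DataFrame(
        {"rank": mean_rank, "layer": [layer_of.get(i) for i in ranks.index]}
    ).dropna()
    return df.groupby("layer")["rank"].mean().reset_index()
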