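"""Synthetic paired female/male connectomes with planted ground truth.

The generator emulates the statistical structure of the inputs the rest of
the package analyses: two "sex" datasets of left/right skeleton pairs
related by mirroring, a cross-dataset affine + smooth warp, type-structured
layered connectivity (sensory -> AN -> DN -> MN), axis-aligned neuropil
compartments, and planted sex-specific and sexually dimorphic types. A
ground-truth manifest records every planted fact so the matching,
annotation, connectivity and dimorphism stages can be scored against it.

Templates are grown by a seeded branching process inside each type's home
compartment; per-dataset, per-side instances add mirror reflection, node
jitter and (for the male dataset) the cross-dataset transform. Synapse
counts per connected member pair are Poisson draws around a type-level
weight matrix W.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import TreeSkeleton
from .errors import GenerationError
from .morphology import mirror

UM = 1000.0  # nm per um

#: VNC compartments laid out on a y-z grid; x spans both sides of the midline.
BOX_NAMES = (
    "NTct", "WTct", "HTct", "IntTct", "LTct",
    "LegNpT1", "LegNpT2", "LegNpT3", "mVAC", "Ov", "ANm",
)

AN_HEMILINEAGES = ("08B", "01A", "12A", "19A", "06B", "13B", "07B", "03A")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic connectome.

    Defaults give a smoke-scale connectome; :func:`recovery_config` is the
    60-type recovery preset with planted sex-specific and dimorphic types.
    """

    n_types: int = 20
    members_per_type: int = 1  # per side
    n_sex_specific_a: int = 0  # present only in the female dataset
    n_sex_specific_b: int = 0  # present only in the male dataset
    n_dimorphic: int = 0
    # tree growth
    segment_mean_um: float = 4.0
    segment_sigma: float = 0.35
    branch_prob: float = 0.12
    direction_jitter: float = 0.35
    max_nodes: int = 60
    sigma_jitter_nm: float = 400.0
    # geometry
    mirror_axis: str = "x"
    mirror_position: float = 0.0
    box_size_um: float = 80.0
    box_margin_um: float = 4.0
    # cross-dataset transform (female -> male space)
    rotation_deg: float = 4.0
    scale: float = 1.05
    translation_um: tuple[float, float, float] = (20.0, 10.0, 5.0)
    warp_amplitude_um: float = 3.0
    warp_period_um: float = 250.0
    landmark_grid: int = 6
    landmark_noise_um: float = 2.0
    # dimorphic modification: scale the designated (~half-arbor) subtree
    dimorphic_scale: float = 1.6
    # connectivity
    modalities: tuple[str, ...] = ("visual", "auditory", "taste-peg")
    n_mn_types: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sex_specific_a + self.n_sex_specific_b + self.n_dimorphic > self.n_types:
            raise GenerationError("more special types than types")
        if not 0 <= self.branch_prob <= 1:
            raise GenerationError("branch_prob must be a probability")


@dataclass
class SyntheticConnectome:
    """Generated datasets plus the ground-truth manifest."""

    skeletons: dict[str, dict[str, TreeSkeleton]]  # dataset -> neuron_id -> skel
    synapses: dict[str, pd.DataFrame]  # dataset -> synapse table
    meta: pd.DataFrame
    landmarks: tuple[np.ndarray, np.ndarray]  # (src in F space, dst in M space)
    #: per-dataset mirroring registration landmarks: point -> its mirror image,
    #: both in that dataset's native space
    mirror_landmarks: dict[str, tuple[np.ndarray, np.ndarray]]
    manifest: dict
    config: GeneratorConfig


def _boxes(cfg: GeneratorConfig) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Axis-aligned compartment boxes (lo, hi) in nm, symmetric about x=0."""
    s = cfg.box_size_um * UM
    out = {}
    for i, name in enumerate(BOX_NAMES):
        iy, iz = i % 4, i // 4
        lo = np.array([-1.5 * s, iy * s, iz * s])
        hi = np.array([1.5 * s, (iy + 1) * s, (iz + 1) * s])
        out[name] = (lo, hi)
    return out


def box_label(point: np.ndarray, boxes: dict[str, tuple[np.ndarray, np.ndarray]]) -> str | None:
    """Name of the compartment containing a point (boundaries inclusive)."""
    for name, (lo, hi) in boxes.items():
        if np.all(point >= lo) and np.all(point <= hi):
            return name
    return None


def _grow_template(
    rng: np.random.Generator, lo: np.ndarray, hi: np.ndarray, cfg: GeneratorConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Grow one left-side template tree inside a box; returns (coords, parents).

    Growth is a branching random walk: tips extend by lognormal segment
    lengths with jittered directions, reflecting off the box walls; each
    extension branches with probability ``branch_prob``.
    """
    m = cfg.box_margin_um * UM
    glo = lo + m
    ghi = hi - m
    # left-side half: keep x below the midline with a margin
    ghi = ghi.copy()
    ghi[0] = -2.0 * cfg.sigma_jitter_nm - m
    if np.any(ghi <= glo):
        raise GenerationError("compartment box too small for growth margins")
    soma = glo + rng.random(3) * (ghi - glo)
    coords = [soma]
    parents = [-1]
    d0 = rng.standard_normal(3)
    d0 /= np.linalg.norm(d0)
    tips: deque[tuple[int, np.ndarray]] = deque([(0, d0)])
    while tips and len(coords) < cfg.max_nodes:
        idx, d = tips.popleft()
        L = rng.lognormal(np.log(cfg.segment_mean_um * UM), cfg.segment_sigma)
        nd = d + cfg.direction_jitter * rng.standard_normal(3)
        nd /= np.linalg.norm(nd)
        new = coords[idx] + L * nd
        for ax in range(3):
            if new[ax] < glo[ax]:
                new[ax] = glo[ax] + (glo[ax] - new[ax])
                nd[ax] = -nd[ax]
            if new[ax] > ghi[ax]:
                new[ax] = ghi[ax] - (new[ax] - ghi[ax])
                nd[ax] = -nd[ax]
        new = np.clip(new, glo, ghi)
        coords.append(new)
        parents.append(idx)
        child = len(coords) - 1
        tips.append((child, nd))
        if rng.random() < cfg.branch_prob:
            bd = nd + 0.8 * rng.standard_normal(3)
            bd /= np.linalg.norm(bd)
            tips.append((child, bd))
    return np.array(coords), np.array(parents, dtype=int)


def _subtree_sizes(parents: np.ndarray) -> np.ndarray:
    n = len(parents)
    size = np.ones(n, dtype=int)
    for i in range(n - 1, 0, -1):  # children have larger indices than parents
        size[parents[i]] += size[i]
    return size


def _designated_subtree(parents: np.ndarray) -> np.ndarray:
    """Node mask of the subtree whose size is closest to half the arbor."""
    n = len(parents)
    size = _subtree_sizes(parents)
    candidates = [i for i in range(1, n)]
    root = min(candidates, key=lambda i: (abs(size[i] - n / 2), i))
    mask = np.zeros(n, dtype=bool)
    mask[root] = True
    for i in range(root + 1, n):
        if mask[parents[i]]:
            mask[i] = True
    return mask


def _apply_dimorphic_scale(
    coords: np.ndarray, parents: np.ndarray, factor: float
) -> np.ndarray:
    """Scale the designated subtree radially about its root node."""
    mask = _designated_subtree(parents)
    root = int(np.argmax(mask))
    out = coords.copy()
    centre = coords[root]
    out[mask] = centre + factor * (coords[mask] - centre)
    return out


def _true_transform(cfg: GeneratorConfig):
    """The planted female -> male space transform: affine + smooth warp."""
    th = np.deg2rad(cfg.rotation_deg)
    R = np.array(
        [[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0.0, 0.0, 1.0]]
    )
    t = np.array(cfg.translation_um) * UM
    amp = cfg.warp_amplitude_um * UM
    period = cfg.warp_period_um * UM

    def f(points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        q = cfg.scale * (p @ R.T) + t
        warp = np.zeros_like(q)
        warp[:, 0] = amp * np.sin(2 * np.pi * p[:, 1] / period)
        warp[:, 2] = amp * np.cos(2 * np.pi * p[:, 1] / period)
        return (q + warp).reshape(np.shape(points))

    return f


def _skeleton_from(coords: np.ndarray, parents: np.ndarray, neuron_id: str) -> TreeSkeleton:
    n = len(parents)
    df = pd.DataFrame(
        {
            "node_id": np.arange(1, n + 1),
            "parent_id": np.where(parents < 0, -1, parents + 1),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "radius": 200.0,
            "label": 0,
        }
    )
    return TreeSkeleton(neuron_id=neuron_id, nodes=df)


def generate_connectome(cfg: GeneratorConfig) -> SyntheticConnectome:
    """Generate the paired female/male connectome described by ``cfg``.

    Deterministic for a fixed config: the same seed reproduces the output
    byte for byte.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    boxes = _boxes(cfg)
    box_names = list(BOX_NAMES)
    tf = _true_transform(cfg)

    # --- type roster -----------------------------------------------------
    # classes alternate so planted specials cover both DNs and ANs; the
    # special types sit at the end of the roster
    types = []
    n_special = cfg.n_sex_specific_a + cfg.n_sex_specific_b + cfg.n_dimorphic
    for i in range(cfg.n_types):
        cls = "AN" if i % 2 == 0 else "DN"
        box = box_names[i % len(box_names)]
        context = AN_HEMILINEAGES[i % len(AN_HEMILINEAGES)] if cls == "AN" else None
        kind = "matched"
        j = i - (cfg.n_types - n_special)
        if j >= 0:
            if j < cfg.n_sex_specific_a:
                kind = "sex_specific_a"
            elif j < cfg.n_sex_specific_a + cfg.n_sex_specific_b:
                kind = "sex_specific_b"
            else:
                kind = "dimorphic"
        types.append(
            {
                "name": f"T{i:03d}",
                "neuron_class": cls,
                "home_box": box,
                "context": context,
                "kind": kind,
            }
        )

    scaffold = []
    for m in cfg.modalities:
        scaffold.append(
            {"name": f"SN_{m}", "neuron_class": "SN", "home_box": box_names[0],
             "modality": m}
        )
    for i in range(cfg.n_mn_types):
        scaffold.append(
            {"name": f"MN{i:02d}", "neuron_class": "MN",
             "home_box": box_names[(5 + i) % len(box_names)], "modality": None}
        )

    # --- templates -------------------------------------------------------
    templates: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for t in types + scaffold:
        lo, hi = boxes[t["home_box"]]
        templates[t["name"]] = _grow_template(rng, lo, hi, cfg)

    # --- type-level weight matrix W (expected synapses per member pair) ---
    W: dict[tuple[str, str], float] = {}
    an_types = [t["name"] for t in types if t["neuron_class"] == "AN"]
    dn_types = [t["name"] for t in types if t["neuron_class"] == "DN"]
    sn_types = [s["name"] for s in scaffold if s["neuron_class"] == "SN"]
    mn_types = [s["name"] for s in scaffold if s["neuron_class"] == "MN"]
    for an in an_types:
        for sn in sn_types:
            if rng.random() < 0.7:
                W[(sn, an)] = float(rng.uniform(15.0, 45.0))
    for dn in dn_types:
        an_in = 0.0
        for an in an_types:
            if rng.random() < 0.3:
                w = float(rng.uniform(15.0, 45.0))
                W[(an, dn)] = w
                an_in += w
        if an_in == 0.0:  # guarantee every DN is reachable from sensory seeds
            an = an_types[int(rng.integers(len(an_types)))]
            w = float(rng.uniform(15.0, 45.0))
            W[(an, dn)] = w
            an_in = w
        # direct sensory drive capped below the spreading threshold so the
        # planted layer depth (AN=1, DN=2, MN=3) survives deterministic ranking
        direct = {}
        for sn in sn_types:
            if rng.random() < 0.6:
                direct[sn] = float(rng.uniform(3.0, 10.0))
        cap = 0.20 * an_in
        tot = sum(direct.values())
        if tot > cap and tot > 0:
            direct = {k: v * cap / tot for k, v in direct.items()}
        for sn, w in direct.items():
            W[(sn, dn)] = w
    for mn in mn_types:
        got = False
        for dn in dn_types:
            if rng.random() < 0.4:
                W[(dn, mn)] = float(rng.uniform(15.0, 45.0))
                got = True
        if not got:
            W[(dn_types[0], mn)] = 30.0

    # --- instantiate neurons ---------------------------------------------
    present_in: dict[str, list[str]] = {}
    for t in types:
        if t["kind"] == "sex_specific_a":
            present_in[t["name"]] = ["F"]
        elif t["kind"] == "sex_specific_b":
            present_in[t["name"]] = ["M"]
        else:
            present_in[t["name"]] = ["F", "M"]
    for s in scaffold:
        present_in[s["name"]] = ["F", "M"]

    all_units = types + scaffold
    skeletons: dict[str, dict[str, TreeSkeleton]] = {"F": {}, "M": {}}
    template_space: dict[str, dict[str, np.ndarray]] = {"F": {}, "M": {}}
    meta_rows = []
    members: dict[str, dict[str, dict[str, list[str]]]] = {}
    for t in all_units:
        name = t["name"]
        coords0, parents = templates[name]
        members[name] = {}
        for ds in ("F", "M"):
            if ds not in present_in[name]:
                continue
            members[name][ds] = {"left": [], "right": []}
            base = coords0
            if ds == "M" and t.get("kind") == "dimorphic":
                base = _apply_dimorphic_scale(coords0, parents, cfg.dimorphic_scale)
            for side, side_key in (("left", "L"), ("right", "R")):
                for k in range(cfg.members_per_type):
                    nid = f"{ds}-{name}-{side_key}{k}"
                    c = base + rng.normal(0.0, cfg.sigma_jitter_nm, size=base.shape)
                    lo, hi = boxes[t["home_box"]]
                    c = np.clip(c, lo, hi)
                    if side == "right":
                        c = mirror(c, cfg.mirror_axis, cfg.mirror_position)
                    template_space[ds][nid] = c
                    out_c = tf(c) if ds == "M" else c
                    skeletons[ds][nid] = _skeleton_from(out_c, parents, nid)
                    members[name][ds][side].append(nid)
                    meta_rows.append(
                        {
                            "neuron_id": nid,
                            "dataset_id": ds,
                            "side": side,
                            "neuron_class": t["neuron_class"],
                            "group_id": f"{ds}-{name}",
                            "well_reconstructed": True,
                            "peptidergic": False,
                            "ahn": False,
                            "abdominal_issue": False,
                        }
                    )
    meta = pd.DataFrame(meta_rows)

    # --- synapses ---------------------------------------------------------
    cls_of = {t["name"]: t["neuron_class"] for t in all_units}
    synapses: dict[str, pd.DataFrame] = {}
    for ds in ("F", "M"):
        rows = []
        for (pre_t, post_t) in sorted(W):
            if ds not in present_in[pre_t] or ds not in present_in[post_t]:
                continue
            w = W[(pre_t, post_t)]
            for side in ("left", "right"):
                for pre_n in members[pre_t][ds][side]:
                    for post_n in members[post_t][ds][side]:
                        count = int(rng.poisson(w))
                        if count == 0:
                            continue
                        # synapse sites sit on the AN dendrite when the
                        # target is an AN, else on the presynaptic arbour
                        host = post_n if cls_of[post_t] == "AN" else pre_n
                        pts = template_space[ds][host]
                        sel = rng.integers(0, len(pts), size=count)
                        for s in sel:
                            p = pts[s]
                            lab = box_label(p, boxes)
                            q = tf(p) if ds == "M" else p
                            rows.append(
                                (pre_n, post_n, q[0], q[1], q[2], lab)
                            )
        df = pd.DataFrame(
            rows, columns=["pre_id", "post_id", "x", "y", "z", "neuropil"]
        )
        if ds == "F" and len(df):
            # only the female dataset's synapse predictions carry cleft scores
            df["cleft_score"] = rng.integers(60, 250, size=len(df))
        synapses[ds] = df

    # --- landmarks ---------------------------------------------------------
    s = cfg.box_size_um * UM
    vol_lo = np.array([-1.5 * s, 0.0, 0.0])
    vol_hi = np.array([1.5 * s, 4 * s, 3 * s])
    g = cfg.landmark_grid
    axes = [np.linspace(vol_lo[i], vol_hi[i], g) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    src = grid + rng.normal(0.0, cfg.landmark_noise_um * UM, size=grid.shape)
    dst = tf(src)

    # within-dataset mirroring registrations: exact plane reflection in the
    # female space; its conjugate under the cross transform in the male space
    mgrid = grid + rng.normal(0.0, cfg.landmark_noise_um * UM, size=grid.shape)
    mgrid_mirror = mirror(mgrid, cfg.mirror_axis, cfg.mirror_position)
    mirror_landmarks = {
        "F": (mgrid, mgrid_mirror),
        "M": (tf(mgrid), tf(mgrid_mirror)),
    }

    # --- manifest -----------------------------------------------------------
    dimorphism_of = {
        "matched": "matched",
        "dimorphic": "sexually_dimorphic",
        "sex_specific_a": "sex_specific",
        "sex_specific_b": "sex_specific",
    }
    manifest = {
        "seed": cfg.rng_seed,
        "types": {
            t["name"]: {
                "neuron_class": t["neuron_class"],
                "home_box": t["home_box"],
                "context": t["context"],
                "present_in": present_in[t["name"]],
                "dimorphism": dimorphism_of[t["kind"]],
                "layer": 1 if t["neuron_class"] == "AN" else 2,
                "members": members[t["name"]],
            }
            for t in types
        },
        "scaffold": {
            st["name"]: {
                "neuron_class": st["neuron_class"],
                "home_box": st["home_box"],
                "modality": st["modality"],
                "layer": 0 if st["neuron_class"] == "SN" else 3,
                "members": members[st["name"]],
            }
            for st in scaffold
        },
        "lr_pairs": {
            ds: [
                [l, r]
                for t in types
                if ds in members[t["name"]]
                for l, r in zip(
                    members[t["name"]][ds]["left"], members[t["name"]][ds]["right"]
                )
            ]
            for ds in ("F", "M")
        },
        "cross_pairs": [
            [f"F-{t['name']}", f"M-{t['name']}"]
            for t in types
            if present_in[t["name"]] == ["F", "M"]
        ],
        "W": {f"{a}|{b}": w for (a, b), w in sorted(W.items())},
        "neuropil_truth": {
            nid: t["home_box"]
            for t in all_units
            for ds in members[t["name"]]
            for side in ("left", "right")
            for nid in members[t["name"]][ds][side]
        },
        "modal_seeds": {
            st["modality"]: {
                ds: members[st["name"]][ds]["left"] + members[st["name"]][ds]["right"]
                for ds in ("F", "M")
            }
            for st in scaffold
            if st["neuron_class"] == "SN"
        },
        "transform": {
            "rotation_deg": cfg.rotation_deg,
            "scale": cfg.scale,
            "translation_um": list(cfg.translation_um),
            "warp_amplitude_um": cfg.warp_amplitude_um,
            "warp_period_um": cfg.warp_period_um,
        },
    }

    return SyntheticConnectome(
        skeletons=skeletons,
        synapses=synapses,
        meta=meta,
        landmarks=(src, dst),
        mirror_landmarks=mirror_landmarks,
        manifest=manifest,
        config=cfg,
    )


def smoke_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Small smoke-scale preset: 20 types, no planted specials."""
    kw = dict(n_types=20, rng_seed=seed)
    kw.update(overrides)
    return GeneratorConfig(**kw)


def recovery_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Recovery preset: 60 types, 5 sex-specific + 5 dimorphic planted."""
    kw = dict(
        n_types=60,
        n_sex_specific_a=3,
        n_sex_specific_b=2,
        n_dimorphic=5,
        rng_seed=seed,
    )
    kw.update(overrides)
    return GeneratorConfig(**kw)


def make_acceptance_suite(out_dir, seed: int = 0) -> dict[str, str]:
    """Write the standard smoke and recovery fixtures to ``out_dir``.

    Each preset gets SWC skeletons, synapse and metadata CSVs, a landmark
    CSV and the ground-truth manifest JSON. Returns preset -> directory.
    """
    import os

    from .core import write_swc

    written = {}
    for preset, cfg in (
        ("smoke", smoke_config(seed)),
        ("recovery", recovery_config(seed)),
    ):
        sc = generate_connectome(cfg)
        d = os.path.join(str(out_dir), preset)
        os.makedirs(os.path.join(d, "swc"), exist_ok=True)
        for ds, skels in sc.skeletons.items():
            for nid, sk in skels.items():
                write_swc(sk, os.path.join(d, "swc", f"{nid}.swc"))
            sc.synapses[ds].to_csv(os.path.join(d, f"synapses_{ds}.csv"), index=False)
        sc.meta.to_csv(os.path.join(d, "meta.csv"), index=False)
        src, dst = sc.landmarks
        cols = ["x_src", "y_src", "z_src", "x_dst", "y_dst", "z_dst"]
        pd.DataFrame(np.hstack([src, dst]), columns=cols).to_csv(
            os.path.join(d, "landmarks.csv"), index=False
        )
        for ds, (msrc, mdst) in sc.mirror_landmarks.items():
            pd.DataFrame(np.hstack([msrc, mdst]), columns=cols).to_csv(
                os.path.join(d, f"mirror_landmarks_{ds}.csv"), index=False
            )
        with open(os.path.join(d, "manifest.json"), "w") as fh:
            json.dump(sc.manifest, fh, indent=1)
        written[preset] = d
    return written
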