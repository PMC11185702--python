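"""Sexual-dimorphism classification, synapse-density grids and type naming.

A cell type compared across the female and male cords is labelled by a
fixed precedence of rules: reconstruction problems and known exclusions
(neuropeptidergic neurons, the ascending histaminergic neurons, abdominal
reconstruction issues) come first; a type confidently paired left-right
within one dataset but absent from the other is sex-specific; a type
matched across datasets whose morphology nonetheless differs is sexually
dimorphic; a member-count difference alone is biological variation, not
dimorphism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import count

import numpy as np
import pandas as pd

from .core import filter_synapses

DEFAULT_TAU_SHAPE = 0.55
DEFAULT_TAU_LR = 0.7
DEFAULT_VOXEL_NM = 5000.0

LABELS = (
    "matched",
    "sex_specific",
    "sexually_dimorphic",
    "biological_variation",
    "reconstruction_issue",
    "excluded",
    "unpaired",
)


@dataclass
class TypeEvidence:
    """Per-type evidence consumed by :func:`classify_dimorphism`."""

    type_name: str
    lr_paired: bool
    lr_score: float
    cross_status: str  # matched | unmatched | ambiguous
    cross_morph_score: float
    group_size_a: int
    group_size_b: int
    well_reconstructed: bool = True
    peptidergic: bool = False
    ahn: bool = False
    abdominal_issue: bool = False


def classify_dimorphism(
    ev: TypeEvidence,
    tau_shape: float = DEFAULT_TAU_SHAPE,
    tau_lr: float = DEFAULT_TAU_LR,
) -> str:
    """Classify one type's evidence record; total over complete records.

    Precedence: reconstruction_issue > excluded > unpaired > sex_specific >
    sexually_dimorphic > biological_variation > matched.
    """
    if ev.cross_status not in ("matched", "unmatched", "ambiguous"):
        raise ValueError(f"invalid cross_status {ev.cross_status!r}")
    if not ev.well_reconstructed or ev.abdominal_issue:
        return "reconstruction_issue"
    if ev.peptidergic or ev.ahn:
        return "excluded"
    if not ev.lr_paired:
        return "unpaired"
    if ev.cross_status == "unmatched":
        return "sex_specific"
    if ev.cross_status == "matched":
        if ev.cross_morph_score < tau_shape and ev.lr_score >= tau_lr:
            return "sexually_dimorphic"
        if ev.group_size_a != ev.group_size_b:
            return "biological_variation"
        return "matched"
    # ambiguous cross matches carry no dimorphism evidence either way
    return "matched"


def classify_types(
    evidence: list[TypeEvidence],
    tau_shape: float = DEFAULT_TAU_SHAPE,
    tau_lr: float = DEFAULT_TAU_LR,
) -> pd.DataFrame:
    """Classify many types; returns a report table with the evidence used."""
    rows = []
    for ev in evidence:
        rows.append(
            {
                "type_name": ev.type_name,
                "label": classify_dimorphism(ev, tau_shape, tau_lr),
                "lr_paired": ev.lr_paired,
                "lr_score": ev.lr_score,
                "cross_status": ev.cross_status,
                "cross_morph_score": ev.cross_morph_score,
                "group_size_a": ev.group_size_a,
                "group_size_b": ev.group_size_b,
                "tau_shape": tau_shape,
                "tau_lr": tau_lr,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class VoxelGrid:
    """Counts of synapses in an axis-aligned grid of cubic voxels (nm)."""

    origin: np.ndarray
    voxel_size: float
    counts: np.ndarray  # 3-D integer array

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.counts.shape)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """Occupied voxels as (ix, iy, iz, count) rows."""
        ix, iy, iz = np.nonzero(self.counts)
        return pd.DataFrame(
            {"ix": ix, "iy": iy, "iz": iz, "count": self.counts[ix, iy, iz]}
        )


def synapse_density(
    synapses: pd.DataFrame,
    voxel_size: float = DEFAULT_VOXEL_NM,
    role: str = "pre",
    cleft_min: float | None = None,
) -> VoxelGrid:
    """Count synapses in roughly isotropic cubic voxels (default 5 um).

    The grid origin sits at the filtered synapses' coordinate-wise minimum;
    a synapse at coordinate c falls in voxel floor((c - origin)/voxel_size)
    (boundary points go to the higher-index voxel). ``role`` is metadata
    recording whether the table holds pre- or postsynaptic sites.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if role not in ("pre", "post"):
        raise ValueError("role must be 'pre' or 'post'")
    df = filter_synapses(synapses, cleft_min=cleft_min)
    if len(df) == 0:
        return VoxelGrid(origin=np.zeros(3), voxel_size=voxel_size,
                         counts=np.zeros((0, 0, 0), dtype=int))
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    origin = xyz.min(axis=0)
    idx = np.floor((xyz - origin) / voxel_size).astype(int)
    shape = idx.max(axis=0) + 1
    counts = np.zeros(shape, dtype=int)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    return VoxelGrid(origin=origin, voxel_size=voxel_size, counts=counts)


def assign_new_type_names(
    unmatched: list[tuple[str, str]],
    existing_names: set[str],
    start: int = 999,
    floor: int = 0,
) -> list[str]:
    """Systematic names for unmatched types, numbering down from 999.

    Each entry is (neuron_class, context_label) where the context is the
    target-neuropil abbreviation for DNs and the hemilineage for ANs;
    names are ``<class><context><number>`` with numbers descending from
    ``start``, skipping collisions with ``existing_names`` and names
    already issued in this call.
    """
    taken = set(existing_names)
    counters: dict[str, int] = {}
    out = []
    for neuron_class, context in unmatched:
        prefix = f"{neuron_class}{context}"
        n = counters.get(prefix, start)
        while f"{prefix}{n:03d}" in taken:
            n -= 1
            if n < floor:
                raise RuntimeError(f"name space exhausted for prefix {prefix!r}")
        name = f"{prefix}{n:03d}"
        if n < floor:
            raise RuntimeError(f"name space exhausted for prefix {prefix!r}")
        taken.add(name)
        counters[prefix] = n - 1
        out.append(name)
    return out


def render_comparative_name(type_name: str, dataset_sex: str) -> str:
    """Render a matched type's name for comparative tables.

    Female-dataset instances of types matched across datasets carry an
    appended "f"; male instances keep the bare name.
    """
    return f"{type_name}f" if dataset_sex == "female" else type_name
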