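"""NBLAST morphological similarity on dotprops.

For every query point the nearest target point is found; the pair's distance
d and absolute tangent dot product contribute one score term. The default
scoring is the parametric form ``|u.v| * exp(-d / sigma)`` (sigma 3 um,
distances in um); an empirical score matrix (distance x dot-product bins)
can be supplied instead, e.g. the published fly-calibrated one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import SchemaError
from .morphology import DotProps

NM_PER_UM = 1000.0
DEFAULT_SIGMA_UM = 3.0


@dataclass
class ScoreMatrix:
    """Empirical NBLAST scoring: a (distance bin) x (|dot| bin) score table.

    ``dist_edges`` are inner bin edges in um (the last bin is open above),
    ``dot_edges`` span [0, 1]. Lookup is defined for every d >= 0 and
    |dot| in [0, 1].
    """

    dist_edges: np.ndarray  # length n_dist + 1; last edge opens the top bin
    dot_edges: np.ndarray  # length n_dot + 1
    scores: np.ndarray  # n_dist x n_dot

    def __post_init__(self) -> None:
        self.dist_edges = np.asarray(self.dist_edges, dtype=float)
        self.dot_edges = np.asarray(self.dot_edges, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.dist_edges) <= 0) or np.any(np.diff(self.dot_edges) <= 0):
            raise SchemaError("score-matrix bin edges must be strictly increasing")
        if not np.all(np.isfinite(self.scores)):
            raise SchemaError("score-matrix entries must be finite")
        if self.scores.shape != (len(self.dist_edges) - 1, len(self.dot_edges) - 1):
            raise SchemaError("score-matrix shape does not match bin edges")

    def lookup(self, dist_um: np.ndarray, absdot: np.ndarray) -> np.ndarray:
        """Score for each (distance in um, |dot|) pair; top bins are open."""
        di = np.clip(
            np.searchsorted(self.dist_edges, dist_um, side="right") - 1,
            0,
            self.scores.shape[0] - 1,
        )
        ai = np.clip(
            np.searchsorted(self.dot_edges, absdot, side="right") - 1,
            0,
            self.scores.shape[1] - 1,
        )
        return self.scores[di, ai]


def _pointwise_scores(
    query: DotProps,
    target: DotProps,
    scoring: ScoreMatrix | None,
    sigma_um: float,
    use_alpha: bool,
) -> np.ndarray:
    tree = cKDTree(target.points)
    d_nm, j = tree.query(query.points, k=1)
    absdot = np.abs(np.einsum("ij,ij->i", query.tangents, target.tangents[j]))
    if use_alpha:
        absdot = absdot * np.sqrt(query.alpha * target.alpha[j])
    d_um = np.asarray(d_nm, dtype=float) / NM_PER_UM
    if scoring is None:
        return absdot * np.exp(-d_um / sigma_um)
    return scoring.lookup(d_um, absdot)


def nblast_raw(
    query: DotProps,
    target: DotProps,
    scoring: ScoreMatrix | None = None,
    sigma_um: float = DEFAULT_SIGMA_UM,
    use_alpha: bool = False,
) -> float:
    """Raw (summed) NBLAST score of ``query`` against ``target``."""
    if len(query) == 0 or len(target) == 0:
        raise ValueError("dotprops must be non-empty")
    return float(_pointwise_scores(query, target, scoring, sigma_um, use_alpha).sum())


def nblast_normalized(
    query: DotProps,
    target: DotProps,
    scoring: ScoreMatrix | None = None,
    sigma_um: float = DEFAULT_SIGMA_UM,
    use_alpha: bool = False,
) -> float:
    """Raw score divided by the query self-score; self-comparison gives 1."""
    self_score = nblast_raw(query, query, scoring, sigma_um, use_alpha)
    if self_score == 0:
        raise ZeroDivisionError("query self-score is zero; cannot normalize")
    if target is query:
        return 1.0
    return nblast_raw(query, target, scoring, sigma_um, use_alpha) / self_score


def nblast_mean(
    a: DotProps,
    b: DotProps,
    scoring: ScoreMatrix | None = None,
    sigma_um: float = DEFAULT_SIGMA_UM,
    use_alpha: bool = False,
) -> float:
    """Mean of the two normalized directions; symmetric in its arguments."""
    fwd = nblast_normalized(a, b, scoring, sigma_um, use_alpha)
    rev = nblast_normalized(b, a, scoring, sigma_um, use_alpha)
    return 0.5 * (fwd + rev)


def nblast_allbyall(
    items: list[DotProps],
    scoring: ScoreMatrix | None = None,
    sigma_um: float = DEFAULT_SIGMA_UM,
    use_alpha: bool = False,
) -> np.ndarray:
    """Full normalized score matrix; entry (i, j) = normalized(items[i], items[j])."""
    if len(items) < 2:
        raise ValueError("need at least 2 dotprops")
    n = len(items)
    self_scores = np.array(
        [nblast_raw(x, x, scoring, sigma_um, use_alpha) for x in items]
    )
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            out[i, j] = (
                nblast_raw(items[i], items[j], scoring, sigma_um, use_alpha)
                / self_scores[i]
            )
    return out


def nblast_cross(
    queries: list[DotProps],
    targets: list[DotProps],
    scoring: ScoreMatrix | None = None,
    sigma_um: float = DEFAULT_SIGMA_UM,
    use_alpha: bool = False,
) -> np.ndarray:
    """Mean-of-directions score matrix between two dotprops collections."""
    q_self = np.array([nblast_raw(q, q, scoring, sigma_um, use_alpha) for q in queries])
    t_self = np.array([nblast_raw(t, t, scoring, sigma_um, use_alpha) for t in targets])
    out = np.empty((len(queries), len(targets)))
    for i, q in enumerate(queries):
        for j, t in enumerate(targets):
            fwd = nblast_raw(q, t, scoring, sigma_um, use_alpha) / q_self[i]
            rev = nblast_raw(t, q, scoring, sigma_um, use_alpha) / t_self[j]
            out[i, j] = 0.5 * (fwd + rev)
    return out


def load_score_matrix(path) -> ScoreMatrix:
    """Read a score-matrix CSV whose first row/column carry the bin edges.

    Layout: cell (0, 0) is empty or a label; the header row holds the
    n_dot + 1 dot-product edges; the first column holds the n_dist + 1
    distance edges (um); the body is the (n_dist x n_dot) score block,
    aligned so scores sit between consecutive edges.
    """
    df = pd.read_csv(path, header=None)
    try:
        dot_edges = df.iloc[0, 1:].astype(float).to_numpy()
        dist_edges = df.iloc[1:, 0].astype(float).to_numpy()
        body = df.iloc[1:, 1:].astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"malformed score-matrix file: {exc}") from None
    scores = body[: len(dist_edges) - 1, : len(dot_edges) - 1]
    return ScoreMatrix(dist_edges=dist_edges, dot_edges=dot_edges, scores=scores)


def save_score_matrix(sm: ScoreMatrix, path) -> None:
    """Write a ScoreMatrix in the CSV layout read by :func:`load_score_matrix`."""
    n_dist, n_dot = sm.scores.shape
    with open(path, "w") as fh:
        fh.write("," + ",".join(f"{e:g}" for e in sm.dot_edges) + "\n")
        for i in range(n_dist + 1):
            row = [f"{sm.dist_edges[i]:g}"]
            if i < n_dist:
                row += [f"{v:g}" for v in sm.scores[i]]
            fh.write(",".join(row) + "\n")
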