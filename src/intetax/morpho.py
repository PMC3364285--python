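"""Landmark morphometrics of forewing shape.

Seven 2-D landmarks per wing (vein junctions and wing margins), digitized
twice per specimen. The analysis chain is: average the digitization
replicates landmark-wise, remove position/scale/orientation by generalized
Procrustes analysis (GPA), extract relative warps (principal components of
the Procrustes-aligned coordinates, uniform component included), test group
separation per axis with one-way ANOVA, and cluster specimens (Ward
linkage) on the leading axes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from scipy import stats
from sklearn.cluster import AgglomerativeClustering

from .partition import Partition

__all__ = [
    "LandmarkSet",
    "WarpScores",
    "read_tps",
    "write_tps",
    "average_replicates",
    "gpa",
    "relative_warps",
    "anova_by_axis",
    "cluster_specimens",
]

_GPA_TOL = 1e-10
_GPA_MAXITER = 1000


@dataclass
class LandmarkSet:
    """Landmark configurations with replicate structure and group labels.

    ``coords`` has shape (records, landmarks, 2); ``specimen_ids`` and
    ``replicates`` give, per record, the specimen and its digitization
    replicate index (0-based, in file order). ``groups`` maps specimen id
    to group label and may be empty for unlabeled data.
    """

    coords: np.ndarray
    specimen_ids: list[str]
    replicates: list[int]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (records, landmarks, 2)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if len(self.specimen_ids) != self.coords.shape[0]:
            raise ValueError("specimen_ids do not match coords")
        if len(self.replicates) != self.coords.shape[0]:
            raise ValueError("replicates do not match coords")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.coords.shape[0]

    def labels_for_records(self) -> list[str]:
        return [self.groups[s] for s in self.specimen_ids]


def read_tps(path) -> LandmarkSet:
    """Read a TPS landmark file (LM= blocks with ID=, optional IMAGE=).

    Repeated ID values are interpreted as digitization replicates in file
    order. All blocks must declare the same landmark count; a mismatch
    raises ``ValueError`` naming the block index.
    """
    blocks: list[tuple[np.ndarray, str]] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    block_idx = 0
    lm_expected: int | None = None
    while i < len(lines):
        if not lines[i].upper().startswith("LM="):
            raise ValueError(f"expected LM= at line {i + 1}")
        k = int(lines[i].split("=", 1)[1])
        if lm_expected is None:
            lm_expected = k
        elif k != lm_expected:
            raise ValueError(
                f"block {block_idx}: LM={k} differs from LM={lm_expected}"
            )
        i += 1
        pts = []
        for _ in range(k):
            x, y = lines[i].split()
            pts.append((float(x), float(y)))
            i += 1
        spec_id = f"spec{block_idx}"
        while i < len(lines) and not lines[i].upper().startswith("LM="):
            key, _, val = lines[i].partition("=")
            if key.upper() == "ID":
                spec_id = val.strip()
            i += 1
        blocks.append((np.array(pts), spec_id))
        block_idx += 1
    coords = np.stack([b[0] for b in blocks])
    ids = [b[1] for b in blocks]
    rep_counter: dict[str, int] = {}
    reps = []
    for s in ids:
        reps.append(rep_counter.get(s, 0))
        rep_counter[s] = reps[-1] + 1
    return LandmarkSet(coords, ids, reps)


def write_tps(lset: LandmarkSet, path) -> None:
    """Write a TPS file; round-trips exactly through :func:`read_tps`."""
    with open(path, "w") as fh:
        for rec in range(len(lset)):
            fh.write(f"LM={lset.n_landmarks}\n")
            for x, y in lset.coords[rec]:
                fh.write(f"{x:.17g} {y:.17g}\n")
            fh.write(f"ID={lset.specimen_ids[rec]}\n")
            fh.write(f"IMAGE={lset.specimen_ids[rec]}_r{lset.replicates[rec]}\n")


def average_replicates(lset: LandmarkSet) -> LandmarkSet:
    """Landmark-wise mean over each specimen's digitization replicates.

    Replicates share the digitization coordinate frame, so raw averaging
    (before any superimposition) is the appropriate measurement-error
    reduction.
    """
    order: list[str] = []
    for s in lset.specimen_ids:
        if s not in order:
            order.append(s)
    coords = np.stack(
        [
            lset.coords[[i for i, sid in enumerate(lset.specimen_ids) if sid == s]].mean(axis=0)
            for s in order
        ]
    )
    return LandmarkSet(coords, order, [0] * len(order), groups=dict(lset.groups))


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

def _center_scale(conf: np.ndarray) -> np.ndarray:
    c = conf - conf.mean(axis=0)
    size = np.sqrt((c**2).sum())
    if size < 1e-12:
        raise ValueError("degenerate configuration: centroid size is zero")
    return c / size


def _rotate_onto(conf: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (no reflection) of ``conf`` onto ``target``."""
    u, _, vt = np.linalg.svd(conf.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return conf @ r


def _canonical_orientation(aligned: np.ndarray, consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the whole aligned set so the consensus lies on its principal axes.

    Removes the arbitrary global orientation of a GPA solution so that the
    output is a deterministic function of the shapes alone. The leftover
    180-degree ambiguity is resolved by the sign of the third moment of the
    consensus x coordinates (falling back to y).
    """
    _, _, vt = np.linalg.svd(consensus - consensus.mean(axis=0))
    q = vt.T
    if np.linalg.det(q) < 0:
        q[:, 1] *= -1.0
    cons = consensus @ q
    sx = float((cons[:, 0] ** 3).sum())
    sy = float((cons[:, 1] ** 3).sum())
    flip = sx < -1e-12 or (abs(sx) <= 1e-12 and sy < 0)
    if flip:
        q = -q  # rotate by pi (det stays +1)
        cons = -cons
    return aligned @ q, cons


def gpa(lset: LandmarkSet | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Generalized Procrustes superimposition.

    Centers every configuration at the origin, scales to unit centroid
    size, and iteratively rotates (proper rotations only) to the running
    consensus until the consensus changes by less than 1e-10. Returns
    ``(aligned, consensus)``; the global orientation is canonicalized to the
    consensus principal axes, making the output invariant (up to numerical
    tolerance) to per-specimen similarity transforms of the input.
    """
    coords = lset.coords if isinstance(lset, LandmarkSet) else np.asarray(lset, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("GPA needs at least 2 specimens")
    aligned = np.stack([_center_scale(c) for c in coords])
    consensus = aligned[0].copy()
    for _ in range(_GPA_MAXITER):
        aligned = np.stack([_rotate_onto(c, consensus) for c in aligned])
        new_consensus = aligned.mean(axis=0)
        size = np.sqrt((new_consensus**2).sum())
        if size < 1e-12:
            raise ValueError("degenerate consensus in GPA")
        new_consensus /= size
        if np.sqrt(((new_consensus - consensus) ** 2).sum()) < _GPA_TOL:
            consensus = new_consensus
            break
        consensus = new_consensus
    aligned = np.stack([_rotate_onto(c, consensus) for c in aligned])
    return _canonical_orientation(aligned, consensus)


@dataclass
class WarpScores:
    """Relative-warp scores and the variance decomposition behind them."""

    scores: np.ndarray  # (specimens, components)
    variance_fractions: np.ndarray
    components: np.ndarray  # (components, 2 * landmarks), orthonormal rows
    consensus: np.ndarray  # (landmarks, 2)
    specimen_ids: list[str]


def relative_warps(
    aligned: np.ndarray, specimen_ids: list[str] | None = None,
    consensus: np.ndarray | None = None,
) -> WarpScores:
    """Relative warps: PCA of Procrustes-aligned coordinate deviations.

    Implemented with the bending-energy exponent alpha = 0 (every landmark
    weighted equally, uniform component retained), i.e. an ordinary
    principal-component decomposition of the aligned coordinates about
    their mean. Degenerate data (all shapes identical) yield zero scores
    and zero variance fractions.
    """
    aligned = np.asarray(aligned, dtype=float)
    n = aligned.shape[0]
    if n < 3:
        raise ValueError("relative warps need at least 3 specimens")
    if specimen_ids is None:
        specimen_ids = [f"spec{i}" for i in range(n)]
    flat = aligned.reshape(n, -1)
    mean = flat.mean(axis=0)
    dev = flat - mean
    u, s, vt = np.linalg.svd(dev, full_matrices=False)
    # deterministic sign convention: largest-magnitude loading positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    keep = s > max(s[0] if s.size else 0.0, 1e-300) * 1e-12
    total = float((s**2).sum())
    if total <= 1e-24:
        k = min(n - 1, flat.shape[1])
        return WarpScores(
            scores=np.zeros((n, k)),
            variance_fractions=np.zeros(k),
            components=vt[:k],
            consensus=(consensus if consensus is not None else mean.reshape(-1, 2)),
            specimen_ids=list(specimen_ids),
        )
    scores = (u * s)[:, keep]
    fractions = (s[keep] ** 2) / total
    return WarpScores(
        scores=scores,
        variance_fractions=fractions,
        components=vt[keep],
        consensus=(consensus if consensus is not None else mean.reshape(-1, 2)),
        specimen_ids=list(specimen_ids),
    )


def anova_by_axis(
    scores: np.ndarray | WarpScores, labels: list[str], axes: int = 3
) -> pd.DataFrame:
    """One-way ANOVA of group differences on each leading score axis.

    F = (SSB/df_B) / (SSW/df_W) with p from the F distribution; zero
    within-group variance with distinct means reports F = inf, p = 0.
    """
    mat = scores.scores if isinstance(scores, WarpScores) else np.asarray(scores, dtype=float)
    if mat.ndim == 1:
        mat = mat[:, None]
    labels = list(labels)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    idx = {g: [i for i, l in enumerate(labels) if l == g] for g in groups}
    if any(len(v) < 2 for v in idx.values()):
        raise ValueError("every group needs at least 2 members")
    n = mat.shape[0]
    axes = min(axes, mat.shape[1])
    rows = []
    for ax in range(axes):
        y = mat[:, ax]
        grand = y.mean()
        ssb = sum(len(idx[g]) * (y[idx[g]].mean() - grand) ** 2 for g in groups)
        ssw = sum(((y[idx[g]] - y[idx[g]].mean()) ** 2).sum() for g in groups)
        df_b = len(groups) - 1
        df_w = n - len(groups)
        if ssw <= 1e-30:
            f_stat, p = float("inf"), 0.0
        else:
            f_stat = (ssb / df_b) / (ssw / df_w)
            p = float(stats.f.sf(f_stat, df_b, df_w))
        rows.append({"axis": ax + 1, "F": float(f_stat), "df_between": df_b,
                     "df_within": df_w, "p": p})
    return pd.DataFrame(rows)


def cluster_specimens(
    scores: np.ndarray | WarpScores, k: int, n_axes: int = 10,
    specimen_ids: list[str] | None = None,
) -> Partition:
    """Ward-linkage hierarchical clustering on the first ``n_axes`` warps."""
    if isinstance(scores, WarpScores):
        ids = scores.specimen_ids if specimen_ids is None else list(specimen_ids)
        mat = scores.scores
    else:
        mat = np.asarray(scores, dtype=float)
        ids = specimen_ids if specimen_ids is not None else [f"spec{i}" for i in range(mat.shape[0])]
    if k > mat.shape[0]:
        raise ValueError(f"k={k} exceeds {mat.shape[0]} specimens")
    use = mat[:, : min(n_axes, mat.shape[1])]
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    labels = model.fit_predict(use)
    return Partition(dict(zip(ids, (int(l) for l in labels))), provenance="morpho")
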