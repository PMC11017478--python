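"""Landmark-based geometric morphometrics.

Generalized Procrustes analysis (GPA) with Procrustes-distance sliding of
semilandmarks, principal-component ordination of aligned shapes, permutation
Procrustes linear models (residual randomization), linear discriminant
classification, and mean-shape disparity distances between populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, cross_val_predict

from .containers import LandmarkSet

__all__ = [
    "ShapeSpace",
    "ProcrustesModelResult",
    "DfaResult",
    "centroid_size",
    "gpa",
    "shape_pca",
    "procrustes_lm",
    "dfa",
    "mean_shape_distances",
]


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared landmark distances to their centroid."""
    c = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(c**2)))


def _normalize(config: np.ndarray) -> np.ndarray:
    c = config - config.mean(axis=0)
    cs = np.sqrt(np.sum(c**2))
    if cs == 0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return c / cs


def _rotate_to(config: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Orthogonal Procrustes rotation of ``config`` onto ``reference``.

    Reflections are forbidden: if the optimal orthogonal map has negative
    determinant the smallest singular direction is flipped.
    """
    u, _, vt = np.linalg.svd(config.T @ reference)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return config @ r


def _canonical_orientation(config: np.ndarray) -> np.ndarray:
    """Rotate a centred configuration to its principal axes, deterministically.

    The rotation (never a reflection) aligns the major axis of landmark
    scatter with x; the remaining 180-degree ambiguity is resolved by making
    the largest-magnitude x-projection positive.  Unstable only for
    configurations with an isotropic landmark scatter, which real specimens
    do not have.
    """
    _, _, vt = np.linalg.svd(config, full_matrices=False)
    v = vt.T
    if np.linalg.det(v) < 0:
        v[:, 1] *= -1
    rotated = config @ v
    j = np.argmax(np.abs(rotated[:, 0]))
    if rotated[j, 0] < 0:
        rotated = -rotated  # 180-degree rotation, still proper
    return rotated


@dataclass
class ShapeSpace:
    """GPA output: aligned coordinates, consensus, centroid sizes, metadata."""

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: np.ndarray
    populations: np.ndarray
    fork_length: np.ndarray
    iterations: list = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def flattened(self) -> np.ndarray:
        return self.aligned.reshape(self.n_specimens, -1)


def gpa(lms: LandmarkSet, tol: float = 1e-10, max_iter: int = 100,
        slide: bool = True) -> ShapeSpace:
    """Generalized Procrustes superimposition.

    Each configuration is centred, scaled to unit centroid size and rotated
    (reflections forbidden) onto the running consensus; semilandmarks are
    slid along their neighbour-chord tangents to minimize Procrustes distance
    to the consensus each outer iteration.  Convergence when the consensus
    moves less than ``tol`` (Frobenius norm) or after ``max_iter`` rounds.
    """
    if lms.n_specimens < 2 or lms.n_landmarks < 3:
        raise ValueError("need at least 2 specimens and 3 landmarks")
    configs = []
    sizes = []
    for i in range(lms.n_specimens):
        try:
            configs.append(_normalize(lms.coords[i]))
        except ValueError as exc:
            raise ValueError(f"specimen {lms.specimen_ids[i]!r}: {exc}") from exc
        sizes.append(centroid_size(lms.coords[i]))
    configs = np.stack(configs)
    sizes = np.asarray(sizes)

    # initial reference: the first specimen in canonical principal-axes
    # orientation.  This makes the whole procedure (including semilandmark
    # sliding) invariant to similarity transforms of the raw input: any two
    # inputs differing only by per-specimen rotation/translation/scale reach
    # this point as identical arrays and follow identical arithmetic.
    consensus = _canonical_orientation(configs[0].copy())
    log = []
    for iteration in range(max_iter):
        for i in range(configs.shape[0]):
            configs[i] = _rotate_to(configs[i], consensus)
        if slide and lms.sliding:
            for before, idx, after in lms.chains:
                if idx not in lms.sliding:
                    continue
                tangents = configs[:, after] - configs[:, before]
                norms = np.linalg.norm(tangents, axis=1, keepdims=True)
                tangents = np.divide(tangents, norms, out=np.zeros_like(tangents),
                                     where=norms > 0)
                shifts = np.einsum("ij,ij->i", consensus[idx] - configs[:, idx], tangents)
                # remove the common slide mode: a collective displacement of a
                # semilandmark along the outline is a flat direction of the
                # objective and would otherwise drift indefinitely
                shifts = shifts - shifts.mean()
                configs[:, idx] += shifts[:, None] * tangents
            for i in range(configs.shape[0]):
                configs[i] = _normalize(configs[i])
        new_consensus = _normalize(configs.mean(axis=0))
        new_consensus = _rotate_to(new_consensus, consensus)
        delta = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        log.append(delta)
        if delta < tol:
            break
    # canonical output frame: consensus on its principal axes
    consensus = _canonical_orientation(consensus)
    for i in range(configs.shape[0]):
        configs[i] = _rotate_to(configs[i], consensus)
    return ShapeSpace(
        aligned=configs,
        consensus=configs.mean(axis=0),
        centroid_sizes=sizes,
        specimen_ids=lms.specimen_ids,
        populations=lms.populations,
        fork_length=lms.fork_length,
        iterations=log,
    )


@dataclass
class ShapePCA:
    scores: pd.DataFrame
    loadings: np.ndarray
    percent_variance: np.ndarray


def shape_pca(space: ShapeSpace) -> ShapePCA:
    """PCA of the aligned (flattened) coordinates.

    Scores are centred at 0 and percent variance sums to 100 over the
    retained non-null components (at most ``min(n - 1, 2k - 4)`` for 2-D
    shapes, the similarity-reduced dimension).  Loading signs are fixed by
    making each component's largest-magnitude element positive.
    """
    if space.n_specimens < 3:
        raise ValueError("need at least 3 specimens for a shape PCA")
    x = space.flattened()
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    max_rank = min(space.n_specimens - 1, 2 * space.n_landmarks - 4)
    keep = np.flatnonzero(s > s[0] * 1e-12)[:max_rank]
    s = s[keep]
    vt = vt[keep]
    u = u[:, keep]
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u * s
    var = s**2
    pct = 100.0 * var / var.sum()
    cols = [f"PC{i + 1}" for i in range(len(s))]
    return ShapePCA(
        scores=pd.DataFrame(scores, columns=cols,
                            index=pd.Index(space.specimen_ids, name="specimen")),
        loadings=vt,
        percent_variance=pct,
    )


# ---------------------------------------------------------------------------
# Procrustes linear models

@dataclass
class ProcrustesModelResult:
    table: pd.DataFrame  # per-term df, SS, MS, F, R2, p
    total_ss: float
    n_perm: int


def _design_blocks(fl: np.ndarray, populations: np.ndarray):
    """Sequential design blocks: intercept | FL | population | FL x population."""
    n = fl.size
    pops = pd.unique(pd.Series(populations))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    dummies = np.zeros((n, len(pops) - 1))
    for j, p in enumerate(pops[1:]):
        dummies[populations == p, j] = 1.0
    flc = (fl - fl.mean())[:, None]
    blocks = [np.ones((n, 1)), flc, dummies, dummies * flc]
    names = ["intercept", "FL", "population", "FL:population"]
    return blocks, names


def procrustes_lm(space: ShapeSpace, n_perm: int = 999, seed: int | None = None,
                  include_interaction: bool = True) -> ProcrustesModelResult:
    """Permutation Procrustes ANOVA on aligned coordinates.

    Terms enter in the fixed order FL, population, FL x population; sums of
    squares are sequential (type I) on the flattened aligned coordinates.
    P-values come from residual randomization: for each term the reduced
    model's residuals are permuted, and the term's F statistic recomputed
    (add-one correction).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    fl = space.fork_length
    populations = space.populations
    if include_interaction:
        counts = pd.Series(populations).value_counts()
        if (counts < 2).any():
            raise ValueError("interaction requires >= 2 specimens per population")
    y = space.flattened()
    y = y - y.mean(axis=0)
    blocks, names = _design_blocks(fl, populations)
    if not include_interaction:
        blocks, names = blocks[:3], names[:3]
    # orthonormal bases of each sequential block after the preceding ones
    qs = []
    prev = np.zeros((y.shape[0], 0))
    for b in blocks:
        resid = b - prev @ (prev.T @ b) if prev.shape[1] else b
        q, r = np.linalg.qr(resid)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
        q = q[:, keep]
        qs.append(q)
        prev = np.hstack([prev, q])
    dfs = [q.shape[1] for q in qs]
    n = y.shape[0]
    df_res = n - sum(dfs)
    total_ss = float(np.sum(y**2))
    term_ss = [float(np.sum((q.T @ y) ** 2)) for q in qs]
    rss = total_ss - sum(term_ss)
    f_obs, p_vals = [], []
    rng = np.random.default_rng(seed)
    for k in range(1, len(qs)):
        ms_term = term_ss[k] / dfs[k]
        ms_res = rss / df_res
        f_k = ms_term / ms_res if ms_res > 0 else np.inf
        f_obs.append(f_k)
        # residuals of the reduced model (terms < k)
        reduced = np.hstack(qs[:k])
        r_red = y - reduced @ (reduced.T @ y)
        hits = 0
        qk = qs[k]
        q_all = np.hstack(qs)  # permuted residuals are not orthogonal to any block
        r_norm2 = float(np.sum(r_red**2))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            rp = r_red[perm]
            num = float(np.sum((qk.T @ rp) ** 2))
            explained = float(np.sum((q_all.T @ rp) ** 2))
            den = r_norm2 - explained
            f_p = (num / dfs[k]) / (den / df_res) if den > 0 else np.inf
            if f_p >= f_k - 1e-12:
                hits += 1
        p_vals.append((hits + 1) / (n_perm + 1))
    table = pd.DataFrame({
        "term": names[1:],
        "df": dfs[1:],
        "SS": term_ss[1:],
        "MS": [ss / d for ss, d in zip(term_ss[1:], dfs[1:])],
        "F": f_obs,
        "R2": [ss / total_ss for ss in term_ss[1:]],
        "p": p_vals,
    }).set_index("term")
    table.loc["residual"] = [df_res, rss, rss / df_res, np.nan, rss / total_ss, np.nan]
    return ProcrustesModelResult(table=table, total_ss=total_ss, n_perm=n_perm)


# ---------------------------------------------------------------------------
# discriminant classification

@dataclass
class DfaResult:
    axes: np.ndarray
    scores: pd.DataFrame
    accuracy_resubstitution: pd.Series
    accuracy_loo: pd.Series
    mean_accuracy_resubstitution: float
    mean_accuracy_loo: float
    n_components: int


def dfa(features: np.ndarray, populations: np.ndarray,
        n_components: int | None = None, var_threshold: float = 0.95) -> DfaResult:
    """Linear discriminant analysis with classification accuracy.

    Features (aligned coordinates or PC scores) are first reduced to the
    leading principal components covering ``var_threshold`` of the variance
    (or a user-set count, clipped with a warning if too large) so the
    within-group covariance is nonsingular.  Accuracy is reported per group
    and averaged, both by resubstitution and leave-one-out refitting.
    """
    x = np.asarray(features, dtype=float)
    populations = np.asarray(populations)
    counts = pd.Series(populations).value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 specimens: {small}")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    nz = np.flatnonzero(s > s[0] * 1e-10)
    var = s[nz] ** 2
    if n_components is None:
        cum = np.cumsum(var) / var.sum()
        n_components = int(np.searchsorted(cum, var_threshold) + 1)
    elif n_components > nz.size:
        warnings.warn(f"n_components clipped from {n_components} to {nz.size}")
        n_components = nz.size
    n_components = min(n_components, x.shape[0] - len(counts))
    pcs = u[:, :n_components] * s[:n_components]

    lda = LinearDiscriminantAnalysis()
    lda.fit(pcs, populations)
    resub_pred = lda.predict(pcs)
    loo_pred = cross_val_predict(LinearDiscriminantAnalysis(), pcs, populations,
                                 cv=LeaveOneOut())
    groups = pd.unique(pd.Series(populations))

    def per_group(pred):
        return pd.Series(
            {g: float(np.mean(pred[populations == g] == g)) for g in groups},
            name="accuracy",
        )

    acc_res = per_group(resub_pred)
    acc_loo = per_group(loo_pred)
    scores = lda.transform(pcs)
    return DfaResult(
        axes=lda.scalings_,
        scores=pd.DataFrame(scores, columns=[f"DF{i+1}" for i in range(scores.shape[1])]),
        accuracy_resubstitution=acc_res,
        accuracy_loo=acc_loo,
        mean_accuracy_resubstitution=float(acc_res.mean()),
        mean_accuracy_loo=float(acc_loo.mean()),
        n_components=n_components,
    )


def mean_shape_distances(space: ShapeSpace, populations=None) -> DistanceMatrix:
    """Euclidean distances between per-population mean aligned shapes."""
    populations = space.populations if populations is None else np.asarray(populations)
    pops = pd.unique(pd.Series(populations))
    means = []
    for p in pops:
        rows = populations == p
        if not rows.any():
            raise ValueError(f"population {p!r} has no specimens")
        means.append(space.flattened()[rows].mean(axis=0))
    means = np.stack(means)
    diff = means[:, None, :] - means[None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=2))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(p) for p in pops])
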