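"""Population trees, geographic distances, and isolation-by-distance tests.

Neighbour-joining phenograms are built from chord distances, with node
support from bootstrap resampling of loci and a majority-rule consensus.
Isolation by distance is tested by (partial) Mantel correlation between a
linearized differentiation matrix ``D / (1 - D)`` and pairwise geographic
distances, optionally controlling for a geographic-area coding matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .containers import GenotypeTable
from .io import parse_coordinate
from .popgen import chord_distance_from_counts

__all__ = [
    "Phenogram",
    "MantelResult",
    "neighbor_joining",
    "bootstrap_consensus",
    "geographic_distances",
    "area_coding_matrix",
    "mantel",
    "partial_mantel",
    "ibd_transform",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class Phenogram:
    """An unrooted tree with optional bootstrap support percentages.

    ``tree`` is a scikit-bio :class:`~skbio.tree.TreeNode` whose internal
    node names hold support percentages (when available).  ``supports`` maps
    each bipartition — the frozenset of leaf labels on the side away from the
    reference taxon — to its support in percent.
    """

    tree: TreeNode
    supports: dict = field(default_factory=dict)
    n_boot: int | None = None

    def newick(self) -> str:
        return str(self.tree).strip()


def _canonical(node_labels):
    return min(node_labels)


def neighbor_joining(dm: DistanceMatrix) -> Phenogram:
    """Saitou–Nei neighbour joining with the Studier–Keppler Q criterion.

    Negative branch lengths are clamped to 0 with the deficit transferred to
    the sister branch (preserving the joined pair's path length).  Q ties are
    broken deterministically toward the smallest (sorted) label pair.
    """
    D = np.array(dm.data, dtype=float)
    if D.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    nodes = [TreeNode(name=str(i)) for i in dm.ids]
    labels = [{str(i)} for i in dm.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12) & (Q <= qmin + 1e-12))
        pairs = {tuple(sorted((int(i), int(j)))) for i, j in ties}
        i, j = min(pairs, key=lambda p: tuple(sorted((_canonical(labels[p[0]]),
                                                      _canonical(labels[p[1]])))))
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = D[i, j] - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
            vi = max(vi, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = vi
        child_j.length = vj
        new = TreeNode(children=[child_i, child_j])
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)],
                       d_new[keep][None, :]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [labels[i] | labels[j]]

    (a, b, c) = range(3)
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, v in zip(nodes, (va, vb, vc)):
        node.length = max(v, 0.0)
    root = TreeNode(children=list(nodes))
    return Phenogram(tree=root)


def _bipartitions(phenogram: Phenogram, reference: str):
    """Internal-edge bipartitions as {clade_frozenset: branch_length}.

    Each clade is expressed as the leaf set on the side *not* containing the
    reference taxon.
    """
    tree = phenogram.tree
    all_leaves = frozenset(n.name for n in tree.tips())
    out = {}
    for node in tree.non_tips(include_self=False):
        clade = frozenset(n.name for n in node.tips())
        if reference in clade:
            clade = all_leaves - clade
        if 1 < len(clade) < len(all_leaves) - 1:
            out[clade] = node.length if node.length is not None else 0.0
    return out


def bootstrap_consensus(gt: GenotypeTable, n_boot: int = 1000,
                        seed: int | None = None,
                        support_threshold: float = 50.0) -> Phenogram:
    """Majority-rule consensus NJ phenogram over locus bootstrap replicates.

    Loci are resampled with replacement; chord distances and the NJ tree are
    recomputed per replicate.  Bipartitions present in more than half the
    replicates enter the consensus; their branch lengths are averaged over
    the replicates containing them, pendant branch lengths over all
    replicates.  ``supports`` holds the replicate percentage per retained
    bipartition (values below ``support_threshold`` are retained in the tree
    but conventionally not displayed).
    """
    if gt.n_loci < 2:
        raise ValueError("need at least 2 loci to bootstrap")
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap replicates: supports will be coarse")
    rng = np.random.default_rng(seed)
    counts, pops, n_typed = gt.counts()
    pops = [str(p) for p in pops]
    reference = sorted(pops)[0]
    bip_counts: dict = {}
    bip_lengths: dict = {}
    pendant: dict = {p: 0.0 for p in pops}
    for _ in range(n_boot):
        loci = rng.integers(0, gt.n_loci, size=gt.n_loci)
        dce = chord_distance_from_counts(counts[:, loci], n_typed[:, loci], pops)
        tree = neighbor_joining(dce)
        for clade, length in _bipartitions(tree, reference).items():
            bip_counts[clade] = bip_counts.get(clade, 0) + 1
            bip_lengths[clade] = bip_lengths.get(clade, 0.0) + length
        for tip in tree.tree.tips():
            pendant[tip.name] += tip.length or 0.0
    majority = {c: n for c, n in bip_counts.items() if n > n_boot / 2}
    supports = {c: 100.0 * n / n_boot for c, n in majority.items()}
    avg_len = {c: bip_lengths[c] / bip_counts[c] for c in majority}
    avg_pendant = {p: v / n_boot for p, v in pendant.items()}

    def build(leafset, clades):
        maximal = [c for c in clades
                   if not any(c < d for d in clades if d != c)]
        children = []
        for c in sorted(maximal, key=lambda c: sorted(c)):
            node = build(c, [d for d in clades if d < c])
            node.length = avg_len[c]
            node.name = f"{supports[c]:.1f}"
            children.append(node)
        covered = set().union(*maximal) if maximal else set()
        for leaf in sorted(leafset - covered):
            children.append(TreeNode(name=leaf, length=avg_pendant[leaf]))
        return TreeNode(children=children)

    root = build(set(pops), list(majority))
    return Phenogram(tree=root, supports=supports, n_boot=n_boot)


# ---------------------------------------------------------------------------
# geography

def geographic_distances(coords: pd.DataFrame, lat_col: str = "lat",
                         lon_col: str = "lon") -> DistanceMatrix:
    """Great-circle (haversine, R = 6371 km) distances between sites.

    ``coords`` is indexed by site label; latitude/longitude columns may hold
    decimal degrees or degree / decimal-minute strings (see
    :func:`cavecharr.io.parse_coordinate`).
    """
    lats, lons = [], []
    for site, row in coords.iterrows():
        try:
            lats.append(np.radians(parse_coordinate(row[lat_col])))
            lons.append(np.radians(parse_coordinate(row[lon_col])))
        except ValueError as exc:
            raise ValueError(f"site {site!r}: {exc}") from exc
    lat = np.asarray(lats)
    lon = np.asarray(lons)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(s) for s in coords.index])


def area_coding_matrix(areas: pd.Series | dict) -> DistanceMatrix:
    """Binary same-area (0) / different-area (1) coding matrix from labels."""
    if isinstance(areas, dict):
        areas = pd.Series(areas)
    labels = areas.to_numpy()
    mat = (labels[:, None] != labels[None, :]).astype(float)
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(mat, ids=[str(s) for s in areas.index])


# ---------------------------------------------------------------------------
# Mantel tests

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str


def _aligned_triangles(*dms):
    ids = dms[0].ids
    for dm in dms[1:]:
        if set(dm.ids) != set(ids):
            raise ValueError("distance matrices must share labels")
    mats = [dm.filter(ids).data for dm in dms]
    iu = np.triu_indices(len(ids), k=1)
    return mats, iu


def _pearson(x, y):
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        raise ValueError("zero-variance distance triangle: Mantel r undefined")
    return float((x * y).sum() / denom)


def mantel(a: DistanceMatrix, b: DistanceMatrix, n_perm: int = 9999,
           seed: int | None = None, tail: str = "greater") -> MantelResult:
    """Mantel correlation between two distance matrices.

    The statistic is the Pearson correlation of the strictly-lower-triangle
    entries; the null distribution comes from simultaneous row/column
    permutations of ``a``.  ``tail='greater'`` (the directional
    isolation-by-distance hypothesis) is the default; ``'two-sided'`` is
    available.  P-values are add-one corrected.
    """
    (ma, mb), iu = _aligned_triangles(a, b)
    n = ma.shape[0]
    if n < 4:
        raise ValueError("need at least 4 labels")
    r_obs = _pearson(ma[iu], mb[iu])
    rng = np.random.default_rng(seed)
    hits = 0
    yb = mb[iu]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = _pearson(ma[np.ix_(perm, perm)][iu], yb)
        if tail == "greater":
            hits += r >= r_obs - 1e-12
        elif tail == "two-sided":
            hits += abs(r) >= abs(r_obs) - 1e-12
        else:
            raise ValueError(f"unknown tail {tail!r}")
    return MantelResult(r=r_obs, p=(hits + 1) / (n_perm + 1), n_perm=n_perm, tail=tail)


def partial_mantel(a: DistanceMatrix, b: DistanceMatrix, c: DistanceMatrix,
                   n_perm: int = 9999, seed: int | None = None,
                   tail: str = "greater") -> MantelResult:
    """Partial Mantel test of A vs B controlling for C.

    A and B triangles are residualized on C (ordinary least squares with
    intercept); the statistic is the correlation of residuals.  The null
    permutes the rows/columns of A's residual matrix (residual permutation).
    A constant C reduces to the plain Mantel test; C perfectly collinear with
    B is an error.
    """
    (ma, mb, mc), iu = _aligned_triangles(a, b, c)
    n = ma.shape[0]
    if n < 4:
        raise ValueError("need at least 4 labels")
    xc = mc[iu]
    if np.ptp(xc) == 0:
        design = np.ones((xc.size, 1))
    else:
        rb = _pearson(mb[iu], xc)
        if abs(rb) > 1 - 1e-12:
            raise ValueError("C is collinear with B: partial correlation undefined")
        design = np.column_stack([np.ones(xc.size), xc])

    def residualize(y):
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return y - design @ beta

    res_b = residualize(mb[iu])
    res_a_vec = residualize(ma[iu])
    r_obs = _pearson(res_a_vec, res_b)
    # square residual matrix of A for row/column permutation
    res_a = np.zeros_like(ma)
    res_a[iu] = res_a_vec
    res_a = res_a + res_a.T
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = _pearson(res_a[np.ix_(perm, perm)][iu], res_b)
        if tail == "greater":
            hits += r >= r_obs - 1e-12
        elif tail == "two-sided":
            hits += abs(r) >= abs(r_obs) - 1e-12
        else:
            raise ValueError(f"unknown tail {tail!r}")
    return MantelResult(r=r_obs, p=(hits + 1) / (n_perm + 1), n_perm=n_perm, tail=tail)


def ibd_transform(d: DistanceMatrix) -> DistanceMatrix:
    """Linearized differentiation ``D / (1 - D)`` for IBD regression.

    Negative inputs are floored at 0 first; an entry equal to 1 (infinite
    transform) is an error.
    """
    m = np.maximum(np.array(d.data, dtype=float), 0.0)
    if np.any(m >= 1.0 - 1e-15):
        raise ValueError("differentiation of 1 transforms to infinity")
    return DistanceMatrix(m / (1.0 - m), ids=d.ids)
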