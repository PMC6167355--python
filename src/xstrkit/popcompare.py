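"""Inter-population comparison from allele-frequency tables.

Populations typed on a shared locus panel are compared through Nei's (1972)
standard genetic distance D = -ln I, where the normalized identity
I = J_AB / sqrt(J_A J_B) is built from arithmetic across-locus means of the
gene-identity sums J = sum p^2 (within) and sum p_A p_B (between); allele
label spaces are unioned per locus with absent alleles at frequency 0.

The distance matrix feeds classical (Torgerson) metric multidimensional
scaling and a neighbor-joining tree; the concatenated per-allele frequency
vectors feed a column-centered covariance PCA.  Deterministic sign
convention throughout: the largest-magnitude loading of each axis is made
positive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .core import AlleleFrequencyTable

__all__ = [
    "nei_distance", "nei_distance_matrix", "pca_frequencies",
    "mds_from_distances", "nj_tree",
]


def _shared_loci(pops: dict[str, AlleleFrequencyTable]) -> list[str]:
    names = list(pops)
    shared = set(pops[names[0]].locus_names)
    for n in names[1:]:
        shared &= set(pops[n].locus_names)
    first = pops[names[0]].locus_names
    return [l for l in first if l in shared]


def nei_distance(pop_a: AlleleFrequencyTable, pop_b: AlleleFrequencyTable,
                 loci: list[str] | None = None) -> float:
    """Nei (1972) standard genetic distance between two populations."""
    if loci is None:
        loci = [l for l in pop_a.locus_names if l in pop_b]
    if not loci:
        raise ValueError("no shared loci between populations")
    jaa = jbb = jab = 0.0
    for locus in loci:
        da = pop_a[locus].as_dict()
        db = pop_b[locus].as_dict()
        alleles = set(da) | set(db)
        pa = np.array([da.get(x, 0.0) for x in alleles])
        pb = np.array([db.get(x, 0.0) for x in alleles])
        jaa += float(np.sum(pa * pa))
        jbb += float(np.sum(pb * pb))
        jab += float(np.sum(pa * pb))
    n = len(loci)
    jaa /= n; jbb /= n; jab /= n
    if jab == 0.0:
        warnings.warn("no shared alleles at any locus: infinite Nei distance")
        return float("inf")
    identity = jab / np.sqrt(jaa * jbb)
    return float(-np.log(identity)) if identity < 1.0 else 0.0


def nei_distance_matrix(pops: dict[str, AlleleFrequencyTable],
                        loci: list[str] | None = None) -> DistanceMatrix:
    """Symmetric Nei distance matrix over a set of populations."""
    names = list(pops)
    if loci is None:
        loci = _shared_loci(pops)
    m = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            d = nei_distance(pops[a], pops[names[j]], loci)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(m, ids=names)


def _freq_matrix(pops: dict[str, AlleleFrequencyTable],
                 loci: list[str]) -> tuple[np.ndarray, list[str]]:
    """Populations x features matrix of per-allele frequencies over the
    per-locus union allele sets (0-filled where a population lacks an allele)."""
    features: list[tuple[str, str]] = []
    for locus in loci:
        alleles = sorted({a for p in pops.values() for a in p[locus].alleles})
        features += [(locus, a) for a in alleles]
    x = np.zeros((len(pops), len(features)))
    for i, p in enumerate(pops.values()):
        dicts = {locus: p[locus].as_dict() for locus in loci}
        for j, (locus, a) in enumerate(features):
            x[i, j] = dicts[locus].get(a, 0.0)
    return x, [f"{locus}:{a}" for locus, a in features]


def _fix_signs(axes: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    for j in range(axes.shape[1]):
        col = axes[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            axes[:, j] = -col
    return axes


def pca_frequencies(pops: dict[str, AlleleFrequencyTable],
                    loci: list[str] | None = None,
                    components: int | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Covariance PCA of populations in per-allele frequency space.

    Returns (scores, loadings, percent variance per component).  Percent
    variance over all retainable components sums to 100.
    """
    if len(pops) < 3:
        raise ValueError("PCA needs at least 3 populations")
    if loci is None:
        loci = _shared_loci(pops)
    x, feat_names = _freq_matrix(pops, loci)
    max_comp = min(len(pops) - 1, x.shape[1])
    if components is None:
        components = max_comp
    if components > max_comp:
        raise ValueError(f"components {components} exceeds max {max_comp}")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (len(pops) - 1)
    total = eig[:max_comp].sum()
    pct = (100.0 * eig[:max_comp] / total) if total > 0 else np.zeros(max_comp)
    load = _fix_signs(vt[:components].T.copy())
    scores = xc @ load
    names = list(pops)
    comp_names = [f"PC{i+1}" for i in range(components)]
    return (pd.DataFrame(scores, index=names, columns=comp_names),
            pd.DataFrame(load, index=feat_names, columns=comp_names),
            pct[:components])


def mds_from_distances(d: DistanceMatrix, dims: int = 2,
                       ) -> tuple[pd.DataFrame, float]:
    """Classical (Torgerson) metric MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and embeds on the
    top ``dims`` axes (negative eigenvalues clipped to 0).  Returns the
    coordinates and the stress-1 of the embedding.
    """
    n = len(d.ids)
    if dims < 1 or dims > n - 1:
        raise ValueError(f"dims must be in [1, {n-1}]")
    dm = d.data
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:dims]
    lam = np.clip(eigval[order], 0.0, None)
    coords = _fix_signs(eigvec[:, order] * np.sqrt(lam))
    fitted = np.sqrt(np.maximum(
        np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1), 0.0))
    iu = np.triu_indices(n, k=1)
    denom = float(np.sum(dm[iu] ** 2))
    stress = float(np.sqrt(np.sum((fitted[iu] - dm[iu]) ** 2) / denom)) if denom > 0 else 0.0
    cols = [f"DIM{i+1}" for i in range(dims)]
    return pd.DataFrame(coords, index=list(d.ids), columns=cols), stress


def nj_tree(d: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Neighbor-joining tree (Saitou-Nei) from a distance matrix.

    Exact on additive matrices.  Ties in the Q criterion break to the
    lexicographically smallest pair of cluster labels (a cluster is labelled
    by its smallest leaf name), so the result is deterministic.  Negative
    branch lengths are clamped to 0 with a warning unless disabled.
    """
    names = list(d.ids)
    if len(names) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = d.data.copy()
    nodes = [TreeNode(name=n) for n in names]
    labels = list(names)  # lexicographic representative per active cluster

    def _length(x: float) -> float:
        if x < 0 and clamp_negative:
            warnings.warn(f"negative NJ branch length {x:.6g} clamped to 0")
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = dm.sum(axis=1)
        q = (m - 2) * dm - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = [(i, j) for i in range(m) for j in range(i + 1, m)
                if q[i, j] <= qmin + 1e-12]
        i, j = min(cand, key=lambda ij: tuple(sorted((labels[ij[0]], labels[ij[1]]))))
        li = 0.5 * dm[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dm[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = _length(li)
        child_j.length = _length(lj)
        parent = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (dm[i, :] + dm[j, :] - dm[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_dm = np.zeros((len(keep) + 1, len(keep) + 1))
        new_dm[:-1, :-1] = dm[np.ix_(keep, keep)]
        new_dm[-1, :-1] = new_dm[:-1, -1] = dnew[keep]
        dm = new_dm
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # terminal 3-node star: three-point formulas
    d01, d02, d12 = dm[0, 1], dm[0, 2], dm[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = _length(ln)
    return TreeNode(children=nodes)
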