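"""Laplacians of physical layouts and their volume-normalized counterpart.

Three operators are built and compared:

* the site-level layout Laplacian ``Q_P(w)`` where intra-node lattice edges
  have weight 1 and inter-node bonds weight ``w``;
* the node-level combinatorial Laplacian ``Q_G`` weighted by link
  multiplicity;
* the physical Laplacian ``Q_phys = V^{-1/2} Q_G V^{-1/2}``, which governs
  the N slow eigenmodes of ``Q_P(w)`` to first order in ``w``: the slow
  eigenvalues divided by ``w`` converge to the spectrum of ``Q_phys``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import eigh
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "LayoutLaplacian",
    "MembershipMatrix",
    "PhysicalLaplacian",
    "SpectrumReport",
    "layout_laplacian",
    "membership_matrix",
    "combinatorial_laplacian",
    "physical_laplacian",
    "shuffled_physical_laplacian",
    "spectrum",
    "perturbation_check",
    "eigvec_distance_profile",
    "localization_report",
]

DENSE_LIMIT = 2000
_EIG_TOL = 1e-9


@dataclass
class LayoutLaplacian:
    w: float
    matrix: sp.csr_matrix
    site_index: dict[int, int]  # lattice site -> matrix row


@dataclass
class MembershipMatrix:
    matrix: sp.csr_matrix  # N x V, entry 1/sqrt(v_i) on node i's sites


@dataclass
class PhysicalLaplacian:
    Q_G: sp.csr_matrix
    volumes: np.ndarray
    Q_phys: sp.csr_matrix


@dataclass
class SpectrumReport:
    eigenvalues: np.ndarray  # ascending; full or the computed extremal set
    lam2: float
    lamN: float
    leading_vector: np.ndarray
    leading_index: int  # argmax |leading_vector|, ties -> smallest index
    mode: str


def layout_laplacian(layout, w: float) -> LayoutLaplacian:
    """Weighted site-level Laplacian of a physical layout.

    Rows/columns are the occupied sites in ascending site order.  At w=0 the
    matrix is block diagonal with one zero mode per physical node.
    """
    if w < 0:
        raise ValueError(f"bond weight must be >= 0, got {w}")
    sites: list[int] = []
    for node in layout.nodes:
        sites.extend(node.trajectory)
    sites_sorted = sorted(sites)
    site_index = {s: i for i, s in enumerate(sites_sorted)}
    rows, cols, vals = [], [], []
    for node in layout.nodes:
        t = node.trajectory
        for a, b in zip(t[:-1], t[1:]):
            ia, ib = site_index[a], site_index[b]
            rows += [ia, ib]
            cols += [ib, ia]
            vals += [1.0, 1.0]
    for bond in layout.bonds:
        ia, ib = site_index[bond.site_a], site_index[bond.site_b]
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [w, w]
    n = len(sites_sorted)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    D = sp.diags(np.asarray(A.sum(axis=1)).ravel())
    Q = (D - A).tocsr()
    return LayoutLaplacian(w=w, matrix=Q, site_index=site_index)


def membership_matrix(layout) -> MembershipMatrix:
    """N x V matrix with entries 1/sqrt(v_i) for node i's sites (M M^T = I)."""
    sites: list[int] = []
    for node in layout.nodes:
        sites.extend(node.trajectory)
    site_index = {s: i for i, s in enumerate(sorted(sites))}
    rows, cols, vals = [], [], []
    for node in layout.nodes:
        inv_sqrt = 1.0 / np.sqrt(node.volume)
        for s in node.trajectory:
            rows.append(node.id)
            cols.append(site_index[s])
            vals.append(inv_sqrt)
    M = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(layout.nodes), len(sites))
    ).tocsr()
    return MembershipMatrix(matrix=M)


def combinatorial_laplacian(network) -> sp.csr_matrix:
    """Weighted Laplacian of a combinatorial network (weight=multiplicity).

    Accepts anything with ``N`` and ``links`` = iterable of (i, j, mult).
    """
    N = network.N
    rows, cols, vals = [], [], []
    for i, j, m in network.links:
        rows += [i, j]
        cols += [j, i]
        vals += [float(m), float(m)]
    A = sp.coo_matrix((vals, (rows, cols)), shape=(N, N)).tocsr()
    D = sp.diags(np.asarray(A.sum(axis=1)).ravel())
    return (D - A).tocsr()


def physical_laplacian(Q_G: sp.spmatrix, volumes) -> PhysicalLaplacian:
    """Volume-normalized Laplacian V^{-1/2} Q_G V^{-1/2}."""
    v = np.asarray(volumes, dtype=float)
    if (v <= 0).any():
        raise ValueError("all volumes must be positive")
    if v.size != Q_G.shape[0]:
        raise ValueError("volume vector length does not match Q_G")
    S = sp.diags(1.0 / np.sqrt(v))
    Q_phys = (S @ Q_G @ S).tocsr()
    return PhysicalLaplacian(Q_G=sp.csr_matrix(Q_G), volumes=v, Q_phys=Q_phys)


def shuffled_physical_laplacian(
    Q_G: sp.spmatrix, volumes, rng: np.random.Generator
) -> PhysicalLaplacian:
    """Physical Laplacian with volumes uniformly permuted across nodes
    (destroys degree-volume correlation, preserves the volume multiset)."""
    v = np.asarray(volumes, dtype=float)
    return physical_laplacian(Q_G, v[rng.permutation(v.size)])


def _dense_spectrum(Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = eigh(Q)
    return vals, vecs


def spectrum(matrix, mode: str = "auto", k: int = 6) -> SpectrumReport:
    """Eigenvalues (and the leading eigenvector) of a symmetric matrix.

    ``mode='full'`` forces a dense solve, ``'extremal'`` computes only the
    ``k`` smallest and largest eigenpairs with sparse solvers, ``'auto'``
    switches on dimension DENSE_LIMIT.  lam2 is obtained after deflating the
    known zero mode (shift-invert at a small negative sigma).
    """
    n = matrix.shape[0]
    if mode == "auto":
        mode = "full" if n <= DENSE_LIMIT else "extremal"
    if mode == "full":
        Q = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, float)
        if not np.allclose(Q, Q.T, atol=1e-10):
            raise ValueError("matrix must be symmetric")
        vals, vecs = _dense_spectrum(Q)
        lam2 = float(vals[1]) if n > 1 else float("nan")
        lamN = float(vals[-1])
        lead = vecs[:, -1]
    elif mode == "extremal":
        Q = sp.csr_matrix(matrix)
        k_eff = min(k, n - 1)
        top_vals, top_vecs = spla.eigsh(Q, k=k_eff, which="LA", tol=_EIG_TOL)
        order = np.argsort(top_vals)
        top_vals, top_vecs = top_vals[order], top_vecs[:, order]
        try:
            low_vals = spla.eigsh(
                Q, k=min(k_eff + 1, n - 1), sigma=-1e-3, which="LM",
                tol=_EIG_TOL, return_eigenvectors=False,
            )
            low_vals = np.sort(low_vals)
        except Exception:  # factorization failure: fall back to SA iteration
            low_vals = np.sort(
                spla.eigsh(Q, k=min(k_eff + 1, n - 1), which="SA", tol=1e-6,
                           return_eigenvectors=False)
            )
        vals = np.concatenate([low_vals, top_vals])
        lam2 = float(low_vals[1]) if low_vals.size > 1 else float("nan")
        lamN = float(top_vals[-1])
        lead = top_vecs[:, -1]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lead = lead / np.linalg.norm(lead)
    leading_index = int(np.argmax(np.abs(lead)))  # np.argmax: first/smallest tie
    return SpectrumReport(
        eigenvalues=np.asarray(vals, dtype=float),
        lam2=lam2,
        lamN=lamN,
        leading_vector=lead,
        leading_index=leading_index,
        mode=mode,
    )


def perturbation_check(layout, w_list, volumes=None) -> np.recarray:
    """First-order perturbation test of the slow eigenmodes of Q_P(w).

    For each w, compares the N smallest eigenvalues of Q_P(w)/w (the slow
    group) against the eigenvalues of Q_phys, reporting the maximum relative
    gap, and checks that the remaining eigenvalues stay Theta(1).
    """
    from .growth import CombinatorialNetwork

    net = CombinatorialNetwork.from_layout(layout)
    N = net.N
    Q_G = combinatorial_laplacian(net)
    v = np.asarray(volumes if volumes is not None else net.volumes, dtype=float)
    phys = physical_laplacian(Q_G, v)
    ref = np.sort(eigh(phys.Q_phys.toarray(), eigvals_only=True))

    rows = []
    for w in w_list:
        if w <= 0:
            raise ValueError("w must be positive")
        lap = layout_laplacian(layout, w)
        n_sites = lap.matrix.shape[0]
        if n_sites > DENSE_LIMIT:
            raise ValueError(
                f"perturbation_check requires <= {DENSE_LIMIT} sites, got {n_sites}"
            )
        vals = np.sort(eigh(lap.matrix.toarray(), eigvals_only=True))
        slow = vals[:N] / w
        # relative gap on the nonzero modes; zero modes compared absolutely
        gaps = []
        for a, b in zip(slow, ref):
            if abs(b) > 1e-9:
                gaps.append(abs(a - b) / abs(b))
            else:
                gaps.append(abs(a - b))
        fast_min = float(vals[N]) if len(vals) > N else float("nan")
        rows.append((float(w), float(np.max(gaps)), fast_min))
    return np.rec.fromarrays(
        list(zip(*rows)), names=["w", "max_rel_gap", "fast_min_eig"]
    )


def eigvec_distance_profile(
    adjacency: sp.spmatrix, eigenvector, center: int
) -> np.recarray:
    """Mean |eigenvector component| per BFS hop-distance shell from center.

    ``adjacency`` may be weighted; hop distances ignore the weights.
    """
    A = sp.csr_matrix(adjacency)
    A_unweighted = A.copy()
    A_unweighted.data = np.ones_like(A_unweighted.data)
    dist = shortest_path(
        A_unweighted, method="BF", unweighted=True, indices=center
    )
    vec = np.abs(np.asarray(eigenvector, dtype=float))
    rows = []
    finite = np.isfinite(dist)
    for h in np.unique(dist[finite]).astype(int):
        sel = dist == h
        rows.append((int(h), float(vec[sel].mean()), int(sel.sum())))
    return np.rec.fromarrays(list(zip(*rows)), names=["hops", "mean_weight", "n"])


def localization_report(
    Q_G: sp.spmatrix, volumes, weighted_degrees=None
) -> dict:
    """Localization centers of the leading eigenvectors of Q_G and Q_phys.

    Reports i_G (combinatorial center), i_phys (physical center), the
    weighted-degree rank of i_phys (1 = largest degree), its volume
    percentile, and argmax_i k_i/v_i for the consistency check.
    """
    v = np.asarray(volumes, dtype=float)
    if weighted_degrees is None:
        weighted_degrees = np.asarray(sp.csr_matrix(Q_G).diagonal(), dtype=float)
    k = np.asarray(weighted_degrees, dtype=float)
    rep_G = spectrum(Q_G)
    phys = physical_laplacian(Q_G, v)
    rep_P = spectrum(phys.Q_phys)
    i_G = rep_G.leading_index
    i_phys = rep_P.leading_index
    order = np.argsort(-k, kind="stable")
    rank = int(np.where(order == i_phys)[0][0]) + 1
    vol_percentile = float(100.0 * np.mean(v <= v[i_phys]))
    ratio = k / v
    i_kv = int(np.argmax(ratio))
    return {
        "i_G": int(i_G),
        "i_phys": int(i_phys),
        "degree_rank_i_phys": rank,
        "volume_percentile_i_phys": vol_percentile,
        "argmax_degree_volume_ratio": i_kv,
        "i_phys_matches_argmax_kv": bool(i_phys == i_kv),
        "lamN_G": rep_G.lamN,
        "lamN_phys": rep_P.lamN,
        "lam2_G": rep_G.lam2,
        "lam2_phys": rep_P.lam2,
    }
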