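"""Analysis of real physical networks given an edge list and node volumes.

A real network enters as a TSV edge list (node_i, node_j, multiplicity) plus
a TSV volume table (node_id, volume).  Directed duplicates are symmetrized
by summing multiplicities, self-links are dropped, and volumes are rescaled
so the mean node volume is exactly 1 — the unit convention under which the
combinatorial and physical Laplacian spectra are directly comparable.

``generate_fixture`` builds heavy-tailed synthetic networks with tunable
degree-volume correlation so that every code path here is testable offline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, special, stats
from scipy.sparse.csgraph import connected_components

from .observables import ccdf, degree_volume_relation
from .spectral import (
    combinatorial_laplacian,
    eigvec_distance_profile,
    localization_report,
    physical_laplacian,
    shuffled_physical_laplacian,
    spectrum,
)

__all__ = [
    "RealNetwork",
    "CutoffFit",
    "load_real_network",
    "weighted_degree",
    "fit_powerlaw_cutoff",
    "degree_volume_report",
    "physical_spectral_report",
    "generate_fixture",
]


@dataclass
class RealNetwork:
    """Weighted undirected network with node volumes (mean normalized to 1)."""

    ids: list  # external node identifiers, index = internal id
    links: list[tuple[int, int, float]]  # (i, j, multiplicity), i < j
    raw_volumes: np.ndarray
    volumes: np.ndarray = field(init=False)
    n_self_links_dropped: int = 0

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw_volumes, dtype=float)
        if (raw <= 0).any():
            raise ValueError("volumes must be positive")
        self.raw_volumes = raw
        self.volumes = raw / raw.mean()

    @property
    def N(self) -> int:
        return len(self.ids)

    def normalize(self) -> None:
        """Idempotent: volumes always carry mean exactly 1."""
        self.volumes = self.volumes / self.volumes.mean()

    def adjacency(self) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for i, j, m in self.links:
            rows += [i, j]
            cols += [j, i]
            vals += [m, m]
        return sp.coo_matrix((vals, (rows, cols)), shape=(self.N, self.N)).tocsr()

    def weighted_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()


def load_real_network(edge_file, volume_file) -> RealNetwork:
    """Load and symmetrize an edge-list + volume-table pair of TSV files."""
    edges = pd.read_csv(
        edge_file, sep="\t", header=None, comment="#",
        names=["i", "j", "mult"],
    )
    if edges.isna().any().any():
        raise ValueError(f"malformed rows in {edge_file}")
    if (edges["mult"] < 1).any():
        raise ValueError("edge multiplicities must be >= 1")
    vols = pd.read_csv(
        volume_file, sep="\t", header=None, comment="#", names=["id", "volume"]
    )
    if vols.isna().any().any():
        raise ValueError(f"malformed rows in {volume_file}")
    if vols["id"].duplicated().any():
        dup = vols["id"][vols["id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate volume entry for node {dup!r}")
    vol_map = dict(zip(vols["id"], vols["volume"].astype(float)))

    node_ids = sorted(set(edges["i"]) | set(edges["j"]), key=str)
    missing = [str(n) for n in node_ids if n not in vol_map]
    if missing:
        raise ValueError(f"missing volumes for nodes: {', '.join(missing[:10])}")
    index = {n: i for i, n in enumerate(node_ids)}

    mult: dict[tuple[int, int], float] = {}
    n_self = 0
    for a, b, m in edges.itertuples(index=False):
        ia, ib = index[a], index[b]
        if ia == ib:
            n_self += 1
            continue
        key = (min(ia, ib), max(ia, ib))
        mult[key] = mult.get(key, 0.0) + float(m)  # directed duplicates sum
    links = [(i, j, m) for (i, j), m in sorted(mult.items())]
    raw_volumes = np.array([vol_map[n] for n in node_ids], dtype=float)
    return RealNetwork(
        ids=list(node_ids),
        links=links,
        raw_volumes=raw_volumes,
        n_self_links_dropped=n_self,
    )


def weighted_degree(network: RealNetwork, node: int) -> float:
    """Sum of link multiplicities incident to an (internal-id) node."""
    if not 0 <= node < network.N:
        raise ValueError(f"node {node} out of range")
    return float(
        sum(m for i, j, m in network.links if i == node or j == node)
    )


# ---------------------------------------------------------------------------
# power law with exponential cutoff


@dataclass
class CutoffFit:
    gamma: float
    kappa: float
    xmin: int
    loglik: float
    loglik_lognormal: float
    lognormal_params: tuple[float, float]
    n_tail: int

    @property
    def likelihood_ratio(self) -> float:
        return self.loglik - self.loglik_lognormal


_SUPPORT_CAP = 10**6


def _cutoff_logpmf(k: np.ndarray, gamma: float, kappa: float, xmin: int) -> np.ndarray:
    # the normalization sum is truncated where the exponential factor (or the
    # power for gamma > 1) has made further terms negligible
    kmax = int(max(k.max(), xmin) + 40 * kappa) + 10
    kmax = min(kmax, _SUPPORT_CAP)
    support = np.arange(xmin, kmax + 1, dtype=float)
    logw = -gamma * np.log(support) - support / kappa
    logZ = special.logsumexp(logw)
    return -gamma * np.log(k) - k / kappa - logZ


def fit_powerlaw_cutoff(degrees, xmin: int, min_tail: int = 50) -> CutoffFit:
    """MLE of P(k) ∝ k^-gamma * exp(-k/kappa) on the tail k >= xmin.

    A discrete lognormal is fitted on the same range and its log-likelihood
    reported for model comparison (heavy tails of real networks are often
    indistinguishable between the two families).
    """
    k = np.asarray(degrees, dtype=float)
    tail = k[k >= xmin]
    if tail.size < min_tail:
        raise ValueError(
            f"need >= {min_tail} samples >= xmin={xmin}, got {tail.size}"
        )

    def nll(params: np.ndarray) -> float:
        gamma, log_kappa = params
        if gamma < -1.0 or gamma > 8.0 or not -5 < log_kappa < 25:
            return 1e12
        return -float(
            np.sum(_cutoff_logpmf(tail, gamma, math.exp(log_kappa), xmin))
        )

    best = None
    for g0, lk0 in [(2.0, math.log(10 * tail.mean())), (1.0, math.log(tail.mean())),
                    (0.1, math.log(tail.mean()))]:
        res = optimize.minimize(nll, x0=[g0, lk0], method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    gamma, kappa = float(best.x[0]), float(math.exp(best.x[1]))
    loglik = -float(best.fun)

    # discrete lognormal on the same range (normalized over k >= xmin)
    def nll_ln(params: np.ndarray) -> float:
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        if not 1e-3 < sigma < 50:
            return 1e12
        logpdf = -np.log(tail) - 0.5 * ((np.log(tail) - mu) / sigma) ** 2
        kmax = min(int(tail.max() * 3) + 10, _SUPPORT_CAP)
        support = np.arange(xmin, kmax + 1, dtype=float)
        logw = -np.log(support) - 0.5 * ((np.log(support) - mu) / sigma) ** 2
        logZ = special.logsumexp(logw)
        return -float(np.sum(logpdf - logZ))

    mu0 = float(np.mean(np.log(tail)))
    s0 = float(np.std(np.log(tail)) + 1e-6)
    res_ln = optimize.minimize(
        nll_ln, x0=[mu0, math.log(s0)], method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8},
    )
    return CutoffFit(
        gamma=gamma,
        kappa=kappa,
        xmin=int(xmin),
        loglik=loglik,
        loglik_lognormal=-float(res_ln.fun),
        lognormal_params=(float(res_ln.x[0]), float(math.exp(res_ln.x[1]))),
        n_tail=int(tail.size),
    )


def degree_volume_report(network: RealNetwork) -> dict:
    """Volume-binned mean degrees, power-law slope, and rank correlation."""
    if network.N < 100:
        raise ValueError("need >= 100 nodes")
    k = network.weighted_degrees()
    v = network.volumes
    fit, table = degree_volume_relation(k, v)
    rho, pval = stats.spearmanr(v, k)
    return {
        "slope": fit.exponent,
        "slope_stderr": fit.stderr,
        "spearman_rho": float(rho),
        "spearman_pval": float(pval),
        "binned_means": table,
    }


def physical_spectral_report(
    network: RealNetwork, rng: np.random.Generator | None = None
) -> dict:
    """Combinatorial-vs-physical spectral comparison on the giant component."""
    A = network.adjacency()
    n_comp, labels = connected_components(A, directed=False)
    sizes = np.bincount(labels)
    giant = int(np.argmax(sizes))
    if sizes[giant] < 0.5 * network.N:
        raise ValueError(
            "no dominant connected component "
            f"(largest has {sizes[giant]}/{network.N} nodes)"
        )
    keep = np.flatnonzero(labels == giant)
    remap = -np.ones(network.N, dtype=int)
    remap[keep] = np.arange(keep.size)
    sub_links = [
        (int(remap[i]), int(remap[j]), m)
        for i, j, m in network.links
        if remap[i] >= 0 and remap[j] >= 0
    ]
    vols = network.volumes[keep]
    vols = vols / vols.mean()

    class _G:
        N = keep.size
        links = sub_links

    Q_G = combinatorial_laplacian(_G)
    k_w = np.asarray(Q_G.diagonal(), dtype=float)
    loc = localization_report(Q_G, vols, weighted_degrees=k_w)
    rng = rng if rng is not None else np.random.default_rng(0)
    phys = physical_laplacian(Q_G, vols)
    shuf = shuffled_physical_laplacian(Q_G, vols, rng)
    rep_G = spectrum(Q_G)
    rep_P = spectrum(phys.Q_phys)
    rep_S = spectrum(shuf.Q_phys)

    A_sub = sp.csr_matrix(sp.diags(k_w) - Q_G)
    prof_G = eigvec_distance_profile(A_sub, rep_G.leading_vector, loc["i_G"])
    prof_P = eigvec_distance_profile(A_sub, rep_P.leading_vector, loc["i_phys"])

    def eig_ccdf(rep):
        vals = rep.eigenvalues[rep.eigenvalues > 1e-12]
        return ccdf(np.round(vals, 12)) if vals.size else []

    return {
        "giant_component_size": int(keep.size),
        "n_components": int(n_comp),
        "lamN_G": rep_G.lamN,
        "lamN_phys": rep_P.lamN,
        "lamN_shuffled": rep_S.lamN,
        "lamN_ratio": rep_G.lamN / rep_P.lamN,
        "lam2_G": rep_G.lam2,
        "lam2_phys": rep_P.lam2,
        "lam2_shuffled": rep_S.lam2,
        "localization": loc,
        "profile_G": prof_G,
        "profile_phys": prof_P,
        "eig_ccdf_G": eig_ccdf(rep_G),
        "eig_ccdf_phys": eig_ccdf(rep_P),
        "eig_ccdf_shuffled": eig_ccdf(rep_S),
    }


def generate_fixture(
    N: int,
    gamma_target: float = 2.5,
    correlation_mode: str = "linear",
    rng: np.random.Generator | None = None,
    noise: float = 0.2,
    planted_slope: float = 0.8,
) -> RealNetwork:
    """Synthetic heavy-tailed network with tunable degree-volume coupling.

    A weighted-attachment random tree: node t attaches to an existing node
    chosen with probability proportional to a Pareto-distributed fitness,
    producing a heavy-tailed degree sequence.  Volumes are then assigned as
    v ∝ k (``linear``), a random permutation of that (``shuffled``), or
    v ∝ k**planted_slope with lognormal noise (``planted``).
    """
    if N < 10:
        raise ValueError("need N >= 10")
    rng = rng if rng is not None else np.random.default_rng(0)
    alpha = max(gamma_target - 1.0, 0.5)
    fitness = rng.pareto(alpha, size=N) + 1.0
    links = []
    cum = np.empty(N)
    total = fitness[0]
    cum[0] = total
    for t in range(1, N):
        u = rng.random() * total
        parent = int(np.searchsorted(cum[:t], u))
        links.append((min(parent, t), max(parent, t), 1.0))
        total += fitness[t]
        cum[t] = total
    deg = np.zeros(N)
    for i, j, m in links:
        deg[i] += m
        deg[j] += m

    if correlation_mode == "linear":
        vols = deg.astype(float).copy()
    elif correlation_mode == "shuffled":
        vols = deg.astype(float)[rng.permutation(N)]
    elif correlation_mode == "planted":
        vols = deg.astype(float) ** planted_slope * np.exp(
            rng.normal(0.0, noise, size=N)
        )
    else:
        raise ValueError(f"unknown correlation_mode {correlation_mode!r}")
    return RealNetwork(
        ids=list(range(N)), links=sorted(links), raw_volumes=vols
    )


def convert_synapse_table(
    adjacency_csv, volume_csv, outdir,
    pre_col: str = "bodyId_pre", post_col: str = "bodyId_post",
    weight_col: str = "weight", id_col: str = "bodyId",
    size_col: str = "size",
) -> tuple[Path, Path]:
    """Convert connectome-style CSV exports to the TSV pair schema.

    ``adjacency_csv`` holds one row per directed neuron pair with a synapse
    count; ``volume_csv`` one row per neuron with its volume (e.g. voxel
    count — raw units cancel under the mean-volume normalization).  Column
    names default to the public fruit-fly release convention and are
    overridable.  No data is downloaded here; this is offline plumbing for
    files the user has already obtained.
    """
    adj = pd.read_csv(adjacency_csv)
    vols = pd.read_csv(volume_csv)
    for col in (pre_col, post_col, weight_col):
        if col not in adj.columns:
            raise ValueError(f"adjacency table lacks column {col!r}")
    for col in (id_col, size_col):
        if col not in vols.columns:
            raise ValueError(f"volume table lacks column {col!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edge_path = outdir / "edges.tsv"
    vol_path = outdir / "volumes.tsv"
    adj[[pre_col, post_col, weight_col]].to_csv(
        edge_path, sep="\t", header=False, index=False
    )
    vols[[id_col, size_col]].to_csv(vol_path, sep="\t", header=False, index=False)
    return edge_path, vol_path


def write_network(network: RealNetwork, outdir) -> tuple[Path, Path]:
    """Write a network to the TSV pair schema that load_real_network reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edge_path = outdir / "edges.tsv"
    vol_path = outdir / "volumes.tsv"
    with open(edge_path, "w") as f:
        for i, j, m in network.links:
            m_out = int(m) if float(m).is_integer() else m
            f.write(f"{network.ids[i]}\t{network.ids[j]}\t{m_out}\n")
    with open(vol_path, "w") as f:
        for nid, v in zip(network.ids, network.raw_volumes):
            f.write(f"{nid}\t{v}\n")
    return edge_path, vol_path
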