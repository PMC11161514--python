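"""Closed-form scaling predictions for the lattice growth model.

All quantities are stated as scalings (no universal prefactors): comparison
against simulation fits a single multiplicative constant where needed.  The
mean-field branch applies when the trajectory fractal dimension satisfies
``d_f <= d/2``, where independently placed trajectories intersect like
uniformly random site sets; both branches coincide at ``d_f = d/2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TheoryParams",
    "intersection_probability",
    "predicted_next_volume",
    "predicted_total_volume",
    "predicted_degree",
    "predicted_degree_exponent",
    "prediction_table",
]


@dataclass(frozen=True)
class TheoryParams:
    """Model parameters: embedding dimension, fractal dimension, system size.

    ``c`` is the integration constant of the continuous-time total-volume
    solution; by default it is chosen so the t=0 prediction equals ``v0``.
    """

    d: int
    d_f: float
    L: int
    v0: float | None = None
    c: float | None = None

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"d must be >= 1, got {self.d}")
        if not 1.0 <= self.d_f <= self.d:
            raise ValueError(f"d_f must lie in [1, d]={[1, self.d]}, got {self.d_f}")
        if self.L < 2:
            raise ValueError(f"L must be >= 2, got {self.L}")

    @property
    def mean_field(self) -> bool:
        return self.d_f <= self.d / 2

    @property
    def d_f_effective(self) -> float:
        """Fractal dimension entering the growth exponents (d/2 in MF)."""
        return self.d / 2 if self.mean_field else self.d_f

    @property
    def n_sites(self) -> int:
        return self.L**self.d

    @property
    def v0_default(self) -> float:
        return float(self.v0) if self.v0 is not None else float(self.L**self.d_f)

    @property
    def c_default(self) -> float:
        """c with predicted_total_volume(0) == v0 (effective-d_f branch)."""
        if self.c is not None:
            return float(self.c)
        d, df = self.d, self.d_f_effective
        v0 = self.v0_default
        n = self.n_sites
        return (d - df) / d * n * (v0 / n) ** (d / (d - df))


def intersection_probability(v_i: float, v_j: float, params: TheoryParams) -> float:
    """Probability scale for two randomly placed trajectories to intersect.

    Box-counting estimate ``v_i * v_j**(d/d_f - 1) / L**d`` (larger node
    first) above the mean-field boundary; plain ``v_i * v_j / L**d`` below
    it.  Clipped to [0, 1].
    """
    if v_i < 1 or v_j < 1:
        raise ValueError("volumes must be >= 1")
    v_i, v_j = max(v_i, v_j), min(v_i, v_j)
    if params.mean_field:
        p = v_i * v_j / params.n_sites
    else:
        p = v_i * v_j ** (params.d / params.d_f - 1) / params.n_sites
    return float(min(max(p, 0.0), 1.0))


def predicted_next_volume(V_prev: float, params: TheoryParams) -> float:
    """Expected volume of the next node given total occupied volume V_prev."""
    if not 0 < V_prev <= params.n_sites:
        raise ValueError(f"V_prev must lie in (0, L^d], got {V_prev}")
    d, df = params.d, params.d_f
    if df >= d:
        raise ValueError("d_f = d (space-filling nodes): next volume undefined")
    return float((V_prev / params.n_sites) ** (-df / (d - df)))


def predicted_total_volume(t, params: TheoryParams):
    """Continuous-time total volume after t node additions.

    ``L^d * [ d/(d-d_f) * (t+c)/L^d ]^{(d-d_f)/d}``, with the asymptotic
    log-log slope ``1 - d_f/d``; in the mean-field regime the effective
    exponent is 1/2.
    """
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("t must be >= 0")
    d, df = params.d, params.d_f_effective
    if params.d_f >= d:
        raise ValueError("d_f = d: total volume saturates immediately")
    n = params.n_sites
    c = params.c_default
    out = n * (d / (d - df) * (t + c) / n) ** ((d - df) / d)
    return float(out) if out.ndim == 0 else out


def growth_exponent(params: TheoryParams) -> float:
    """Asymptotic log-log slope of the total volume vs time."""
    return 1 - params.d_f_effective / params.d


def predicted_degree(t: float, N: float, params: TheoryParams) -> float:
    """Expected degree of node t after N nodes, by direct summation.

    ``1 + (v_t/L^d) * sum_{s=t+1}^{N} v_s**(d/d_f - 1)`` with the
    continuous-time node volume ``v_s = (s/L^d)**(-d_f/d)``; proportional to
    ``v_t * (N/L^d)**(d/d_f)`` for t << N.
    """
    if not 1 <= t <= N:
        raise ValueError(f"need 1 <= t <= N, got t={t}, N={N}")
    d = params.d
    df = params.d_f_effective
    n = params.n_sites
    s = np.arange(int(t) + 1, int(N) + 1, dtype=float)
    v_s = (s / n) ** (-df / d)
    v_t = (t / n) ** (-df / d)
    return float(1 + v_t / n * np.sum(v_s ** (d / df - 1)))


def predicted_degree_exponent(params: TheoryParams) -> float:
    """Degree-distribution density exponent: 1 + d/d_f, or 3 in mean field."""
    if params.mean_field:
        return 3.0
    return 1 + params.d / params.d_f


def prediction_table(params: TheoryParams, t_values) -> "np.recarray":
    """Table of (t, V_t, v_t, k_t) predictions plus the gamma exponent."""
    t_values = np.asarray(t_values, dtype=float)
    V = predicted_total_volume(t_values, params)
    df, d, n = params.d_f_effective, params.d, params.n_sites
    v = np.where(t_values > 0, (np.maximum(t_values, 1) / n) ** (-df / d), np.nan)
    N = float(t_values.max())
    k = np.array([predicted_degree(max(t, 1.0), N, params) for t in t_values])
    rec = np.rec.fromarrays([t_values, V, v, k], names=["t", "V_t", "v_t", "k_t"])
    return rec
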