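"""Bioreactor coupling and integration.

One or more :class:`~cocultsim.core.SpeciesModel` instances share a
well-mixed metabolite pool in a constant-volume reactor operated in
batch (no flow), chemostat (constant dilution) or pulsed mode, where the
dilution rate is a square wave: ``D(t) = D_on`` while ``t mod 1/w < s/w``
and 0 otherwise, so the time-averaged dilution is ``s * D_on``.

The joint ODE system is integrated segment-wise between exact pulse
edges with a stiff-capable adaptive solver, so the discontinuities in
D(t) are never stepped over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import EnzymeState, SpeciesModel, cybernetic_weights, pathway_growth_returns

__all__ = [
    "FeedProgram",
    "ReactorState",
    "Trajectory",
    "dilution_profile",
    "coculture_rhs",
    "integrate",
]

CLAMP_TOL = 1e-12


@dataclass(frozen=True)
class FeedProgram:
    """Square-wave dilution schedule and feed composition.

    ``D_on`` is the dilution rate during the feed-on phase (h^-1); ``w`` the
    pulse frequency (h^-1, period 1/w); ``s`` the on-fraction of the period.
    With ``D_is_average`` the given rate is interpreted as the time-averaged
    dilution s*D_on instead.
    """

    mode: str = "batch"  # batch | chemostat | pulsed
    D_on: float = 0.0
    w: float = 0.0
    s: float = 1.0
    feed: Mapping[str, float] = field(
        default_factory=lambda: {"GLU": 30.0, "ACE": 0.0, "ETH": 0.0}
    )
    D_is_average: bool = False

    def __post_init__(self):
        if self.mode not in ("batch", "chemostat", "pulsed"):
            raise ValueError(f"unknown mode '{self.mode}'")
        if self.D_on < 0:
            raise ValueError("D_on must be >= 0")
        if self.mode == "pulsed":
            if self.w <= 0:
                raise ValueError("pulsed mode requires w > 0")
            if not (0 < self.s <= 1):
                raise ValueError("s must be in (0, 1]")

    @property
    def D_peak(self) -> float:
        """Dilution rate during the on-phase."""
        if self.D_is_average and self.mode == "pulsed":
            return self.D_on / self.s
        return self.D_on

    @property
    def period(self) -> float:
        return 1.0 / self.w if self.mode == "pulsed" else math.inf

    @property
    def D_mean(self) -> float:
        if self.mode == "batch":
            return 0.0
        if self.mode == "chemostat" or self.s == 1:
            return self.D_peak
        return self.s * self.D_peak

    def feed_vector(self, metabolites: Sequence[str]) -> np.ndarray:
        return np.array([self.feed.get(m, 0.0) for m in metabolites])


def dilution_profile(t: float, fp: FeedProgram) -> float:
    """Realized dilution rate D(t), h^-1."""
    if fp.mode == "batch":
        return 0.0
    if fp.mode == "chemostat" or fp.s == 1:
        return fp.D_peak
    period = 1.0 / fp.w
    phase = t % period
    return fp.D_peak if phase < fp.s * period else 0.0


@dataclass
class ReactorState:
    """Instantaneous reactor state: time, biomasses, pool, enzyme levels."""

    t: float
    X: np.ndarray  # g/L, one per species
    M: np.ndarray  # g/L, one per pool metabolite
    E: list[EnzymeState]  # one per species

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if np.any(self.X < -CLAMP_TOL) or np.any(self.M < -CLAMP_TOL):
            raise ValueError(f"negative concentrations at t={self.t}")
        self.X = np.maximum(self.X, 0.0)
        self.M = np.maximum(self.M, 0.0)


class _System:
    """Packs the joint state vector and evaluates the coupled RHS.

    Layout: [X_1..X_K | M_1..M_nm | psi(species 1) | ... | psi(species K)].
    """

    def __init__(self, species: Sequence[SpeciesModel], metabolites: Sequence[str]):
        self.species = list(species)
        self.metabolites = list(metabolites)
        self.n_sp = len(self.species)
        self.n_m = len(self.metabolites)
        for sp in self.species:
            if list(sp.metabolites) != self.metabolites:
                # species pools must align with the shared reactor pool
                missing = set(sp.metabolites) - set(self.metabolites)
                if missing:
                    raise ValueError(
                        f"species '{sp.name}' uses metabolites {sorted(missing)} "
                        f"absent from the reactor pool {self.metabolites}"
                    )
        self.met_map = [
            np.array([self.metabolites.index(m) for m in sp.metabolites])
            for sp in self.species
        ]
        self.psi_slices = []
        off = self.n_sp + self.n_m
        for sp in self.species:
            self.psi_slices.append(slice(off, off + sp.n_pathways))
            off += sp.n_pathways
        self.n_state = off

    def pack(self, state: ReactorState) -> np.ndarray:
        y = np.empty(self.n_state)
        y[: self.n_sp] = state.X
        y[self.n_sp : self.n_sp + self.n_m] = state.M
        for sl, E in zip(self.psi_slices, state.E):
            y[sl] = E.psi_rel
        return y

    def unpack(self, t: float, y: np.ndarray) -> ReactorState:
        return ReactorState(
            t=t,
            X=y[: self.n_sp].copy(),
            M=y[self.n_sp : self.n_sp + self.n_m].copy(),
            E=[EnzymeState(np.clip(y[sl], 0.0, 1 + 1e-6)) for sl in self.psi_slices],
        )

    def rhs(self, t: float, y: np.ndarray, D: float, feed: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(f"non-finite state at t={t:.4f}: {y}")
        X = np.maximum(y[: self.n_sp], 0.0)
        M = np.maximum(y[self.n_sp : self.n_sp + self.n_m], 0.0)
        dy = np.zeros_like(y)
        dM = D * (feed - M)
        for k, sp in enumerate(self.species):
            if sp.fixed_enzymes:
                psi = np.ones(sp.n_pathways)
            else:
                psi = np.maximum(y[self.psi_slices[k]], 0.0)
            M_sp = M[self.met_map[k]]
            S = M_sp[sp.substrate_idx]
            H = S / (sp.Ks + S)
            mu = sp.Yx * sp.q_max * psi * H  # un-gated growth returns
            total = mu.sum()
            if total <= 1e-12:
                u = np.full(sp.n_pathways, 1.0 / sp.n_pathways)
                v = np.ones(sp.n_pathways)
            else:
                u = mu / total
                v = mu / mu.max()
            rate = v * sp.q_max * psi * H * X[k]
            flux = sp.psi @ rate
            mu_total = float((v * mu).sum())
            dy[k] = flux[0] - D * X[k]
            dM[self.met_map[k]] += flux[1:]
            if not sp.fixed_enzymes:
                H_ind = S / (sp.K_ind + S)
                inducible = u * sp.eps_i * H_ind
                if sp.enzyme_synthesis_scaled_by_biomass:
                    inducible = inducible * X[k]
                dy[self.psi_slices[k]] = (sp.eps_c + inducible) / sp.psi_max - (
                    sp.delta + mu_total
                ) * psi
        dy[self.n_sp : self.n_sp + self.n_m] = dM
        return dy


def coculture_rhs(
    t: float,
    state: ReactorState,
    species: Sequence[SpeciesModel],
    fp: FeedProgram,
    metabolites: Sequence[str] | None = None,
) -> ReactorState:
    """Joint state derivative at time t (species contributions summed).

    Returns a :class:`ReactorState` whose fields hold derivatives rather
    than concentrations.  Mostly useful for inspection and testing; the
    integrator uses the packed form directly.
    """
    metabolites = list(metabolites or species[0].metabolites)
    sys = _System(species, metabolites)
    y = sys.pack(state)
    D = dilution_profile(t, fp)
    dy = sys.rhs(t, y, D, fp.feed_vector(metabolites))
    n_sp, n_m = sys.n_sp, sys.n_m
    out = ReactorState.__new__(ReactorState)  # bypass non-negativity check
    out.t = t
    out.X = dy[:n_sp]
    out.M = dy[n_sp : n_sp + n_m]
    out.E = [EnzymeState.__new__(EnzymeState) for _ in species]
    for E, sl in zip(out.E, sys.psi_slices):
        E.psi_rel = dy[sl]
    return out


@dataclass
class Trajectory:
    """Simulated time course with per-species cybernetic diagnostics.

    All concentration blocks are (n_times, ...) arrays on a uniform
    reporting grid; diagnostics (mu, u, v) are recomputed from the states
    and therefore always consistent with them.
    """

    t: np.ndarray
    D: np.ndarray
    X: np.ndarray  # (n_t, n_species)
    M: np.ndarray  # (n_t, n_metabolites)
    psi_rel: list[np.ndarray]  # per species, (n_t, n_pathways)
    mu_pathway: list[np.ndarray]  # per species, un-gated returns
    u: list[np.ndarray]
    v: list[np.ndarray]
    mu_total: np.ndarray  # (n_t, n_species), realized growth rate
    species_names: list[str]
    metabolites: list[str]
    pathway_ids: list[list[str]]

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a tidy wide table, one row per reporting time."""
        cols: dict[str, np.ndarray] = {"t": self.t, "D": self.D}
        for k, name in enumerate(self.species_names):
            cols[f"X_{name}"] = self.X[:, k]
        for j, m in enumerate(self.metabolites):
            cols[m] = self.M[:, j]
        for k, name in enumerate(self.species_names):
            for j, pid in enumerate(self.pathway_ids[k]):
                cols[f"psi_rel_{name}_{pid}"] = self.psi_rel[k][:, j]
            for j, pid in enumerate(self.pathway_ids[k]):
                cols[f"u_{name}_{pid}"] = self.u[k][:, j]
            for j, pid in enumerate(self.pathway_ids[k]):
                cols[f"v_{name}_{pid}"] = self.v[k][:, j]
        for k, name in enumerate(self.species_names):
            cols[f"mu_{name}"] = self.mu_total[:, k]
        return pd.DataFrame(cols)

    def final_state(self) -> ReactorState:
        return ReactorState(
            t=float(self.t[-1]),
            X=self.X[-1],
            M=self.M[-1],
            E=[EnzymeState(np.clip(p[-1], 0, 1 + 1e-6)) for p in self.psi_rel],
        )


def _pulse_edges(fp: FeedProgram, t0: float, t_end: float) -> np.ndarray:
    """Exact discontinuity times of D(t) in (t0, t_end)."""
    if fp.mode != "pulsed" or fp.s == 1:
        return np.array([])
    period = 1.0 / fp.w
    edges = []
    n0 = math.floor(t0 / period)
    k = n0
    while k * period < t_end + period:
        for e in (k * period, k * period + fp.s * period):
            if t0 < e < t_end:
                edges.append(e)
        k += 1
    return np.array(sorted(set(edges)))


def integrate(
    initial: ReactorState,
    species: Sequence[SpeciesModel],
    fp: FeedProgram,
    t_end: float,
    *,
    metabolites: Sequence[str] | None = None,
    report_dt: float = 0.05,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the joint reactor system from ``initial.t`` to ``t_end``.

    Integration is restarted at every pulse edge so the square-wave
    dilution is exactly piecewise constant within each solver segment.
    States are clamped to zero below the 1e-12 tolerance; the result is
    deterministic given identical inputs.
    """
    if t_end <= initial.t:
        raise ValueError("t_end must exceed the initial time")
    metabolites = list(metabolites or species[0].metabolites)
    sys = _System(species, metabolites)
    feed = fp.feed_vector(metabolites)

    t0 = initial.t
    t_report = np.arange(t0, t_end + 0.5 * report_dt, report_dt)
    t_report[-1] = min(t_report[-1], t_end)
    edges = _pulse_edges(fp, t0, t_end)
    seg_bounds = np.concatenate([[t0], edges, [t_end]])

    y = sys.pack(initial)
    y_report = np.empty((sys.n_state, len(t_report)))
    y_report[:, 0] = y
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        if b - a < 1e-12:
            continue
        D = dilution_profile(0.5 * (a + b), fp)
        tol = 1e-9  # absorbs accumulated rounding in the reporting grid
        in_seg = np.nonzero((t_report > a + tol) & (t_report <= b + tol))[0]
        t_eval = np.unique(np.append(np.clip(t_report[in_seg], a, b), b))
        sol = solve_ivp(
            sys.rhs,
            (a, b),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            args=(D, feed),
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed in segment [{a:.4f}, {b:.4f}] h "
                f"(D={D}): {sol.message}"
            )
        for i_rep in in_seg:
            pos = min(
                int(np.searchsorted(sol.t, t_report[i_rep] - 1e-9)), len(sol.t) - 1
            )
            y_report[:, i_rep] = sol.y[:, pos]
        y = sol.y[:, -1].copy()
        y[np.abs(y) < CLAMP_TOL] = 0.0
        y = np.maximum(y, 0.0)

    y_report = np.maximum(y_report, 0.0)
    return _diagnostics(sys, fp, t_report, y_report)


def _diagnostics(sys: _System, fp: FeedProgram, t: np.ndarray, y: np.ndarray) -> Trajectory:
    n_t = len(t)
    D = np.array([dilution_profile(tt, fp) for tt in t])
    X = y[: sys.n_sp].T
    M = y[sys.n_sp : sys.n_sp + sys.n_m].T
    psi_rel, mu_path, u_all, v_all = [], [], [], []
    mu_total = np.zeros((n_t, sys.n_sp))
    for k, sp in enumerate(sys.species):
        psi = np.clip(y[sys.psi_slices[k]].T, 0.0, None)
        mu = np.zeros((n_t, sp.n_pathways))
        u = np.zeros_like(mu)
        v = np.zeros_like(mu)
        for i in range(n_t):
            E = EnzymeState(np.clip(psi[i], 0, 1 + 1e-6))
            mu[i] = pathway_growth_returns(M[i][sys.met_map[k]], E, sp)
            w = cybernetic_weights(mu[i])
            u[i], v[i] = w.u, w.v
            mu_total[i, k] = float((w.v * mu[i]).sum())
        psi_rel.append(psi)
        mu_path.append(mu)
        u_all.append(u)
        v_all.append(v)
    return Trajectory(
        t=t,
        D=D,
        X=X,
        M=M,
        psi_rel=psi_rel,
        mu_pathway=mu_path,
        u=u_all,
        v=v_all,
        mu_total=mu_total,
        species_names=[sp.name for sp in sys.species],
        metabolites=sys.metabolites,
        pathway_ids=[sp.pathway_ids() for sp in sys.species],
    )
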