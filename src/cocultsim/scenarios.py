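"""In-silico cultivation scenarios and their summary metrics.

Covers batch mono-cultures (diauxic growth at different initial glucose
levels), chemostat and square-wave pulsed co-cultures, and a coexistence
scan over the (dilution rate D, pulse frequency w, on-fraction s) grid.
Everything in this module is deterministic: identical configurations
yield bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import EnzymeState, SpeciesModel
from .reactor import FeedProgram, ReactorState, Trajectory, integrate

__all__ = [
    "run_batch",
    "run_chemostat",
    "run_pulsed",
    "biomass_fractions",
    "coexistence_scan",
    "growth_rate_reduction",
    "CoexistenceResult",
    "ScanResult",
]

#: total biomass below which species fractions are undefined, g/L
FRACTION_FLOOR = 1e-9

#: default OD600 -> g dry weight / L conversion (assumption, configurable)
GDW_PER_OD = 0.5


def _initial_state(
    species: Sequence[SpeciesModel],
    X0: Sequence[float],
    M0: Sequence[float],
    metabolites: Sequence[str],
    psi0: Sequence[np.ndarray] | None = None,
) -> ReactorState:
    if psi0 is None:
        # resting-cell constitutive steady state (ones in Monod baseline mode)
        psi0 = [sp.psi_rel_initial for sp in species]
    return ReactorState(
        t=0.0,
        X=np.asarray(X0, dtype=float),
        M=np.asarray(M0, dtype=float),
        E=[EnzymeState(np.asarray(p, dtype=float)) for p in psi0],
    )


def run_batch(
    sp: SpeciesModel,
    S0: float,
    X0: float = 0.05,
    t_end: float = 30.0,
    **options,
) -> Trajectory:
    """Mono-culture batch growth from initial glucose S0 g/L.

    X0 defaults to 0.05 g/L (standing in for an inoculum of ~0.1 OD at
    0.5 gDW/L per OD unit).  Produces the diauxic pattern: overflow
    byproducts (acetate for E. coli, ethanol/acetate for yeast) are made
    while glucose lasts and re-assimilated after its exhaustion.
    """
    if S0 <= 0:
        raise ValueError("S0 must be > 0")
    M0 = [S0 if m == "GLU" else 0.0 for m in sp.metabolites]
    state = _initial_state([sp], [X0], M0, sp.metabolites)
    fp = FeedProgram(mode="batch")
    return integrate(state, [sp], fp, t_end, **options)


def _coculture_initial(
    species: Sequence[SpeciesModel],
    inoculum_ratio: float,
    X_total0: float,
    S0: float,
) -> ReactorState:
    """1:ratio co-culture inoculum in fresh medium with S0 g/L glucose."""
    n = len(species)
    if n == 2:
        x_first = X_total0 * inoculum_ratio / (1 + inoculum_ratio)
        X0 = [x_first, X_total0 - x_first]
    else:
        X0 = [X_total0 / n] * n
    mets = species[0].metabolites
    M0 = [S0 if m == "GLU" else 0.0 for m in mets]
    return _initial_state(species, X0, M0, mets)


def run_chemostat(
    species: Sequence[SpeciesModel],
    D: float,
    t_end: float = 80.0,
    inoculum_ratio: float = 1.0,
    *,
    X_total0: float = 0.1,
    S0: float = 20.0,
    batch_phase: float = 10.0,
    feed: dict | None = None,
    **options,
) -> Trajectory:
    """Continuous co-culture at constant dilution rate D.

    Mirrors the experimental protocol: a batch phase (default 10 h) on the
    initial glucose charge, after which the feed (default 30 g/L GLU) is
    switched on at dilution rate D.  ``inoculum_ratio`` is the biomass
    ratio first:second species at t = 0.
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    state = _coculture_initial(species, inoculum_ratio, X_total0, S0)
    fp_feed = {"GLU": 30.0, "ACE": 0.0, "ETH": 0.0} if feed is None else feed
    if batch_phase > 0:
        traj0 = integrate(state, species, FeedProgram(mode="batch"), batch_phase, **options)
        state = traj0.final_state()
        fp = FeedProgram(mode="chemostat", D_on=D, feed=fp_feed)
        traj1 = integrate(state, species, fp, t_end, **options)
        return _concat(traj0, traj1)
    fp = FeedProgram(mode="chemostat", D_on=D, feed=fp_feed)
    return integrate(state, species, fp, t_end, **options)


def run_pulsed(
    species: Sequence[SpeciesModel],
    fp: FeedProgram,
    t_end: float = 80.0,
    inoculum_ratio: float = 1.0,
    *,
    X_total0: float = 0.1,
    S0: float = 20.0,
    batch_phase: float = 10.0,
    **options,
) -> Trajectory:
    """Continuous co-culture under a square-wave pulsed feed program."""
    if fp.mode != "pulsed":
        raise ValueError("run_pulsed requires a pulsed FeedProgram")
    state = _coculture_initial(species, inoculum_ratio, X_total0, S0)
    if batch_phase > 0:
        traj0 = integrate(state, species, FeedProgram(mode="batch"), batch_phase, **options)
        state = traj0.final_state()
        traj1 = integrate(state, species, fp, t_end, **options)
        return _concat(traj0, traj1)
    return integrate(state, species, fp, t_end, **options)


def _concat(a: Trajectory, b: Trajectory) -> Trajectory:
    """Join two consecutive trajectory pieces (b starts where a ends)."""
    keep = a.t < b.t[0] - 1e-12
    return Trajectory(
        t=np.concatenate([a.t[keep], b.t]),
        D=np.concatenate([a.D[keep], b.D]),
        X=np.concatenate([a.X[keep], b.X]),
        M=np.concatenate([a.M[keep], b.M]),
        psi_rel=[np.concatenate([pa[keep], pb]) for pa, pb in zip(a.psi_rel, b.psi_rel)],
        mu_pathway=[
            np.concatenate([pa[keep], pb]) for pa, pb in zip(a.mu_pathway, b.mu_pathway)
        ],
        u=[np.concatenate([pa[keep], pb]) for pa, pb in zip(a.u, b.u)],
        v=[np.concatenate([pa[keep], pb]) for pa, pb in zip(a.v, b.v)],
        mu_total=np.concatenate([a.mu_total[keep], b.mu_total]),
        species_names=a.species_names,
        metabolites=a.metabolites,
        pathway_ids=a.pathway_ids,
    )


def biomass_fractions(traj: Trajectory) -> pd.DataFrame:
    """Per-species biomass fraction time series.

    Fractions are computed on biomass concentration, the model's state
    variable (flow-cytometry event fractions are not comparable without a
    cells-per-gram conversion).  Where total biomass is below 1e-9 g/L
    the fractions are NaN and flagged in the ``defined`` column.
    """
    if traj.X.shape[1] < 2:
        raise ValueError("fractions need at least two species")
    total = traj.X.sum(axis=1)
    defined = total > FRACTION_FLOOR
    frac = np.full_like(traj.X, np.nan)
    frac[defined] = traj.X[defined] / total[defined, None]
    df = pd.DataFrame(frac, columns=[f"frac_{n}" for n in traj.species_names])
    df.insert(0, "t", traj.t)
    df["defined"] = defined
    return df


@dataclass
class CoexistenceResult:
    """Persistence summary of one (D, w, s) operating point."""

    D: float
    w: float
    s: float
    fractions: dict[str, float]  # mean fraction over the last 20% of the run
    min_fractions: dict[str, float]  # min over the same window
    persistent: dict[str, bool]
    status: str = "ok"

    @property
    def coexists(self) -> bool:
        return self.status == "ok" and all(self.persistent.values())


@dataclass
class ScanResult:
    """Coexistence metric over a (D, w, s) grid."""

    D_grid: np.ndarray
    w_grid: np.ndarray
    s_grid: np.ndarray
    entries: list[CoexistenceResult] = field(default_factory=list)

    @property
    def largest_coexistence_D(self) -> float | None:
        """Largest dilution rate with >= 1 coexistence-supporting (w, s)."""
        ds = [e.D for e in self.entries if e.coexists]
        return max(ds) if ds else None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"D": e.D, "w": e.w, "s": e.s}
            for name, f in e.fractions.items():
                row[f"frac_{name}"] = f
            for name, p in e.persistent.items():
                row[f"persistent_{name}"] = p
            row["status"] = e.status
            rows.append(row)
        return pd.DataFrame(rows)


def summarize_coexistence(
    traj: Trajectory, D: float, w: float, s: float, threshold: float = 0.01,
    window: float = 0.2,
) -> CoexistenceResult:
    """Reduce a co-culture trajectory to a persistence verdict.

    A species persists if its biomass fraction, averaged over the final
    ``window`` share of the simulated time, exceeds ``threshold``.
    """
    frac = biomass_fractions(traj)
    t0 = traj.t[-1] - window * (traj.t[-1] - traj.t[0])
    tail = frac[frac["t"] >= t0]
    fractions, min_fractions, persistent = {}, {}, {}
    for name in traj.species_names:
        vals = tail[f"frac_{name}"].to_numpy()
        mean = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else 0.0
        fractions[name] = mean
        min_fractions[name] = (
            float(np.nanmin(vals)) if np.any(np.isfinite(vals)) else 0.0
        )
        persistent[name] = mean > threshold
    status = "ok" if tail["defined"].any() else "washout"
    return CoexistenceResult(D, w, s, fractions, min_fractions, persistent, status)


def coexistence_scan(
    species: Sequence[SpeciesModel],
    D_grid: Sequence[float] = (0.025, 0.05, 0.075, 0.1, 0.15, 0.2, 0.3),
    w_grid: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    s_grid: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    t_end: float = 200.0,
    threshold: float = 0.01,
    *,
    completed: set | None = None,
    on_result=None,
    **options,
) -> ScanResult:
    """Scan pulsed-feed co-cultures over a (D, w, s) grid.

    Integrator failures at individual grid points are recorded in that
    point's ``status`` and do not abort the scan.  ``completed`` (a set of
    (D, w, s) tuples) lets an interrupted scan resume; ``on_result`` is an
    optional callback invoked with each fresh CoexistenceResult.
    """
    if not (0 < threshold < 0.5):
        raise ValueError("threshold must be in (0, 0.5)")
    options.setdefault("report_dt", 0.1)
    options.setdefault("rtol", 1e-6)
    options.setdefault("atol", 1e-8)
    result = ScanResult(
        np.asarray(D_grid, float), np.asarray(w_grid, float), np.asarray(s_grid, float)
    )
    completed = completed or set()
    for D in result.D_grid:
        for w in result.w_grid:
            for s in result.s_grid:
                if (float(D), float(w), float(s)) in completed:
                    continue
                fp = FeedProgram(mode="pulsed", D_on=float(D), w=float(w), s=float(s))
                try:
                    traj = run_pulsed(species, fp, t_end=t_end, **options)
                    entry = summarize_coexistence(
                        traj, float(D), float(w), float(s), threshold
                    )
                except (RuntimeError, FloatingPointError) as exc:
                    entry = CoexistenceResult(
                        float(D), float(w), float(s), {}, {}, {}, status=f"error: {exc}"
                    )
                result.entries.append(entry)
                if on_result is not None:
                    on_result(entry)
    return result


def growth_rate_reduction(
    sp: SpeciesModel,
    S0_hi: float,
    S0_lo: float,
    *,
    X0: float = 0.05,
    t_end: float = 30.0,
    burn_in: float = 0.5,
    **options,
) -> float:
    """Percent drop of the peak specific growth rate between two batch runs.

    100 * (1 - max_t mu(t; S0_lo) / max_t mu(t; S0_hi)), with the maximum
    taken over the reporting grid after a burn-in (default 0.5 h) that
    skips the enzyme-initialization transient.
    """
    if not (S0_hi >= S0_lo > 0):
        raise ValueError("require S0_hi >= S0_lo > 0")
    mu_max = []
    for S0 in (S0_hi, S0_lo):
        traj = run_batch(sp, S0, X0=X0, t_end=t_end, **options)
        sel = traj.t >= burn_in
        mu = traj.mu_total[sel, 0]
        peak = float(mu.max())
        if peak <= 0:
            raise ValueError(f"no growth at S0={S0} g/L")
        mu_max.append(peak)
    return 100.0 * (1.0 - mu_max[1] / mu_max[0])
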