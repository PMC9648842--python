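"""Cybernetic Monod-type kinetics for a single microbial species.

A species is described by a set of substrate-assimilation pathways
(e.g. fermentative glucose uptake, oxidative glucose uptake, acetate or
ethanol re-assimilation).  Each pathway has Monod uptake kinetics gated
by a lumped virtual "key enzyme" whose synthesis is dynamically allocated
between pathways by matching-law cybernetic weights: the allocation
weight ``u_i`` distributes inducible enzyme synthesis in proportion to
each pathway's growth return, and the activity weight ``v_i`` gates
uptake in proportion to the best available return.

All enzyme levels are carried in relative form ``psi_rel = Psi/Psi_max``
in [0, 1], where ``Psi_max`` is the steady level reached under full
allocation at maximal growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PathwayParams",
    "SpeciesModel",
    "EnzymeState",
    "CyberneticWeights",
    "monod_fraction",
    "pathway_growth_returns",
    "cybernetic_weights",
    "enzyme_odes",
    "species_flux",
]

#: below this total growth return the matching law is degenerate and a
#: uniform allocation is used (uptake is already zero through the Monod factor)
EPS_ZERO = 1e-12

#: relative slack allowed when checking mu_max against Yx * q_max
CONSISTENCY_RTOL = 0.02
#: absolute slack: half a unit in the last place of a 3-decimal printed value
CONSISTENCY_ATOL = 5e-4


def monod_fraction(S: float, K: float):
    """Monod saturation fraction S/(K+S).

    Parameters
    ----------
    S : float or ndarray
        Substrate concentration, g/L.  Must be >= 0.
    K : float or ndarray
        Half-saturation constant, g/L.  Must be > 0.

    Returns
    -------
    float or ndarray in [0, 1), equal to 0.5 at S == K.
    """
    S = np.asarray(S, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any(S < 0):
        raise ValueError(f"negative substrate concentration: {S}")
    if np.any(K <= 0):
        raise ValueError(f"non-positive saturation constant: {K}")
    out = S / (K + S)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PathwayParams:
    """Kinetic, yield and enzyme-dynamics constants of one pathway.

    ``q_max`` is stored as a positive magnitude (g substrate / g biomass / h);
    the consumption sign lives in the species stoichiometric matrix.
    """

    id: str
    substrate: str
    mu_max: float  # h^-1
    Ks: float  # g/L
    q_max: float  # g/gX/h, positive magnitude
    Yx: float  # gX/gS
    Yp: Mapping[str, float] = field(default_factory=dict)  # product yields, g/gS
    eps_c: float = 0.01  # constitutive enzyme synthesis, enzyme-units/h
    eps_i: float = 1.0  # inducible enzyme synthesis, enzyme-units/h
    K_ind: float | None = None  # induction saturation, g/L; defaults to Ks
    delta: float = 0.05  # enzyme degradation, h^-1

    def __post_init__(self):
        if self.K_ind is None:
            object.__setattr__(self, "K_ind", self.Ks)
        errors = []
        for name in ("mu_max", "Ks", "q_max", "Yx", "eps_c", "eps_i", "K_ind", "delta"):
            if getattr(self, name) < 0:
                errors.append(f"{name} < 0")
        if self.Ks <= 0:
            errors.append("Ks must be > 0")
        if self.delta <= 0:
            errors.append("delta must be > 0")
        if any(y < 0 for y in self.Yp.values()):
            errors.append("negative byproduct yield")
        if self.Yx + sum(self.Yp.values()) > 1 + 1e-9:
            errors.append(
                f"mass bound violated: Yx + sum(Yp) = "
                f"{self.Yx + sum(self.Yp.values()):.4f} > 1"
            )
        if self.mu_max > 0:
            # agreement with the printed growth rate, at printed precision
            if abs(self.mu_max - self.Yx * self.q_max) > max(
                CONSISTENCY_RTOL * self.mu_max, CONSISTENCY_ATOL
            ):
                errors.append(
                    f"mu_max = {self.mu_max} inconsistent with "
                    f"Yx*q_max = {self.Yx * self.q_max:.5f}"
                )
        if errors:
            raise ValueError(f"pathway '{self.id}': " + "; ".join(errors))

    @property
    def psi_max(self) -> float:
        """Maximum attainable key-enzyme level (synthesis/(loss) balance)."""
        return (self.eps_c + self.eps_i) / (self.delta + self.mu_max)

    @property
    def psi_rel_resting(self) -> float:
        """Constitutive steady level of a resting cell, relative units."""
        return (self.eps_c / self.delta) / self.psi_max


class SpeciesModel:
    """A named organism: metabolite pool, pathways, stoichiometric matrix.

    The stoichiometric matrix ``psi`` has rows ``[biomass] + metabolites``
    and one column per pathway: +Yx in the biomass row, -1 in the pathway's
    own-substrate row, +Yp in byproduct rows, 0 elsewhere.  Multiplying it
    by the vector of pathway uptake rates gives the rates of change of
    biomass and every metabolite (in g/L/h once scaled by biomass).
    """

    def __init__(
        self,
        name: str,
        pathways: Sequence[PathwayParams],
        metabolites: Sequence[str] = ("GLU", "ACE", "ETH"),
        enzyme_synthesis_scaled_by_biomass: bool = False,
        fixed_enzymes: bool = False,
    ):
        self.name = name
        self.metabolites = list(metabolites)
        self.pathways = list(pathways)
        self.enzyme_synthesis_scaled_by_biomass = enzyme_synthesis_scaled_by_biomass
        #: classical-Monod baseline: key enzymes pinned at psi_rel = 1
        self.fixed_enzymes = fixed_enzymes
        if not self.pathways:
            raise ValueError(f"species '{name}' has no pathways")
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        for p in self.pathways:
            if p.substrate not in met_index:
                raise ValueError(
                    f"species '{name}', pathway '{p.id}': substrate "
                    f"'{p.substrate}' not in metabolite list {self.metabolites}"
                )
            for prod in p.Yp:
                if prod not in met_index:
                    raise ValueError(
                        f"species '{name}', pathway '{p.id}': byproduct "
                        f"'{prod}' not in metabolite list"
                    )
                if prod == p.substrate:
                    raise ValueError(
                        f"species '{name}', pathway '{p.id}': byproduct equals substrate"
                    )
        # cached parameter arrays, one entry per pathway
        self.substrate_idx = np.array([met_index[p.substrate] for p in self.pathways])
        self.mu_max = np.array([p.mu_max for p in self.pathways])
        self.Ks = np.array([p.Ks for p in self.pathways])
        self.q_max = np.array([p.q_max for p in self.pathways])
        self.Yx = np.array([p.Yx for p in self.pathways])
        self.eps_c = np.array([p.eps_c for p in self.pathways])
        self.eps_i = np.array([p.eps_i for p in self.pathways])
        self.K_ind = np.array([p.K_ind for p in self.pathways])
        self.delta = np.array([p.delta for p in self.pathways])
        self.psi_max = np.array([p.psi_max for p in self.pathways])
        self.psi_rel_resting = np.array([p.psi_rel_resting for p in self.pathways])
        self.psi = self._build_psi()

    def _build_psi(self) -> np.ndarray:
        n_m = len(self.metabolites)
        psi = np.zeros((1 + n_m, len(self.pathways)))
        for j, p in enumerate(self.pathways):
            psi[0, j] = p.Yx
            psi[1 + self.substrate_idx[j], j] = -1.0
            for prod, y in p.Yp.items():
                psi[1 + self.metabolites.index(prod), j] = y
        return psi

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    @property
    def psi_rel_initial(self) -> np.ndarray:
        """Default initial enzyme levels: resting constitutive steady state,
        or all ones in the fixed-enzyme (classical Monod) baseline."""
        if self.fixed_enzymes:
            return np.ones(self.n_pathways)
        return self.psi_rel_resting.copy()

    def pathway_ids(self) -> list[str]:
        return [p.id for p in self.pathways]

    def replace_pathway_params(
        self, updates: Mapping[str, float], tie_q_max: bool = False
    ) -> "SpeciesModel":
        """Return a copy with pathway fields replaced.

        Keys are ``"<pathway id>.<field>"``, e.g. ``"glu_ferm.mu_max"``.
        When ``Yx`` changes on a pathway with byproducts, the byproduct
        yields are rescaled by (1 - Yx_new)/(1 - Yx_old) so the split of
        non-biomass carbon is preserved and the mass bound stays intact.
        With ``tie_q_max``, q_max is re-derived as mu_max/Yx on any pathway
        whose mu_max or Yx changed (unless q_max is itself replaced),
        keeping growth/uptake consistency exact.
        """
        from dataclasses import replace

        by_id = {p.id: dict() for p in self.pathways}
        for key, val in updates.items():
            pid, _, fname = key.partition(".")
            if pid not in by_id:
                raise KeyError(f"unknown pathway '{pid}' in species '{self.name}'")
            by_id[pid][fname] = float(val)
        for p in self.pathways:
            upd = by_id[p.id]
            if "Yx" in upd and "Yp" not in upd and p.Yp:
                scale = (1.0 - upd["Yx"]) / (1.0 - p.Yx)
                upd["Yp"] = {m: y * scale for m, y in p.Yp.items()}
            if tie_q_max and ("mu_max" in upd or "Yx" in upd) and "q_max" not in upd:
                upd["q_max"] = upd.get("mu_max", p.mu_max) / upd.get("Yx", p.Yx)
        new_pathways = [replace(p, **by_id[p.id]) if by_id[p.id] else p for p in self.pathways]
        return SpeciesModel(
            self.name,
            new_pathways,
            self.metabolites,
            self.enzyme_synthesis_scaled_by_biomass,
            self.fixed_enzymes,
        )

    def __repr__(self):
        return (
            f"SpeciesModel({self.name!r}, pathways={self.pathway_ids()}, "
            f"metabolites={self.metabolites})"
        )


@dataclass
class EnzymeState:
    """Relative key-enzyme levels, one per pathway, in [0, 1]."""

    psi_rel: np.ndarray

    def __post_init__(self):
        self.psi_rel = np.asarray(self.psi_rel, dtype=float)
        if np.any(self.psi_rel < -1e-9) or np.any(self.psi_rel > 1 + 1e-6):
            raise ValueError(f"psi_rel out of [0, 1]: {self.psi_rel}")


@dataclass
class CyberneticWeights:
    """Matching-law weights: u allocates synthesis, v gates activity."""

    u: np.ndarray
    v: np.ndarray


def pathway_growth_returns(
    M: np.ndarray, E: EnzymeState, sp: SpeciesModel
) -> np.ndarray:
    """Growth return mu_i of each pathway at the current pool and enzyme state.

    mu_i = Yx_i * q_max_i * psi_rel_i * S_i/(Ks_i + S_i), h^-1.  These are
    the un-gated potential returns the matching law compares; the activity
    weight v is applied later, in the flux assembly.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError(f"negative metabolite concentration: {M}")
    S = M[sp.substrate_idx]
    H = S / (sp.Ks + S)
    return sp.Yx * sp.q_max * E.psi_rel * H


def cybernetic_weights(mu: np.ndarray) -> CyberneticWeights:
    """Matching-law allocation u_i = mu_i/sum(mu) and gating v_i = mu_i/max(mu).

    When every return is (numerically) zero the law is degenerate; by
    convention u is uniform and v is all ones — harmless because uptake is
    already nulled by the Monod factor, while constitutive synthesis keeps
    basal enzyme available for re-induction.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError(f"negative growth return: {mu}")
    total = mu.sum()
    if total <= EPS_ZERO:
        n = len(mu)
        return CyberneticWeights(u=np.full(n, 1.0 / n), v=np.ones(n))
    return CyberneticWeights(u=mu / total, v=mu / mu.max())


def enzyme_odes(
    E: EnzymeState,
    M: np.ndarray,
    mu_total: float,
    u: np.ndarray,
    sp: SpeciesModel,
    X: float = 1.0,
) -> np.ndarray:
    """Time derivative of the relative key-enzyme levels, h^-1.

    d psi_i/dt = [eps_c_i + u_i * eps_i_i * S/(K_ind_i + S)] / Psi_max_i
                 - (delta_i + mu_total) * psi_i

    Psi_max_i = (eps_c_i + eps_i_i)/(delta_i + mu_max_i), so the derivative
    vanishes at psi_i = 1 under full allocation, saturating substrate and
    growth at mu_max_i.  Enzymes are intensive (per-biomass) quantities;
    with ``enzyme_synthesis_scaled_by_biomass`` set on the species, the
    inducible synthesis term is additionally multiplied by biomass X.
    """
    M = np.asarray(M, dtype=float)
    if mu_total < 0:
        raise ValueError(f"negative total growth rate: {mu_total}")
    S = np.maximum(M[sp.substrate_idx], 0.0)
    H_ind = S / (sp.K_ind + S)
    inducible = u * sp.eps_i * H_ind
    if sp.enzyme_synthesis_scaled_by_biomass:
        inducible = inducible * X
    return (sp.eps_c + inducible) / sp.psi_max - (sp.delta + mu_total) * E.psi_rel


def species_flux(
    M: np.ndarray,
    E: EnzymeState,
    v: np.ndarray,
    X: float,
    sp: SpeciesModel,
) -> np.ndarray:
    """Rates of change of [biomass] + metabolites contributed by one species.

    rate_i = v_i * q_max_i * psi_rel_i * S_i/(Ks_i+S_i) * X  (g substrate/L/h)
    and the returned vector is ``psi @ rate`` (g/L/h): biomass production in
    row 0, own-substrate consumption negative, byproduct formation positive.
    """
    M = np.asarray(M, dtype=float)
    if X < 0:
        raise ValueError(f"negative biomass: {X}")
    if len(M) != len(sp.metabolites):
        raise ValueError(
            f"pool has {len(M)} entries but species '{sp.name}' expects "
            f"{len(sp.metabolites)}"
        )
    S = np.maximum(M[sp.substrate_idx], 0.0)
    H = S / (sp.Ks + S)
    rate = np.asarray(v) * sp.q_max * E.psi_rel * H * X
    return sp.psi @ rate
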