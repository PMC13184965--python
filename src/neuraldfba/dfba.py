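"""Classical dynamic FBA baseline: iterative linear programs plus Euler
integration of the monitored concentrations.

At every step the LP  max biomass flux  s.t.  S_int V = 0, 0 <= V <= ub(C)
is solved over the irreversible expansion; uptake bounds either are fixed
or follow Monod kinetics in the current concentrations, and shrink as
substrates fall.  There is no lag gate (r = 1 throughout) -- growth starts
at the first step whenever substrate is available, which is exactly the
behavior the hybrid model's learned lag corrects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .metabolic_io import BIOMASS_SPECIES, IrreversibleModel, TransportMatrix
from .model import Trajectory

__all__ = ["DfbaConfig", "dfba_simulate"]


@dataclass
class DfbaConfig:
    """Uptake rules and integration grid for the dFBA baseline.

    ``uptake`` maps monitored species to either ``("fixed", bound)`` or
    ``("monod", vmax, km)`` in mmol/gDW/h; species without a rule default
    to ``default_ub``.
    """

    uptake: dict = field(default_factory=dict)
    default_ub: float = 1000.0
    dt: float = 0.25
    tmax: float = 24.0

    def bound(self, species: str, conc: float) -> float:
        rule = self.uptake.get(species)
        if rule is None:
            return self.default_ub
        if rule[0] == "fixed":
            return float(rule[1])
        if rule[0] == "monod":
            vmax, km = rule[1], rule[2]
            c = max(conc, 0.0)
            return float(vmax * c / (km + c))
        raise ValueError(f"unknown uptake rule {rule!r}")


def dfba_simulate(model: IrreversibleModel, transport: TransportMatrix,
                  medium: dict[str, float], cfg: DfbaConfig) -> Trajectory:
    """Run the dFBA loop for one medium.

    ``medium`` maps monitored species to initial concentrations (biomass
    included; defaults to 0.01 gDW/L when omitted).  An LP failure mid-run
    is treated as stationary phase (fluxes zero, step flagged), so panels
    of media always complete.  Fluxes in the returned trajectory are
    volumetric (per liter), so the same Euler identity holds as for the
    hybrid rollout with r = 1.
    """
    if cfg.dt <= 0:
        raise ValueError("dt must be positive")
    S_int = sp.csr_matrix(model.internal_stoichiometry())
    Tm = transport.T
    n_sp, n_rxn = Tm.shape
    species = transport.species_ids
    bio = transport.biomass_index
    C0 = np.array([
        float(medium.get(s, 0.01 if s == BIOMASS_SPECIES else 0.0))
        for s in species
    ])
    # columns consuming each monitored extracellular species
    uptake_cols = {i: np.flatnonzero(Tm[i] < 0) for i in range(n_sp)
                   if i != bio}
    objective = -Tm[bio]  # linprog minimizes

    n_steps = int(round(cfg.tmax / cfg.dt))
    times = np.arange(n_steps + 1) * cfg.dt
    C = np.empty((n_sp, n_steps + 1))
    V = np.zeros((n_rxn, n_steps + 1))
    r = np.zeros(n_steps + 1)
    flags: list[str] = []
    C[:, 0] = C0
    A_eq = S_int if S_int.shape[0] else None
    for t in range(1, n_steps + 1):
        c_now = C[:, t - 1]
        X = max(c_now[bio], 0.0)
        ub = np.full(n_rxn, cfg.default_ub)
        for i, cols in uptake_cols.items():
            b = cfg.bound(species[i], c_now[i])
            if len(cols):
                # also cap so the Euler step cannot overdraw the pool
                for j in cols:
                    avail = max(c_now[i], 0.0) / (X * cfg.dt * abs(Tm[i, j]) *
                                                  len(cols)) if X > 0 else 0.0
                    ub[j] = min(b, avail)
        res = linprog(objective, A_eq=A_eq,
                      b_eq=np.zeros(S_int.shape[0]) if A_eq is not None else None,
                      bounds=list(zip(np.zeros(n_rxn), ub)), method="highs")
        if res.status != 0:
            flags.append(f"lp_failed_step_{t}")
            v = np.zeros(n_rxn)
        else:
            v = np.maximum(res.x, 0.0)
        v_vol = X * v
        C[:, t] = c_now + (Tm @ v_vol) * cfg.dt
        C[:, t] = np.where((C[:, t] < 0) & (C[:, t] > -1e-9), 0.0, C[:, t])
        V[:, t] = v_vol
        r[t] = 1.0
    traj = Trajectory(times=times, C=C, V=V, r=r, species_ids=list(species))
    traj.flags = flags
    return traj
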