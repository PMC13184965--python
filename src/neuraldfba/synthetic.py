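"""Mechanistic synthetic growth data: combinatorial media, Monod kinetics,
yield stoichiometry, class-dependent lag phases, replicate noise.

The generator integrates a true kinetic ODE (not the hybrid model's own
update rule), so parameter-recovery and generalization tests against it are
non-circular.  For a toy network with substrates j the dynamics are

    dX/dt   = r(t) * X * sum_j Y_j v_j(C)        (biomass, gDW/L)
    dC_j/dt = -r(t) * X * v_j(C)                 (substrates, mM)
    v_j(C)  = vmax_j * C_j / (Km_j + C_j)        (uptake, mmol/gDW/h)

with the same lag gate r(t) the hybrid model uses, per-medium lag onset
drawn from the nutrient class of the medium's primary carbon source, and
gate stiffness klag = kappa / tlag so that the gate completes (r ~ 1-e^-kappa)
exactly around tlag -- the reading under which tlag is the observable lag
duration.  An optional overflow pair adds byproduct secretion during fast
substrate uptake and byproduct re-consumption (repressed while the primary
substrate remains), which produces classical diauxic curves.

Yields come from carbon bookkeeping: each substrate carries ``carbon`` atoms
per molecule, a fraction ``efficiency`` of assimilated carbon ends up in
biomass, and biomass costs ``gamma`` mmol carbon per gDW, so
Y_j = efficiency * carbon_j / gamma (gDW per mmol).
"""

from __future__ import annotations

import itertools
import json
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .metabolic_io import (
    BIOMASS_SPECIES,
    GenomeScaleModel,
    write_toy_table,
)
from .model import LagParams, lag_gate

__all__ = [
    "Component",
    "ToyNetwork",
    "SimConfig",
    "six_substrate_panel",
    "overflow_network",
    "design_media",
    "primary_class",
    "simulate_growth",
    "add_noise_and_replicate",
    "write_dataset",
    "load_tables",
    "generate_dataset",
]


@dataclass
class Component:
    """A medium component: nutrient class, carbon content, uptake kinetics."""

    id: str
    cls: str                 # 'sugar' | 'amino_acid' | 'nucleobase' | other
    carbon: int              # C atoms per molecule
    vmax: float              # mmol/gDW/h
    km: float                # mM


@dataclass
class ToyNetwork:
    """Desk-scale metabolic network: one uptake reaction per substrate into a
    shared internal carbon pool, one growth reaction draining the pool, and
    an optional overflow pair (byproduct secretion + re-consumption)."""

    substrates: list[Component]
    overflow: dict | None = None   # {source, byproduct, fraction, ki}
    efficiency: float = 0.6        # carbon fraction assimilated into biomass
    gamma: float = 40.0            # mmol C per gDW of biomass

    def __post_init__(self):
        ids = [c.id for c in self.substrates]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate substrate ids")
        if self.overflow is not None:
            for key in ("source", "byproduct"):
                if self.overflow[key] not in ids:
                    raise ValueError(f"overflow {key} not a substrate")

    @property
    def species_order(self) -> list[str]:
        """Monitored species: substrates in declared order, biomass last."""
        return [c.id for c in self.substrates] + [BIOMASS_SPECIES]

    def yield_of(self, comp: Component) -> float:
        """gDW produced per mmol substrate consumed (no overflow diversion)."""
        return self.efficiency * comp.carbon / self.gamma

    def component(self, cid: str) -> Component:
        return next(c for c in self.substrates if c.id == cid)

    def to_model(self) -> GenomeScaleModel:
        """Express the network in the toy-table stoichiometric form.

        Metabolites: one extracellular species per substrate plus an
        internal carbon pool; reactions: uptake per substrate, optional
        byproduct secretion, and the biomass reaction (flux = growth rate).
        """
        import scipy.sparse as sp

        met_ids = [f"{c.id}_e" for c in self.substrates] + ["c_pool"]
        compartments = ["e"] * len(self.substrates) + ["c"]
        rxn_ids = [f"upt_{c.id}" for c in self.substrates]
        rows, cols, vals = [], [], []
        pool = len(self.substrates)
        for j, c in enumerate(self.substrates):
            rows += [j, pool]
            cols += [j, j]
            vals += [-1.0, self.efficiency * c.carbon]
        if self.overflow is not None:
            byp = self.component(self.overflow["byproduct"])
            j = len(rxn_ids)
            rxn_ids.append(f"sec_{byp.id}")
            i_byp = [c.id for c in self.substrates].index(byp.id)
            rows += [pool, i_byp]
            cols += [j, j]
            vals += [-self.efficiency * byp.carbon, 1.0]
        j = len(rxn_ids)
        rxn_ids.append("growth")
        rows.append(pool)
        cols.append(j)
        vals.append(-self.gamma)
        S = sp.csc_matrix((vals, (rows, cols)),
                          shape=(len(met_ids), len(rxn_ids)))
        return GenomeScaleModel(
            metabolite_ids=met_ids,
            reaction_ids=rxn_ids,
            S=S,
            reversible=np.zeros(len(rxn_ids), dtype=bool),
            compartments=compartments,
            biomass_reaction_id="growth",
        )

    def species_mapping(self) -> dict[str, str]:
        """Monitored species id -> extracellular metabolite id."""
        return {c.id: f"{c.id}_e" for c in self.substrates}


def six_substrate_panel() -> ToyNetwork:
    """The standard desk-scale panel: 3 sugars + 3 amino acids.

    Kinetic constants are in the range reported for E. coli sugar and
    amino-acid transport (vmax ~ 5-10 mmol/gDW/h, Km ~ 0.1-0.5 mM).
    """
    return ToyNetwork(substrates=[
        Component("glc", "sugar", 6, 10.0, 0.1),
        Component("xyl", "sugar", 5, 8.0, 0.5),
        Component("succ", "sugar", 4, 9.0, 0.2),
        Component("ala", "amino_acid", 3, 6.0, 0.1),
        Component("glt", "amino_acid", 5, 5.0, 0.1),
        Component("ser", "amino_acid", 3, 7.0, 0.1),
    ])


def overflow_network(fraction: float = 0.3, ki: float = 0.05) -> ToyNetwork:
    """Glucose/acetate overflow pair: acetate is secreted in proportion to
    glucose uptake and re-consumed only once glucose is (nearly) gone."""
    return ToyNetwork(
        substrates=[
            Component("glc", "sugar", 6, 10.0, 0.1),
            Component("ace", "organic_acid", 2, 6.0, 0.5),
        ],
        overflow={"source": "glc", "byproduct": "ace",
                  "fraction": fraction, "ki": ki},
    )


@dataclass
class SimConfig:
    """Study conditions of the synthetic experiments.

    ``lag_rule`` maps nutrient class to (mean, sd) of the lag onset tlag in
    hours; ``kappa`` sets per-medium gate stiffness klag = kappa/tlag (use
    ``fixed_klag`` to override).  ``x0`` is the inoculum in gDW/L; noise is
    multiplicative lognormal per observation.
    """

    lag_rule: dict = field(default_factory=lambda: {
        "sugar": (5.6, 0.3),
        "amino_acid": (1.5, 0.3),
        "nucleobase": (3.0, 0.3),
    })
    default_lag: tuple = (3.0, 0.3)
    kappa: float = 3.0
    fixed_klag: float | None = None
    noise_sd: float = 0.02
    replicates: int = 3
    dt: float = 0.25
    tmax: float = 24.0
    x0: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.replicates < 1:
            raise ValueError("noise sd must be >= 0 and replicates >= 1")
        if self.dt <= 0 or self.tmax <= 0 or self.x0 <= 0:
            raise ValueError("dt, tmax and x0 must be positive")


# ---------------------------------------------------------------------------
# media design

def design_media(components: list[Component], scheme: str,
                 n_media: int | None = None, seed: int = 0, k: int = 2,
                 levels: tuple = (5.0, 10.0, 20.0)) -> pd.DataFrame:
    """Combinatorial media over the component panel.

    Schemes: ``single`` (one component per medium), ``pairwise`` (all
    unordered pairs), ``random-k`` (distinct random draws of k components,
    each at a concentration level drawn from ``levels``), ``random-k-pure``
    (like random-k but all k components share one nutrient class, so the
    medium's primary-nutrient class is unambiguous -- the design used to
    probe class-dependent lag times).  Deterministic given the seed; media
    are distinct by construction.  Returns a long table (medium_id,
    species, concentration) in mM.
    """
    rng = np.random.default_rng(seed)
    mid_level = levels[len(levels) // 2]
    combos: list[tuple[tuple[str, float], ...]] = []
    if scheme == "single":
        combos = [((c.id, mid_level),) for c in components]
    elif scheme == "single-levels":
        combos = [((c.id, float(lv)),) for c in components for lv in levels]
    elif scheme == "pairwise":
        combos = [((a.id, mid_level), (b.id, mid_level))
                  for a, b in itertools.combinations(components, 2)]
    elif scheme == "random-k-pure":
        if n_media is None:
            raise ValueError("random-k-pure scheme requires n_media")
        from math import comb

        classes = sorted({c.cls for c in components})
        by_cls = {cl: [c for c in components if c.cls == cl] for cl in classes}
        capacity = sum(comb(len(v), k) * len(levels) ** k
                       for v in by_cls.values() if len(v) >= k)
        if n_media > capacity:
            raise ValueError(
                f"requested {n_media} media but only {capacity} distinct "
                f"class-pure combinations exist"
            )
        seen = set()
        while len(combos) < n_media:
            cl = classes[int(rng.integers(len(classes)))]
            pool = by_cls[cl]
            if len(pool) < k:
                continue
            idx = tuple(sorted(rng.choice(len(pool), size=k, replace=False)))
            lv = tuple(rng.choice(len(levels), size=k))
            key = (cl, idx, lv)
            if key in seen:
                continue
            seen.add(key)
            combos.append(tuple((pool[i].id, float(levels[l]))
                                for i, l in zip(idx, lv)))
    elif scheme == "random-k":
        if n_media is None:
            raise ValueError("random-k scheme requires n_media")
        from math import comb

        capacity = comb(len(components), k) * len(levels) ** k
        if n_media > capacity:
            raise ValueError(
                f"requested {n_media} media but only {capacity} distinct "
                f"combinations exist (n={len(components)}, k={k}, "
                f"{len(levels)} levels)"
            )
        seen = set()
        while len(combos) < n_media:
            idx = tuple(sorted(rng.choice(len(components), size=k,
                                          replace=False)))
            lv = tuple(rng.choice(len(levels), size=k))
            key = (idx, lv)
            if key in seen:
                continue
            seen.add(key)
            combos.append(tuple((components[i].id, float(levels[l]))
                                for i, l in zip(idx, lv)))
    else:
        raise ValueError(f"unknown media scheme {scheme!r}")

    if n_media is not None and scheme != "random-k":
        if n_media > len(combos):
            raise ValueError(
                f"requested {n_media} media but scheme {scheme!r} yields "
                f"only {len(combos)}"
            )
        combos = combos[:n_media]

    rows = []
    for m, combo in enumerate(combos):
        for species, conc in combo:
            rows.append({"medium_id": f"M{m:03d}", "species": species,
                         "concentration": conc})
    return pd.DataFrame(rows)


def primary_class(medium: dict[str, float],
                  components: list[Component]) -> str:
    """Nutrient class supplying the largest carbon-weighted concentration."""
    by_cls: dict[str, float] = {}
    comp_map = {c.id: c for c in components}
    for species, conc in medium.items():
        if species == BIOMASS_SPECIES or species not in comp_map:
            continue
        c = comp_map[species]
        by_cls[c.cls] = by_cls.get(c.cls, 0.0) + c.carbon * conc
    if not by_cls:
        return "other"
    return max(by_cls, key=by_cls.get)


# ---------------------------------------------------------------------------
# kinetic simulation

def _draw_lag(cls: str, cfg: SimConfig, rng) -> tuple[float, float]:
    mean, sd = cfg.lag_rule.get(cls, cfg.default_lag)
    tlag = max(float(rng.normal(mean, sd)), 0.2)
    klag = cfg.fixed_klag if cfg.fixed_klag is not None else cfg.kappa / tlag
    return tlag, klag


def simulate_growth(net: ToyNetwork, medium: dict[str, float], cfg: SimConfig,
                    rng=None, lag: tuple[float, float] | None = None):
    """Noiseless trajectory on the dt grid plus ground truth.

    ``medium`` maps substrate ids to initial mM.  Returns ``(times, C,
    truth)`` with ``C`` of shape (n_species, n_times) ordered as
    ``net.species_order`` (biomass last, starting at cfg.x0) and ``truth``
    recording tlag, klag, nutrient class, and yields.  Integration uses an
    adaptive solver with internal steps capped at dt/10 and terminal
    depletion events, so substrates never go negative.
    """
    unknown = set(medium) - {c.id for c in net.substrates}
    if unknown:
        raise ValueError(f"medium components not in network: {sorted(unknown)}")
    rng = rng or np.random.default_rng(cfg.seed)
    subs = net.substrates
    n_s = len(subs)
    cls = primary_class(medium, subs)
    tlag, klag = lag if lag is not None else _draw_lag(cls, cfg, rng)
    lag_p = LagParams(tlag, klag)

    over = net.overflow
    i_src = i_byp = None
    if over is not None:
        ids = [c.id for c in subs]
        i_src, i_byp = ids.index(over["source"]), ids.index(over["byproduct"])
        e_byp = net.efficiency * subs[i_byp].carbon

    C0 = np.array([float(medium.get(c.id, 0.0)) for c in subs] + [cfg.x0])
    active = C0[:n_s] > 0
    if over is not None:
        active[i_byp] = True  # byproduct may appear even if absent initially

    def rhs(t, y):
        C, X = y[:n_s], y[n_s]
        r = float(lag_gate(t, lag_p))
        v = np.array([
            c.vmax * max(Cj, 0.0) / (c.km + max(Cj, 0.0)) if act else 0.0
            for c, Cj, act in zip(subs, C, active)
        ])
        carbon_in = net.efficiency * np.array([c.carbon for c in subs]) * v
        dC = -v.copy()
        v_sec = 0.0
        if over is not None:
            # divert a fixed carbon fraction of source uptake to the byproduct
            v_sec = over["fraction"] * carbon_in[i_src] / e_byp
            carbon_in[i_src] *= 1.0 - over["fraction"]
            # re-consumption is repressed while the source remains
            rep = over["ki"] / (over["ki"] + max(C[i_src], 0.0))
            carbon_in[i_byp] *= rep
            dC[i_byp] = -v[i_byp] * rep + v_sec
        v_gro = carbon_in.sum() / net.gamma
        return np.concatenate([r * X * dC, [r * X * v_gro]])

    n_times = int(round(cfg.tmax / cfg.dt)) + 1
    times = np.arange(n_times) * cfg.dt
    out = np.empty((n_s + 1, n_times))
    out[:, 0] = C0

    def make_events():
        evs = []
        for j in range(n_s):
            if not active[j] or (over is not None and j == i_byp):
                continue

            def ev(t, y, j=j):
                return y[j] - 1e-9

            ev.terminal = True
            ev.direction = -1
            evs.append((j, ev))
        return evs

    t0, y0 = 0.0, C0.copy()
    filled = 1
    while t0 < cfg.tmax - 1e-12:
        events = make_events()
        sol = solve_ivp(rhs, (t0, cfg.tmax), y0, method="RK45",
                        max_step=cfg.dt / 10.0, rtol=1e-8, atol=1e-10,
                        events=[e for _, e in events], dense_output=True)
        if not sol.success and sol.status != 1:
            raise RuntimeError(f"integration failed at t={t0}: {sol.message}")
        t_end = sol.t[-1]
        while filled < n_times and times[filled] <= t_end + 1e-12:
            out[:, filled] = sol.sol(min(times[filled], t_end))
            filled += 1
        if sol.status == 1:  # a substrate depleted: clamp, deactivate, go on
            y0 = sol.y[:, -1].copy()
            for (j, _), t_ev in zip(events, sol.t_events):
                if len(t_ev):
                    y0[j] = 0.0
                    active[j] = False
            t0 = t_end
        else:
            break
    out[:n_s, :] = np.maximum(out[:n_s, :], 0.0)

    truth = {
        "tlag": tlag, "klag": klag, "class": cls,
        "yields": {c.id: net.yield_of(c) for c in subs},
    }
    return times, out, truth


def add_noise_and_replicate(times, C, species: list[str], medium_id: str,
                            cfg: SimConfig, rng,
                            measured: list[str] | None = None) -> pd.DataFrame:
    """Observation table with multiplicative lognormal noise per replicate.

    Only ``measured`` species are emitted (default: all); noise is
    independent across observations and replicates, seeded by ``rng``.
    """
    measured = measured if measured is not None else list(species)
    rows = []
    for rep in range(cfg.replicates):
        for i, sp_id in enumerate(species):
            if sp_id not in measured:
                continue
            noise = (np.exp(rng.normal(0.0, cfg.noise_sd, size=len(times)))
                     if cfg.noise_sd > 0 else np.ones(len(times)))
            vals = C[i] * noise
            for t, v in zip(times, vals):
                rows.append({"medium_id": medium_id, "time": float(t),
                             "species": sp_id, "value": float(v),
                             "replicate": rep})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset assembly and I/O

def generate_dataset(net: ToyNetwork, media: pd.DataFrame, cfg: SimConfig,
                     measured: list[str] | None = None):
    """Simulate every medium, add replicate noise, and assemble a dataset.

    ``measured`` lists observed species (default: biomass only, the
    plate-reader setting); initial concentrations of all components are
    always known via the media table.  Returns ``(GrowthDataset, truth)``
    where truth maps medium id to the generator's lag parameters, class,
    and the noiseless curves.
    """
    from .training import GrowthDataset

    rng = np.random.default_rng(cfg.seed)
    measured = measured if measured is not None else [BIOMASS_SPECIES]
    species = net.species_order
    media = media.copy()
    series_frames = []
    truth: dict[str, dict] = {}
    for mid, grp in media.groupby("medium_id", sort=True):
        comp = dict(zip(grp["species"], grp["concentration"]))
        comp.pop(BIOMASS_SPECIES, None)
        times, C, tr = simulate_growth(net, comp, cfg, rng=rng)
        tr["noiseless"] = C
        truth[mid] = tr
        series_frames.append(add_noise_and_replicate(
            times, C, species, mid, cfg, rng, measured))
    # record the inoculum so C(0) is complete
    bio_rows = pd.DataFrame({
        "medium_id": sorted(truth),
        "species": BIOMASS_SPECIES,
        "concentration": cfg.x0,
    })
    media_full = pd.concat([media, bio_rows], ignore_index=True)
    series = pd.concat(series_frames, ignore_index=True)
    mask = pd.DataFrame([{"species": s, "measured": s in measured}
                         for s in species])
    ds = GrowthDataset(media=media_full, series=series, mask=mask,
                       dt=cfg.dt, species=species)
    return ds, truth


def write_dataset(media: pd.DataFrame, series: pd.DataFrame,
                  mask: pd.DataFrame, out_dir: str,
                  truth: dict | None = None,
                  network: ToyNetwork | None = None) -> None:
    """Emit media.csv, series.csv, mask.csv (+ truth.json, network.toy)."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    media.to_csv(out / "media.csv", index=False)
    series.to_csv(out / "series.csv", index=False)
    mask.to_csv(out / "mask.csv", index=False)
    if truth is not None:
        slim = {mid: {k: v for k, v in tr.items() if k != "noiseless"}
                for mid, tr in truth.items()}
        with open(out / "truth.json", "w") as fh:
            json.dump(slim, fh, indent=1)
    if network is not None:
        write_toy_table(network.to_model(), str(out / "network.toy"))


def load_tables(data_dir: str):
    """Read back the three CSV tables written by :func:`write_dataset`."""
    d = pathlib.Path(data_dir)
    media = pd.read_csv(d / "media.csv")
    series = pd.read_csv(d / "series.csv")
    mask = pd.read_csv(d / "mask.csv")
    return media, series, mask
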