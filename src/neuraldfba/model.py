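"""The hybrid neural-mechanistic growth model.

Two small feedforward networks are embedded in an Euler-integrated,
stoichiometrically constrained rollout:

* a lag network maps the initial monitored concentrations ``C(0)`` to
  lag-phase parameters ``(tlag, klag)``;
* a flux network maps the monitored state ``C(t-1)`` to a flux vector
  ``V(t)`` over all expanded (irreversible) reactions.

The rollout is the residual update

    C(t) = C(t-1) + r(t) * T V(t) * dt,      t = 1..tmax/dt,

where ``T`` is the transport matrix (rows of the expanded stoichiometric
matrix for the monitored external species plus biomass) and ``r(t)`` the
lag gate: r(t) = 1 - exp(-klag*t) for t <= tlag and 1 afterwards.  The
current state acts as the skip connection and the flux network only learns
the residual correction, so training starts from the flat trajectory.

Training minimizes a four-term, time-decayed loss: data fit (mse against
measured concentrations, masked to the measured channels), biomass
monotonicity, the intracellular steady-state constraint S.V = 0, and flux
nonnegativity, each weighted by w_i(t) = lambda_i * exp(-k_i * t) with t
the step index.  Gradients flow end-to-end through every Euler step; the
backward pass is written out explicitly in :func:`loss_and_gradients`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .metabolic_io import TransportMatrix
from .nn import MLP, sigmoid, softplus, softplus_inv

__all__ = [
    "LagParams",
    "Normalizer",
    "LagNet",
    "FluxNet",
    "LossWeights",
    "Trajectory",
    "DamnModel",
    "lag_gate",
    "lag_gate_grads",
    "predict_lag",
    "predict_flux",
    "rollout",
    "decay_weight",
    "loss_fit",
    "loss_biomass_monotone",
    "loss_steady_state",
    "loss_flux_positivity",
    "total_loss",
    "loss_and_gradients",
]

KLAG_FLOOR = 1e-3  # h^-1; keeps the gate well defined for any net output


@dataclass
class LagParams:
    """Lag-phase parameters: onset-of-full-growth time and gate stiffness.

    ``tlag`` in hours (>= 0), ``klag`` in 1/h (> 0).  Scalar or batched.
    """

    tlag: np.ndarray
    klag: np.ndarray

    def __post_init__(self):
        self.tlag = np.asarray(self.tlag, dtype=float)
        self.klag = np.asarray(self.klag, dtype=float)
        if not (np.all(np.isfinite(self.tlag)) and np.all(np.isfinite(self.klag))):
            raise ValueError("lag parameters must be finite")
        if np.any(self.tlag < 0) or np.any(self.klag <= 0):
            raise ValueError("tlag must be >= 0 and klag > 0")


@dataclass
class Normalizer:
    """Per-species affine standardization fitted on training data only.

    ``ln_mean``/``ln_sd`` standardize the log-biomass feature fed to the
    flux network in addition to the raw state: batch growth is exponential
    in biomass, so states that differ by orders of magnitude in biomass
    (lag versus late exponential) are well separated in log coordinates
    but nearly indistinguishable after linear standardization.
    """

    mean: np.ndarray
    sd: np.ndarray
    ln_mean: float = 0.0
    ln_sd: float = 1.0

    @classmethod
    def identity(cls, n: int) -> "Normalizer":
        return cls(np.zeros(n), np.ones(n))

    @classmethod
    def fit(cls, values: np.ndarray, floor: float = 1e-6,
            bio_index: int = -1) -> "Normalizer":
        """Fit from an (n_obs, n_species) array that may contain NaN."""
        mean = np.nanmean(values, axis=0)
        sd = np.nanstd(values, axis=0)
        mean = np.where(np.isfinite(mean), mean, 0.0)
        sd = np.where(np.isfinite(sd) & (sd > floor), sd, 1.0)
        bio = values[:, bio_index]
        ln = np.log(bio[np.isfinite(bio) & (bio > 0)])
        ln_mean = float(ln.mean()) if ln.size else 0.0
        ln_sd = float(ln.std()) if ln.size and ln.std() > floor else 1.0
        return cls(mean, sd, ln_mean, ln_sd)

    def transform(self, C: np.ndarray) -> np.ndarray:
        return (C - self.mean) / self.sd


def lag_gate(t, lag: LagParams):
    """The lag gate exactly as defined: 1 - e^(-klag*t) for t <= tlag, 1 after.

    Nondecreasing in t, bounded in [0, 1], 0 at t = 0.  The jump at t = tlag
    (from 1 - e^(-klag*tlag) to 1, applied for t > tlag) is part of the
    definition and is negligible when klag*tlag >> 1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("lag gate requires t >= 0")
    ramp = -np.expm1(-lag.klag * t)
    return np.where(t > lag.tlag, 1.0, ramp)


def lag_gate_grads(t, tlag, klag, tau: float = 0.5):
    """Gate value plus the derivatives used by the training rollout.

    The forward value is the exact piecewise gate (so training and
    evaluation see the same dynamics).  The klag derivative is the exact
    one of the ramp branch; the tlag derivative, which is zero almost
    everywhere for the piecewise form, is replaced by the derivative of a
    sigmoid blend of width ``tau`` (a straight-through surrogate: it
    concentrates the jump's influence in a window of width ~tau around
    tlag instead of a point mass).  Returns (r, dr/dtlag, dr/dklag).
    """
    t = np.asarray(t, dtype=float)
    E = np.exp(-klag * t)
    r = np.where(t > tlag, 1.0, 1.0 - E)
    s = sigmoid((t - tlag) / tau)
    dr_dtlag = -E * s * (1.0 - s) / tau
    dr_dklag = np.where(t > tlag, 0.0, t * E)
    return r, dr_dtlag, dr_dklag


class LagNet:
    """Feedforward map from initial monitored concentrations to LagParams.

    Outputs pass through softplus (plus a floor on klag) so the LagParams
    invariants hold for any input; the output bias is seeded so that a
    zero-weight network returns the configured defaults (tlag0, klag0).
    """

    def __init__(self, n_in: int, hidden=(16,), tlag0: float = 3.0,
                 klag0: float = 1.0, rng=None,
                 normalizer: Normalizer | None = None):
        self.mlp = MLP([n_in, *hidden, 2], rng=rng, out_scale=0.1)
        self.mlp.b[-1][0] = softplus_inv(tlag0)
        self.mlp.b[-1][1] = softplus_inv(klag0 - KLAG_FLOOR)
        self.normalizer = normalizer or Normalizer.identity(n_in)
        self.tlag0, self.klag0 = tlag0, klag0

    def forward(self, C0: np.ndarray):
        """Return (LagParams, cache); C0 is (batch, n_species) raw units."""
        x = self.normalizer.transform(np.atleast_2d(np.asarray(C0, float)))
        z, cache = self.mlp.forward(x)
        tlag = softplus(z[:, 0])
        klag = softplus(z[:, 1]) + KLAG_FLOOR
        return LagParams(tlag, klag), (cache, z)

    def __call__(self, C0):
        return self.forward(C0)[0]

    def backward(self, cache_z, g_tlag, g_klag):
        cache, z = cache_z
        dz = np.stack([g_tlag * sigmoid(z[:, 0]),
                       g_klag * sigmoid(z[:, 1])], axis=1)
        return self.mlp.backward(cache, dz)


class FluxNet:
    """Feedforward map from the monitored state C(t-1) to a flux vector.

    By default the network predicts per-biomass specific rates g(C) and
    the flux vector is V = X * g(C) with X the biomass component of the
    state -- the standard kinetic parameterization of volumetric fluxes
    (reaction rates scale with catalyst amount), still a pure function of
    C(t-1).  This makes the dependence of V on biomass structural, so
    trajectories extrapolate correctly to biomass densities outside the
    training range; set ``biomass_scaled=False`` for a direct volumetric
    output.  The input is the standardized state augmented with a
    standardized log-biomass feature (growth is exponential in biomass,
    so the log coordinate separates lag-phase from exponential-phase
    states that are nearly identical on a linear scale).  Output is raw
    linear by default -- flux nonnegativity is encouraged softly by the
    positivity loss term, mirroring how the training objective is posed
    -- with an optional softplus output that enforces it exactly.
    """

    X_FLOOR = 1e-6  # gDW/L; log feature is clipped (zero gradient) below

    def __init__(self, n_in: int, n_rxn: int, hidden=(64, 64),
                 nonnegative: bool = False, rng=None,
                 normalizer: Normalizer | None = None,
                 bio_index: int = -1, log_bio: bool = True,
                 biomass_scaled: bool = True):
        extra = 1 if log_bio else 0
        self.mlp = MLP([n_in + extra, *hidden, n_rxn], rng=rng, out_scale=0.05)
        self.nonnegative = nonnegative
        self.normalizer = normalizer or Normalizer.identity(n_in)
        self.n_rxn = n_rxn
        self.n_species = n_in
        self.bio_index = bio_index
        self.log_bio = log_bio
        self.biomass_scaled = biomass_scaled

    def forward(self, state: np.ndarray):
        """Return (V, cache); state is (batch, n_species) raw units."""
        state = np.atleast_2d(np.asarray(state, float))
        x = self.normalizer.transform(state)
        if self.log_bio:
            Xc = np.maximum(state[:, self.bio_index], self.X_FLOOR)
            f = (np.log(Xc) - self.normalizer.ln_mean) / self.normalizer.ln_sd
            x = np.concatenate([x, f[:, None]], axis=1)
        a, cache = self.mlp.forward(x)
        g = softplus(a) if self.nonnegative else a
        if self.biomass_scaled:
            X = np.maximum(state[:, self.bio_index], 0.0)
            V = X[:, None] * g
        else:
            V = g
        return V, (cache, a, state, g)

    def __call__(self, state):
        return self.forward(state)[0]

    def backward(self, cache_a, gV):
        """Accumulate parameter grads; return dL/d(state) in raw units."""
        cache, a, state, g = cache_a
        if self.biomass_scaled:
            X = np.maximum(state[:, self.bio_index], 0.0)
            gg = gV * X[:, None]
        else:
            gg = gV
        ga = gg * sigmoid(a) if self.nonnegative else gg
        gx = self.mlp.backward(cache, ga)
        gstate = gx[:, :self.n_species] / self.normalizer.sd
        if self.log_bio:
            X_raw = state[:, self.bio_index]
            live = X_raw > self.X_FLOOR
            gstate[:, self.bio_index] += np.where(
                live, gx[:, self.n_species] / (np.maximum(X_raw, self.X_FLOOR)
                                               * self.normalizer.ln_sd), 0.0)
        if self.biomass_scaled:
            pos = state[:, self.bio_index] > 0
            gstate[:, self.bio_index] += np.where(
                pos, np.sum(gV * g, axis=1), 0.0)
        return gstate


def predict_lag(net: LagNet, C0) -> LagParams:
    """Lag-phase parameters for one or more initial media."""
    return net(C0)


def predict_flux(net: FluxNet, state) -> np.ndarray:
    """Flux vector over all expanded reactions for a monitored state."""
    return net(state)


@dataclass
class LossWeights:
    """Scale factors lambda_i and decay rates k_i of w_i(t) = lambda_i e^(-k_i t).

    Order of terms: (fit, biomass-monotone, steady-state, flux-positivity).
    """

    lam: np.ndarray = field(default_factory=lambda: np.ones(4))
    k: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if self.lam.shape != (4,) or self.k.shape != (4,):
            raise ValueError("LossWeights needs 4 lambdas and 4 ks")
        if np.any(self.lam <= 0) or np.any(self.k < 0):
            raise ValueError("lambdas must be > 0 and ks >= 0")

    def at(self, t) -> np.ndarray:
        """Weight 4-vector at step index t."""
        return self.lam * np.exp(-self.k * np.asarray(t, dtype=float))


def decay_weight(t, lam: float, k: float) -> float:
    """Time-decayed loss weight w(t) = lam * e^(-k*t); t is the step index."""
    if lam <= 0 or k < 0:
        raise ValueError("need lam > 0 and k >= 0")
    return lam * np.exp(-k * np.asarray(t, dtype=float))


@dataclass
class Trajectory:
    """Rollout output on the grid t = 0..tmax step dt.

    ``C`` is (n_species, n_times) concentrations, ``V`` (n_reactions,
    n_times) fluxes (column 0 is zero: V(t) is defined for t >= 1), ``r``
    the gate value per time.
    """

    times: np.ndarray
    C: np.ndarray
    V: np.ndarray
    r: np.ndarray
    species_ids: list[str] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.times) - 1


def rollout(C0, transport: TransportMatrix, lag_net: LagNet,
            flux_net: FluxNet, dt: float, tmax: float,
            clamp: bool = False) -> Trajectory:
    """Deterministic forward rollout for a single medium (exact lag gate).

    C(0) is assigned from the medium (hard constraint); each step applies
    the gated residual update exactly, so C(t) - C(t-1) = r(t) T V(t) dt.
    With ``clamp=True`` concentrations are floored at zero after each step
    (physical nonnegativity); useful for forward simulation beyond the
    observation window, where an unclamped rollout can drift into states
    far outside anything seen in training.  The default keeps the plain
    residual update, whose Euler identity holds exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    C0 = np.asarray(C0, dtype=float).ravel()
    if C0.shape[0] != transport.n_species:
        raise ValueError(
            f"C0 has {C0.shape[0]} species, transport expects {transport.n_species}"
        )
    n_steps = int(round(tmax / dt))
    times = np.arange(n_steps + 1) * dt
    lag_b = lag_net(C0[None, :])
    lag = LagParams(lag_b.tlag[0], lag_b.klag[0])
    Tm = transport.T
    consumes = Tm < 0
    consumes[transport.biomass_index, :] = False
    C = np.empty((transport.n_species, n_steps + 1))
    V = np.zeros((Tm.shape[1], n_steps + 1))
    r = np.zeros(n_steps + 1)
    C[:, 0] = C0
    for t in range(1, n_steps + 1):
        v = flux_net(C[:, t - 1][None, :])[0].ravel()
        if clamp:
            # physical simulation mode: irreversible reactions cannot run
            # backward, and nothing can be taken up from an exhausted pool
            # (training only encourages both softly)
            v = np.maximum(v, 0.0)
            empty = C[:, t - 1] <= 0.0
            v = np.where(empty @ consumes, 0.0, v)
        rt = float(lag_gate(times[t], lag))
        C[:, t] = C[:, t - 1] + rt * (Tm @ v) * dt
        if clamp:
            C[:, t] = np.maximum(C[:, t], 0.0)
        if not np.all(np.isfinite(C[:, t])):
            raise RuntimeError(f"non-finite concentrations at rollout step {t}")
        V[:, t] = v
        r[t] = rt
    return Trajectory(times=times, C=C, V=V, r=r,
                      species_ids=list(transport.species_ids))


# ---------------------------------------------------------------------------
# loss terms (per-time series over the trajectory grid; index 0 is zero
# because the total loss sums over t = 1..tmax)

def _check_grid(n_a: int, n_b: int):
    if n_a != n_b:
        raise ValueError(f"time grids differ in length ({n_a} vs {n_b})")


def loss_fit(traj: Trajectory, C_true: np.ndarray,
             mask: np.ndarray | None = None) -> np.ndarray:
    """Masked mse(C(t), C_true(t)) per time over the measured species.

    ``C_true`` is (n_species, n_times), NaN where unmeasured; ``mask``
    optionally restricts further.  Times with no measured species
    contribute zero.
    """
    C_true = np.asarray(C_true, dtype=float)
    _check_grid(traj.C.shape[1], C_true.shape[1])
    m = np.isfinite(C_true)
    if mask is not None:
        m = m & np.asarray(mask, dtype=bool)
    diff = np.where(m, traj.C - np.where(m, C_true, 0.0), 0.0)
    counts = m.sum(axis=0)
    out = np.zeros(C_true.shape[1])
    nz = counts > 0
    out[nz] = (diff[:, nz] ** 2).sum(axis=0) / counts[nz]
    out[0] = 0.0
    return out


def loss_biomass_monotone(traj: Trajectory, biomass_index: int = -1,
                          sign: str = "prose") -> np.ndarray:
    """Penalty for biomass decreases (batch biomass cannot shrink).

    ``sign="prose"`` (default) penalizes drops, relu(X(t-1) - X(t))^2;
    ``sign="printed"`` penalizes increases, relu(X(t) - X(t-1))^2, kept for
    fidelity with the alternative reading of the objective.
    """
    X = traj.C[biomass_index]
    d = X[:-1] - X[1:] if sign == "prose" else X[1:] - X[:-1]
    out = np.zeros_like(X)
    out[1:] = np.maximum(d, 0.0) ** 2
    return out


def loss_steady_state(traj: Trajectory, S) -> np.ndarray:
    """mse(S V(t), 0) per time: soft intracellular steady-state constraint."""
    S = sp.csr_matrix(S)
    if S.shape[1] != traj.V.shape[0]:
        raise ValueError(
            f"S has {S.shape[1]} columns but V has {traj.V.shape[0]} reactions"
        )
    W = S @ traj.V
    out = np.asarray(W).reshape(S.shape[0], -1)
    res = (out ** 2).mean(axis=0)
    res[0] = 0.0
    return res


def loss_flux_positivity(traj: Trajectory) -> np.ndarray:
    """mse(relu(-V(t)), 0) per time: zero iff all fluxes are nonnegative."""
    res = (np.maximum(-traj.V, 0.0) ** 2).mean(axis=0)
    res[0] = 0.0
    return res


def total_loss(parts, weights: LossWeights) -> float:
    """Double sum over t = 1..tmax and the four terms of w_i(t) * Loss_i(t)."""
    parts = [np.asarray(p, dtype=float) for p in parts]
    n = parts[0].shape[-1]
    for p in parts[1:]:
        _check_grid(p.shape[-1], n)
    t = np.arange(1, n)
    total = 0.0
    for i, p in enumerate(parts):
        w = weights.lam[i] * np.exp(-weights.k[i] * t)
        total += float(np.sum(w * p[1:]))
    return total


# ---------------------------------------------------------------------------
# training-time rollout with explicit backward pass (BPTT)

def loss_and_gradients(C0, C_true, model: "DamnModel",
                       weights: LossWeights | None = None,
                       accumulate: bool = True, return_traj: bool = False):
    """Batched training rollout, four-term loss, and exact gradients.

    ``C0`` is (B, n_species); ``C_true`` is (B, n_species, n_times) with NaN
    at unobserved entries.  Uses the sigmoid-smoothed lag gate (width
    ``model.gate_tau``) so the lag-onset time receives a gradient.  Returns
    ``(total, parts)`` where ``parts`` is the (4,) vector of summed weighted
    terms; parameter gradients are accumulated into both networks unless
    ``accumulate`` is False (forward pass only).
    """
    weights = weights or model.weights
    B, S_n = C0.shape
    n_times = C_true.shape[2]
    T_steps = n_times - 1
    Tm = model.transport.T
    R = Tm.shape[1]
    S_int = model.S_loss
    M = max(S_int.shape[0], 1)
    bio = model.transport.biomass_index
    dt = model.dt
    pm = 1.0 if model.loss2_sign == "prose" else -1.0
    tau = model.gate_tau
    flux_net, lag_net = model.flux_net, model.lag_net

    mask = np.isfinite(C_true)
    C_obs = np.where(mask, C_true, 0.0)
    counts = mask.sum(axis=1)                       # (B, n_times)
    inv_counts = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
    # mild channel balancing: residuals are scaled by sqrt(sd_bio/sd_ch), a
    # compromise between raw units (a 20 mM substrate channel drowns a
    # 1 g/L biomass channel) and full standardization (which makes small
    # unphysical substrate excursions nearly free)
    sd = model.normalizer.sd
    ch_w = np.sqrt(sd[bio] / sd)[None, :]

    lag, lag_cache = lag_net.forward(C0)
    tlag, klag = lag.tlag, lag.klag
    consumes = Tm < 0
    consumes[bio, :] = False
    # exhaustion masking applies only to channels that are actually
    # measured: for those, continued uptake at zero observed concentration
    # is an unphysical escape route the data cannot veto strongly enough;
    # unmeasured channels keep the plain residual dynamics
    measured_ch = np.any(mask, axis=2)                 # (B, n_species)

    w = np.stack([weights.at(t) for t in range(n_times)])   # (n_times, 4)

    C_t = C0.copy()
    Cs = [C0]
    caches, Vs, Us = [], [], []
    r_all = np.zeros((n_times, B))
    dr_dtl = np.zeros((n_times, B))
    dr_dkl = np.zeros((n_times, B))
    parts = np.zeros(4)
    masks = []
    for t in range(1, n_times):
        V_raw, cache = flux_net.forward(C_t)
        # uptake from exhausted substrates is masked (binary, treated as
        # constant in the backward pass)
        m_upt = ~(((C_t <= 0.0) & measured_ch) @ consumes)
        V = V_raw * m_upt
        masks.append(m_upt)
        r, drt, drk = lag_gate_grads(t * dt, tlag, klag, tau)
        U = V @ Tm.T
        C_t = C_t + dt * r[:, None] * U
        if not np.all(np.isfinite(C_t)):
            raise FloatingPointError(f"non-finite state at rollout step {t}")
        caches.append(cache)
        Vs.append(V)
        Us.append(U)
        Cs.append(C_t)
        r_all[t], dr_dtl[t], dr_dkl[t] = r, drt, drk

        diff = (C_t - C_obs[:, :, t]) * mask[:, :, t] * ch_w
        parts[0] += w[t, 0] * np.sum(diff ** 2 * inv_counts[:, None, t]) / B
        d2 = pm * (Cs[t - 1][:, bio] - C_t[:, bio])
        parts[1] += w[t, 1] * np.sum(np.maximum(d2, 0.0) ** 2) / B
        W_res = S_int @ V.T                              # (M, B)
        W_res = np.asarray(W_res)
        parts[2] += w[t, 2] * np.sum(W_res ** 2) / (M * B)
        parts[3] += w[t, 3] * np.sum(np.maximum(-V, 0.0) ** 2) / (R * B)

    total = float(parts.sum())
    if return_traj:
        return total, parts, np.stack(Cs, axis=2)   # (B, n_species, n_times)
    if not accumulate:
        return total, parts

    gC = np.zeros((B, S_n))
    g_tlag = np.zeros(B)
    g_klag = np.zeros(B)
    for t in range(T_steps, 0, -1):
        C_here, C_prev = Cs[t], Cs[t - 1]
        diff = (C_here - C_obs[:, :, t]) * mask[:, :, t] * ch_w
        gC += w[t, 0] * 2.0 * diff * ch_w * inv_counts[:, None, t] / B
        d2 = pm * (C_prev[:, bio] - C_here[:, bio])
        g_d2 = w[t, 1] * 2.0 * np.maximum(d2, 0.0) / B
        gC[:, bio] += -pm * g_d2

        V, U, cache = Vs[t - 1], Us[t - 1], caches[t - 1]
        gV = dt * r_all[t][:, None] * (gC @ Tm)
        W_res = np.asarray(S_int @ V.T)
        gV += w[t, 2] * (2.0 / (M * B)) * np.asarray(S_int.T @ W_res).T
        gV += -w[t, 3] * (2.0 / (R * B)) * np.maximum(-V, 0.0)

        g_r = dt * np.sum(gC * U, axis=1)
        g_tlag += g_r * dr_dtl[t]
        g_klag += g_r * dr_dkl[t]

        gx = flux_net.backward(cache, gV * masks[t - 1])
        gC = gC + gx
        gC[:, bio] += pm * g_d2
    lag_net.backward(lag_cache, g_tlag, g_klag)
    return total, parts


# ---------------------------------------------------------------------------
# model bundle

class DamnModel:
    """Bundle of transport matrix, constraint matrix, both nets and config."""

    def __init__(self, transport: TransportMatrix, S_int, dt: float = 0.25,
                 weights: LossWeights | None = None,
                 lag_hidden=(16,), flux_hidden=(64, 64),
                 tlag0: float = 3.0, klag0: float = 1.0,
                 nonnegative_flux: bool = False, biomass_scaled: bool = True,
                 loss2_sign: str = "prose", gate_tau: float = 0.5,
                 seed: int = 0):
        if loss2_sign not in ("prose", "printed"):
            raise ValueError("loss2_sign must be 'prose' or 'printed'")
        self.transport = transport
        self.S_int = sp.csr_matrix(S_int)
        # row-normalized copy used by the training penalty: the constraint
        # S.V = 0 has the same zero set, but unnormalized rows (biomass
        # stoichiometries reach tens of mmol/gDW) give the penalty a
        # curvature ~|row|^2 that dwarfs the data-fit term and stalls
        # optimization on the constraint manifold
        if self.S_int.shape[0]:
            norms = np.sqrt(np.asarray(self.S_int.multiply(self.S_int)
                                       .sum(axis=1)).ravel())
            D = sp.diags(1.0 / np.maximum(norms, 1e-12))
            self.S_loss = sp.csr_matrix(D @ self.S_int)
        else:
            self.S_loss = self.S_int
        self.dt = float(dt)
        self.weights = weights or LossWeights()
        self.loss2_sign = loss2_sign
        self.gate_tau = float(gate_tau)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        n_sp = transport.n_species
        n_rxn = transport.T.shape[1]
        self.normalizer = Normalizer.identity(n_sp)
        self.lag_net = LagNet(n_sp, hidden=lag_hidden, tlag0=tlag0,
                              klag0=klag0, rng=rng, normalizer=self.normalizer)
        self.flux_net = FluxNet(n_sp, n_rxn, hidden=flux_hidden,
                                nonnegative=nonnegative_flux, rng=rng,
                                normalizer=self.normalizer,
                                bio_index=transport.biomass_index,
                                biomass_scaled=biomass_scaled)
        self._config = dict(dt=dt, lag_hidden=list(lag_hidden),
                            flux_hidden=list(flux_hidden), tlag0=tlag0,
                            klag0=klag0, nonnegative_flux=nonnegative_flux,
                            biomass_scaled=biomass_scaled,
                            loss2_sign=loss2_sign, gate_tau=gate_tau, seed=seed)

    # -- convenience -----------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return self.transport.species_ids

    def set_normalizer(self, norm: Normalizer) -> None:
        self.normalizer = norm
        self.lag_net.normalizer = norm
        self.flux_net.normalizer = norm

    def parameters(self):
        return self.lag_net.mlp.parameters() + self.flux_net.mlp.parameters()

    def gradients(self):
        return self.lag_net.mlp.gradients() + self.flux_net.mlp.gradients()

    def zero_grad(self):
        self.lag_net.mlp.zero_grad()
        self.flux_net.mlp.zero_grad()

    def simulate(self, C0, tmax: float, clamp: bool = False) -> Trajectory:
        """Forward rollout with the exact (printed) lag gate."""
        return rollout(C0, self.transport, self.lag_net, self.flux_net,
                       self.dt, tmax, clamp=clamp)

    # -- checkpointing ---------------------------------------------------
    def save(self, path: str) -> None:
        """Single-file npz checkpoint plus a JSON config sidecar."""
        S_coo = sp.coo_matrix(self.S_int)
        arrays = {
            "T": self.transport.T,
            "S_int_row": S_coo.row, "S_int_col": S_coo.col,
            "S_int_data": S_coo.data,
            "S_int_shape": np.array(S_coo.shape),
            "norm_mean": self.normalizer.mean, "norm_sd": self.normalizer.sd,
            "norm_ln": np.array([self.normalizer.ln_mean,
                                 self.normalizer.ln_sd]),
            "lam": self.weights.lam, "k": self.weights.k,
        }
        for i, (wm, bm) in enumerate(zip(self.lag_net.mlp.W, self.lag_net.mlp.b)):
            arrays[f"lag_W{i}"], arrays[f"lag_b{i}"] = wm, bm
        for i, (wm, bm) in enumerate(zip(self.flux_net.mlp.W, self.flux_net.mlp.b)):
            arrays[f"flux_W{i}"], arrays[f"flux_b{i}"] = wm, bm
        np.savez(path, **arrays)
        sidecar = dict(self._config,
                       species_ids=self.transport.species_ids,
                       reaction_ids=self.transport.reaction_ids)
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "DamnModel":
        with open(str(path) + ".json") as fh:
            cfg = json.load(fh)
        data = np.load(str(path) if str(path).endswith(".npz") else str(path))
        transport = TransportMatrix(species_ids=cfg["species_ids"],
                                    T=data["T"],
                                    reaction_ids=cfg.get("reaction_ids", []))
        S_int = sp.coo_matrix(
            (data["S_int_data"], (data["S_int_row"], data["S_int_col"])),
            shape=tuple(data["S_int_shape"]),
        ).tocsr()
        model = cls(transport, S_int, dt=cfg["dt"],
                    weights=LossWeights(data["lam"], data["k"]),
                    lag_hidden=tuple(cfg["lag_hidden"]),
                    flux_hidden=tuple(cfg["flux_hidden"]),
                    tlag0=cfg["tlag0"], klag0=cfg["klag0"],
                    nonnegative_flux=cfg["nonnegative_flux"],
                    biomass_scaled=cfg.get("biomass_scaled", True),
                    loss2_sign=cfg["loss2_sign"], gate_tau=cfg["gate_tau"],
                    seed=cfg["seed"])
        ln = data["norm_ln"] if "norm_ln" in data else np.array([0.0, 1.0])
        model.set_normalizer(Normalizer(data["norm_mean"], data["norm_sd"],
                                        float(ln[0]), float(ln[1])))
        for i in range(len(model.lag_net.mlp.W)):
            model.lag_net.mlp.W[i][...] = data[f"lag_W{i}"]
            model.lag_net.mlp.b[i][...] = data[f"lag_b{i}"]
        for i in range(len(model.flux_net.mlp.W)):
            model.flux_net.mlp.W[i][...] = data[f"flux_W{i}"]
            model.flux_net.mlp.b[i][...] = data[f"flux_b{i}"]
        return model
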