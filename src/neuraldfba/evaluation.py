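"""Goodness of fit per growth curve, distribution summaries, growth-rate
extraction, and lag-time reporting by nutrient class."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metabolic_io import BIOMASS_SPECIES
from .model import DamnModel

__all__ = [
    "CurveScore",
    "LagReport",
    "r2_curve",
    "summarize",
    "growth_rate",
    "lag_by_class",
    "evaluate_model",
]


@dataclass
class CurveScore:
    """Fit quality for one medium: biomass R^2, per-species R^2, and flags
    (negative predicted concentrations, non-monotone biomass, undefined R^2)."""

    medium_id: str
    r2: float
    per_species: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


@dataclass
class LagReport:
    """Predicted lag times grouped by nutrient class."""

    per_medium: pd.DataFrame          # medium_id, tlag, label
    class_means: pd.DataFrame         # label, mean, sd, n


def r2_curve(pred, obs, min_cv: float = 0.0) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot between curves.

    Returns NaN (undefined) when the observations have zero variance, or
    -- if ``min_cv`` > 0 -- when their coefficient of variation falls
    below it: a window that contains no dynamics beyond measurement noise
    (e.g. pure stationary phase) has SS_tot at the noise floor and R^2
    degenerates into a noise ratio.  Can be negative for fits worse than
    the observation mean.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must be aligned")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return np.nan
    if min_cv > 0 and abs(obs.mean()) > 0:
        if obs.std() / abs(obs.mean()) < min_cv:
            return np.nan
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def summarize(scores: list[CurveScore], bins=None) -> dict:
    """Mean/median/histogram over finite scores; flagged counts separately."""
    if not scores:
        raise ValueError("no scores to summarize")
    vals = np.array([s.r2 for s in scores], dtype=float)
    finite = vals[np.isfinite(vals)]
    if bins is None:
        bins = np.linspace(0.0, 1.0, 11)
    hist, edges = (np.histogram(np.clip(finite, bins[0], bins[-1]), bins=bins)
                   if finite.size else (np.zeros(len(bins) - 1, int), np.asarray(bins)))
    return {
        "n": len(scores),
        "n_undefined": int(np.sum(~np.isfinite(vals))),
        "n_flagged": sum(1 for s in scores if s.flags),
        "mean_r2": float(finite.mean()) if finite.size else np.nan,
        "median_r2": float(np.median(finite)) if finite.size else np.nan,
        "hist_counts": hist.tolist(),
        "hist_edges": np.asarray(edges).tolist(),
    }


def growth_rate(biomass, times, window: int = 5) -> float:
    """Maximum specific growth rate mu_max (1/h).

    Sliding-window least-squares slope of ln(biomass) against time, maximum
    over windows; exact on pure exponentials for any window size.
    """
    X = np.asarray(biomass, dtype=float)
    t = np.asarray(times, dtype=float)
    if np.any(X <= 0):
        raise ValueError("growth-rate extraction requires positive biomass")
    if len(X) < window + 1:
        raise ValueError(f"need at least {window + 1} points")
    ln = np.log(X)
    best = -np.inf
    for i in range(len(X) - window):
        tw = t[i:i + window + 1]
        yw = ln[i:i + window + 1]
        tc = tw - tw.mean()
        denom = float(np.sum(tc * tc))
        slope = float(np.sum(tc * (yw - yw.mean())) / denom)
        best = max(best, slope)
    return max(best, 0.0)


def lag_by_class(lags: dict[str, float], labels: dict[str, str]) -> LagReport:
    """Per-class mean and dispersion of predicted lag times.

    ``lags`` maps medium id to predicted tlag (hours); ``labels`` maps
    medium id to its nutrient-class label.  Every medium must be labeled;
    classes are reported only over their own media.
    """
    missing = set(lags) - set(labels)
    if missing:
        raise ValueError(f"unlabeled media: {sorted(missing)[:5]}")
    per = pd.DataFrame([
        {"medium_id": m, "tlag": v, "label": labels[m]}
        for m, v in sorted(lags.items())
    ])
    rows = []
    for label, grp in per.groupby("label"):
        rows.append({"label": label, "mean": float(grp["tlag"].mean()),
                     "sd": float(grp["tlag"].std(ddof=0)),
                     "n": len(grp)})
    return LagReport(per_medium=per, class_means=pd.DataFrame(rows))


def evaluate_model(model: DamnModel, ds, medium_ids=None,
                   neg_tol: float = 1e-6, min_cv: float = 0.0) -> list[CurveScore]:
    """Score the model's full-horizon rollouts against observed curves.

    For each medium the model is rolled out from C(0) over the dataset's
    time grid; R^2 is computed on the biomass channel at the observed times
    (per-species R^2 where other channels are measured).  With a forecast
    test slice the observed times are only the final third, so the score
    measures extrapolation.
    """
    ids = list(medium_ids) if medium_ids is not None else ds.medium_ids
    target, grid = ds.target_tensor(ids)
    C0 = ds.c0_matrix(ids)
    bio = model.transport.biomass_index
    scores = []
    for b, mid in enumerate(ids):
        traj = model.simulate(C0[b], tmax=grid[-1])
        per_species = {}
        flags = []
        for si, sp_id in enumerate(ds.species):
            obs = target[b, si, :]
            have = np.isfinite(obs)
            if have.sum() < 2:
                continue
            r2 = r2_curve(traj.C[si, have], obs[have], min_cv=min_cv)
            if np.isnan(r2):
                flags.append(f"undefined_r2:{sp_id}")
            per_species[sp_id] = r2
        if np.any(traj.C < -neg_tol):
            flags.append("negative_concentrations")
        X = traj.C[bio]
        if np.any(np.diff(X) < -neg_tol):
            flags.append("non_monotone_biomass")
        scores.append(CurveScore(
            medium_id=mid,
            r2=per_species.get(BIOMASS_SPECIES, np.nan),
            per_species=per_species,
            flags=flags,
        ))
    return scores
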