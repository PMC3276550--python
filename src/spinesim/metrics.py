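"""Readouts computed from trajectories.

Reported quantities follow the conventions of the source experiments:

* "phosphoThr34 DARPP-32" (and Thr75) count every species carrying the
  phosphosite, free or complexed, reported as total quantity divided by the
  volume of the reporting region;
* GluA1 phosphorylation is a percentage of the total receptor pool (Ser845
  status regardless of Ser831);
* "PKA activity" is the free catalytic subunit summed (integrated) over the
  recording window;
* spatial profiles are fit with a single exponential C0*exp(-x/lambda) + b;
* the colocalization analysis regresses PKA activity on local cAMP
  (continuous) and colocalization (binary) across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .network import ReactionNetwork
from .trajectory import Trajectory

__all__ = [
    "SpeciesGroup",
    "GradientFit",
    "phospho_groups",
    "window_average",
    "fold_change",
    "percent_phospho_GluA1",
    "fit_exponential_gradient",
    "activity_regression",
]

BASAL_CAMP_NM = 35.6


@dataclass(frozen=True)
class SpeciesGroup:
    """Named weighted set of species (weights = phosphosite multiplicity)."""

    name: str
    members: dict[str, int]

    def trace(self, traj: Trajectory, region: str = "all") -> np.ndarray:
        return traj.group_conc(self.members, region)


def _contains(network: ReactionNetwork, token: str) -> dict[str, int]:
    return {s.name: 1 for s in network.species if token in s.name}


def phospho_groups(network: ReactionNetwork) -> dict[str, SpeciesGroup]:
    """The standard reporting groups, derived from the species registry."""
    groups = {
        "pThr34": SpeciesGroup("pThr34", _contains(network, "p34D32")),
        "pThr75": SpeciesGroup("pThr75", _contains(network, "p75D32")),
        "pSer845": SpeciesGroup("pSer845", _contains(network, "pS845")),
        "pSer831": SpeciesGroup("pSer831", _contains(network, "pS831")),
        "PKAc_free": SpeciesGroup("PKAc_free", {"PKAc": 1}),
        "cAMP": SpeciesGroup("cAMP", {"cAMP": 1}),
        "Ca": SpeciesGroup("Ca", {"Ca": 1}),
        "GluA1_total": SpeciesGroup(
            "GluA1_total",
            {s.name: s.composition["glua1"] for s in network.species
             if s.composition.get("glua1")}),
        "D32_total": SpeciesGroup(
            "D32_total",
            {s.name: s.composition["d32"] for s in network.species
             if s.composition.get("d32")}),
        "pCaMKII": SpeciesGroup(
            "pCaMKII",
            {"CaMKIIp": 1, "CaMKIIpCamCa4": 1, "pComplex": 1, "CaMKIIp_PP1": 1,
             "CaMKIIpCamCa4_PP1": 1, "GluA1_CaMKIIp": 1, "GluA1_CaMKIIpCamCa4": 1,
             "pS845GluA1_CaMKIIp": 1, "pS845GluA1_CaMKIIpCamCa4": 1}),
    }
    return groups


# ---------------------------------------------------------------------------
# temporal metrics
# ---------------------------------------------------------------------------

def _window(traj: Trajectory, t0: float, t1: float) -> np.ndarray:
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    mask = (traj.times >= t0 - 1e-9) & (traj.times <= t1 + 1e-9)
    if mask.sum() < 2:
        raise ValueError(f"window [{t0}, {t1}] contains fewer than 2 samples")
    return mask


def window_average(traj: Trajectory, group: SpeciesGroup | dict[str, float],
                   t0: float, t1: float, region: str = "all",
                   mode: str = "mean") -> float:
    """Time average (or time integral, mode="sum") of a group concentration."""
    weights = group.members if isinstance(group, SpeciesGroup) else group
    mask = _window(traj, t0, t1)
    t = traj.times[mask]
    y = traj.group_conc(weights, region)[mask]
    integral = float(np.trapezoid(y, t))
    if mode == "sum":
        return integral
    if mode == "mean":
        return integral / (t[-1] - t[0])
    raise ValueError(f"unknown mode {mode!r}")


def fold_change(traj: Trajectory, group: SpeciesGroup | dict[str, float],
                baseline_window: tuple[float, float],
                response_window: tuple[float, float],
                region: str = "all", response_mode: str = "peak") -> float:
    """Response statistic divided by the baseline average.

    response_mode "peak": maximum of the trace inside the response window;
    "min": minimum (for quantities suppressed by the stimulus);
    "window": average over the response window.
    """
    weights = group.members if isinstance(group, SpeciesGroup) else group
    base = window_average(traj, weights, *baseline_window, region=region)
    if base <= 0:
        raise ValueError("baseline average is zero; fold change undefined")
    if response_mode == "window":
        resp = window_average(traj, weights, *response_window, region=region)
    else:
        mask = _window(traj, *response_window)
        y = traj.group_conc(weights, region)[mask]
        resp = float(np.max(y) if response_mode == "peak" else np.min(y))
    return resp / base


def percent_phospho_GluA1(traj: Trajectory, network: ReactionNetwork,
                          region: str = "all", site: str = "pSer845") -> np.ndarray:
    """Percent of the GluA1 pool phosphorylated on Ser845 (or Ser831), per time.

    Counts the site regardless of the other site's status, including
    phosphatase-bound forms.
    """
    groups = phospho_groups(network)
    phospho = groups[site].trace(traj, region)
    total = groups["GluA1_total"].trace(traj, region)
    out = np.zeros_like(phospho)
    nz = total > 0
    out[nz] = 100.0 * phospho[nz] / total[nz]
    return out


# ---------------------------------------------------------------------------
# spatial gradient fit
# ---------------------------------------------------------------------------

@dataclass
class GradientFit:
    decay_length: float | None  # um
    amplitude: float | None     # nM
    baseline: float             # nM
    decay_length_se: float | None
    residual: float
    identifiable: bool

    @property
    def lam(self):
        return self.decay_length


def fit_exponential_gradient(positions: np.ndarray, values: np.ndarray,
                             baseline: float | None = None) -> GradientFit:
    """Nonlinear least squares of C(x) = C0 * exp(-x / lambda) + b.

    ``baseline`` fixes b (e.g. at the basal concentration); otherwise b is a
    free parameter. A profile with no resolvable decay (relative range below
    2% or an amplitude indistinguishable from noise) is flagged
    non-identifiable and carries no decay length.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 positions")
    span = y.max() - y.min()
    scale = max(abs(y).max(), 1e-300)
    if span / scale < 0.02:
        return GradientFit(None, None, float(y.mean()), None,
                           float(np.std(y)), identifiable=False)

    span_x = x.max() - x.min()
    lam0 = span_x / 4 if span_x > 0 else 1.0
    if baseline is None:
        def model(x_, c0, lam, b):
            return c0 * np.exp(-x_ / lam) + b
        p0 = [max(span, 1e-12), lam0, max(float(y.min()), 1e-12)]
        bounds = ([0, 1e-6, 0], [np.inf, np.inf, np.inf])
    else:
        def model(x_, c0, lam):
            return c0 * np.exp(-x_ / lam) + baseline
        p0 = [max(span, 1e-12), lam0]
        bounds = ([0, 1e-6], [np.inf, np.inf])
    try:
        popt, pcov = curve_fit(model, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError:
        return GradientFit(None, None, float(baseline if baseline is not None
                                             else y.min()),
                           None, float(np.std(y)), identifiable=False)
    resid = float(np.sqrt(np.mean((model(x, *popt) - y) ** 2)))
    lam_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else None
    b = float(baseline if baseline is not None else popt[2])
    return GradientFit(float(popt[1]), float(popt[0]), b, lam_se, resid,
                       identifiable=True)


def trial_summary(values) -> dict:
    """Mean +/- SEM across repeated trials (the error bars of the figures)."""
    v = np.asarray(values, dtype=float)
    return {"mean": float(v.mean()),
            "sem": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
            "n": int(len(v))}


def welch_test(a, b) -> dict:
    """Two-sample comparison of seed ensembles (unequal variances)."""
    from scipy.stats import ttest_ind

    res = ttest_ind(np.asarray(a, float), np.asarray(b, float),
                    equal_var=False)
    return {"t": float(res.statistic), "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# colocalization regression
# ---------------------------------------------------------------------------

def activity_regression(local_camp: np.ndarray, colocalized: np.ndarray,
                        pka_activity: np.ndarray) -> dict:
    """OLS of PKA activity on local cAMP (continuous) + colocalization (0/1).

    Returns model R^2 and per-predictor p-values. Requires at least 8 runs
    spanning both colocalization levels.
    """
    import statsmodels.api as sm

    camp = np.asarray(local_camp, dtype=float)
    coloc = np.asarray(colocalized, dtype=float)
    y = np.asarray(pka_activity, dtype=float)
    if len(y) < 8:
        raise ValueError("need at least 8 runs for the regression")
    X = sm.add_constant(np.column_stack([camp, coloc]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()
    return {
        "r2": float(fit.rsquared),
        "p_camp": float(fit.pvalues[1]),
        "p_coloc": float(fit.pvalues[2]),
        "coef_camp": float(fit.params[1]),
        "coef_coloc": float(fit.params[2]),
        "n": int(len(y)),
    }
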