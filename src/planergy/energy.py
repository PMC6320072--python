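"""Organismal energy-balance model with three control paradigms.

The model states the physical energy balance of a growing/degrowing
planarian: the physiologically accessible energy content ``E`` changes
as ``dE/dt = J - P``, where ``J`` is the net influx of food energy and
``P`` the metabolic rate (heat loss). Dividing by the total cell number
``N`` gives a per-cell balance with influx ``j = J/N`` (non-zero only
while the animal is digesting a meal) and metabolic rate ``p = P/N``,
both in pW/cell. Cell number and energy are coupled because planarians
grow and shrink predominantly by changing cell number.

Three control paradigms close the model, i.e. specify how the reserve
per cell ``e = E/N`` behaves:

1. *dynamic reserve* — ``e`` is an independent state; cell number
   responds to the reserve deviation, ``(1/N) dN/dt = k (e - e_set)``.
   Two animals of equal size can carry different reserves depending on
   feeding history.
2. *isometric* — ``E = epsilon * N``: the reserve per cell is a
   size-independent constant.
3. *allometric* — ``E = e_ref * N_ref * (N/N_ref)**(1+c)``: the reserve
   per cell itself scales with size, ``e(N) = e_ref * (N/N_ref)**c``.

The paradigms make distinct predictions for how ``J/N``, ``E/N`` and
``P/N`` scale with ``N``, which is what lets calorimetry and feeding
data discriminate between them. Internally the per-day bookkeeping uses
J/day; pW inputs are converted at the API boundary
(1 pW = 86400e-12 J/day).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .powerlaw import PowerLawResults, DERIVED

__all__ = [
    "PW_TO_J_PER_DAY",
    "EnergyBalanceModel",
    "FeedingSchedule",
    "Trajectory",
    "ScalingPrediction",
    "ParadigmRateModel",
    "ParadigmFitResults",
    "fit_paradigm",
    "compare_paradigms",
    "predict_energy_per_cell",
    "assimilation_ratio",
]

#: 1 pW expressed in J/day.
PW_TO_J_PER_DAY = 86400e-12

DYNAMIC_RESERVE, ISOMETRIC, ALLOMETRIC = 1, 2, 3

_RTOL = 1e-8
_N_FLOOR = 1e3  # cells; starvation below this truncates the trajectory


class EnergyModelError(ValueError):
    pass


@dataclass(frozen=True)
class FeedingSchedule:
    """Boxcar feeding schedule: influx ``J = j*N`` inside the intervals.

    ``intervals`` are non-overlapping, ordered ``(start, end)`` pairs in
    days. Feeding is modelled as a continuous influx over a digestion
    window rather than an instantaneous pulse.
    """

    intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        prev_end = -math.inf
        for s, e in self.intervals:
            if e <= s:
                raise EnergyModelError(f"empty/reversed interval ({s}, {e})")
            if s < prev_end:
                raise EnergyModelError("feeding intervals overlap or are unordered")
            prev_end = e

    @classmethod
    def starvation(cls) -> "FeedingSchedule":
        return cls(())

    @classmethod
    def weekly(cls, n_weeks: int, pulse_days: float = 1.0,
               start: float = 0.0) -> "FeedingSchedule":
        """One feeding per week, each a ``pulse_days``-long influx window."""
        if not 0 < pulse_days <= 7:
            raise EnergyModelError("pulse_days must be in (0, 7]")
        iv = tuple((start + 7.0 * k, start + 7.0 * k + pulse_days)
                   for k in range(int(n_weeks)))
        return cls(iv)

    def fed(self, t: float) -> bool:
        return any(s <= t < e for s, e in self.intervals)

    def feeding_times(self) -> list[float]:
        return [s for s, _ in self.intervals]

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        pts = {t0, t1}
        for s, e in self.intervals:
            for p in (s, e):
                if t0 < p < t1:
                    pts.add(p)
        return np.array(sorted(pts))


@dataclass(frozen=True)
class Trajectory:
    """Simulated time course of cell number and energy content.

    ``net_input`` is the cumulative net energy influx
    ``Q(t) = integral of (J - P) dt`` carried as an auxiliary integrator
    state, so energy conservation ``E(t) - E(0) = Q(t)`` can be checked
    to integrator tolerance.
    """

    times: np.ndarray
    N: np.ndarray
    E: np.ndarray
    fed: np.ndarray
    paradigm: int
    net_input: np.ndarray
    truncated: bool = False

    def conservation_residual(self) -> float:
        """max |E(t) - E(0) - Q(t)| / max E over the trajectory."""
        resid = np.abs(self.E - self.E[0] - self.net_input)
        return float(np.max(resid) / np.max(self.E))

    def to_traces_frame(self, animal_id: str, n_vs_area: PowerLawResults
                        ) -> "pd.DataFrame":
        """Export in the long traces schema (areas via the inverse N/A law)."""
        import pandas as pd

        area = n_vs_area.invert().predict(self.N)
        return pd.DataFrame({
            "animal_id": animal_id,
            "time_days": self.times,
            "plan_area_mm2": area,
            "fed": self.fed.astype(int),
        })


@dataclass(frozen=True)
class EnergyBalanceModel:
    """Parameter set for one control paradigm of the energy balance.

    Parameters
    ----------
    paradigm : {1, 2, 3}
        1 dynamic reserve, 2 isometric (E = eps*N), 3 allometric
        (E/N = e_ref * (N/N_ref)**c).
    j, p : float
        Per-cell influx while fed, and per-cell metabolic rate [pW/cell].
    c : float
        Allometry exponent of the reserve per cell (paradigm 3 only);
        the energy content then scales as ``N**(1+c)``.
    e_ref : float
        Reserve per cell at the reference size N_ref [J/cell] (paradigm 3).
    n_ref : float
        Reference cell number decoupling the prefactor from unit choices.
    epsilon : float
        Constant reserve per cell [J/cell] (paradigm 2).
    k : float
        Sensitivity of the relative cell-number change to the reserve
        deviation [1/(day * J/cell)] (paradigm 1).
    e_set : float
        Reserve set point [J/cell] (paradigm 1).
    """

    paradigm: int
    j: float = 2.5
    p: float = 1.0
    c: float = 0.38
    e_ref: float = 3e-6
    n_ref: float = 1e6
    epsilon: float = 3e-6
    k: float = 1e4
    e_set: float = 3e-6

    def __post_init__(self):
        if self.paradigm not in (1, 2, 3):
            raise EnergyModelError(f"unknown paradigm {self.paradigm}")
        if self.p <= 0 or self.j < 0:
            raise EnergyModelError("require p > 0 and j >= 0")
        if self.paradigm == 3 and not (self.c > -1 and self.e_ref > 0):
            raise EnergyModelError("paradigm 3 requires c > -1 and e_ref > 0")
        if self.paradigm == 2 and self.epsilon <= 0:
            raise EnergyModelError("paradigm 2 requires epsilon > 0")
        if self.paradigm == 1 and self.k <= 0:
            raise EnergyModelError("paradigm 1 requires k > 0")

    # convenient constructors ------------------------------------------------
    @classmethod
    def dynamic_reserve(cls, j: float, p: float, k: float, e_set: float
                        ) -> "EnergyBalanceModel":
        return cls(paradigm=1, j=j, p=p, k=k, e_set=e_set)

    @classmethod
    def isometric(cls, j: float, p: float, epsilon: float) -> "EnergyBalanceModel":
        return cls(paradigm=2, j=j, p=p, epsilon=epsilon)

    @classmethod
    def allometric(cls, j: float, p: float, c: float, e_ref: float,
                   n_ref: float = 1e6) -> "EnergyBalanceModel":
        return cls(paradigm=3, j=j, p=p, c=c, e_ref=e_ref, n_ref=n_ref)

    # closed-form pieces -----------------------------------------------------
    def energy_of_cells(self, N):
        """``E(N)`` for the coupled paradigms (2 and 3).

        Paradigm 2: ``E = epsilon * N``. Paradigm 3:
        ``E = e_ref * N_ref * (N/N_ref)**(1+c)`` so ``E/N = e_ref *
        (N/N_ref)**c``. Paradigm 1 has no such constraint (E is state).
        """
        N = np.asarray(N, dtype=float)
        if np.any(N <= 0):
            raise EnergyModelError("N must be > 0")
        if self.paradigm == 2:
            out = self.epsilon * N
        elif self.paradigm == 3:
            out = self.e_ref * self.n_ref * (N / self.n_ref) ** (1.0 + self.c)
        else:
            raise EnergyModelError(
                "paradigm 1 has no E(N) constraint; E is an independent state")
        return out if out.ndim else float(out)

    def growth_rate(self, N, e: float | None = None, fed: bool = False):
        """Fractional growth rate ``(1/N) dN/dt`` in 1/day.

        Paradigm 2: ``(j[fed] - p)/epsilon``; paradigm 3 divides by the
        marginal energy cost of a cell, ``e_ref (1+c) (N/N_ref)**c``;
        paradigm 1 requires the current reserve ``e`` and returns
        ``k (e - e_set)``.
        """
        N = np.asarray(N, dtype=float)
        if np.any(N <= 0):
            raise EnergyModelError("N must be > 0")
        net = (self.j * (1.0 if fed else 0.0) - self.p) * PW_TO_J_PER_DAY
        if self.paradigm == 2:
            if e is not None:
                raise EnergyModelError("paradigm 2 takes no reserve argument")
            out = net / self.epsilon * np.ones_like(N)
        elif self.paradigm == 3:
            if e is not None:
                raise EnergyModelError("paradigm 3 takes no reserve argument")
            out = net / (self.e_ref * (1.0 + self.c)
                         * (N / self.n_ref) ** self.c)
        else:
            if e is None:
                raise EnergyModelError("paradigm 1 requires the reserve e")
            out = self.k * (e - self.e_set) * np.ones_like(N)
        return out if out.ndim else float(out)

    def predict_scaling_exponents(self) -> "ScalingPrediction":
        """Predicted exponents of E/N, P/N and J/N versus N."""
        if self.paradigm == 2:
            return ScalingPrediction(self.paradigm, 0.0, 0.0, 0.0)
        if self.paradigm == 3:
            return ScalingPrediction(self.paradigm, self.c, 0.0, 0.0)
        return ScalingPrediction(self.paradigm, None, 0.0, 0.0,
                                 note="E/N is history-dependent; "
                                      "not a pure power law")

    # simulation -------------------------------------------------------------
    def simulate(self, schedule: FeedingSchedule, N0: float,
                 E0: float | None = None,
                 t_grid: Sequence[float] | None = None,
                 t_end: float | None = None,
                 n_floor: float = _N_FLOOR) -> Trajectory:
        """Integrate the model over ``t_grid`` under ``schedule``.

        Paradigms 2/3 integrate ``N`` alone (E follows from the
        constraint); paradigm 1 integrates ``(N, E)`` jointly with
        ``dE/dt = (j [fed] - p) N`` and ``dN/dt = N k (E/N - e_set)``.
        Integration is adaptive explicit Runge-Kutta (rtol 1e-8),
        restarted at every feeding-interval edge so the discontinuous
        forcing never crosses a step. If ``N`` hits ``n_floor`` during
        starvation the trajectory is truncated and flagged.
        """
        if t_grid is None:
            if t_end is None:
                raise EnergyModelError("provide t_grid or t_end")
            t_grid = np.linspace(0.0, float(t_end), 201)
        t_grid = np.asarray(t_grid, dtype=float)
        if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
            raise EnergyModelError("t_grid must be strictly increasing")
        if N0 <= 0:
            raise EnergyModelError("N0 must be > 0")
        if self.paradigm == 1:
            if E0 is None:
                raise EnergyModelError("paradigm 1 requires E0")
        elif E0 is not None:
            raise EnergyModelError("E0 is only a free state for paradigm 1")

        t0, t1 = float(t_grid[0]), float(t_grid[-1])
        edges = self.__schedule_edges(schedule, t0, t1)

        if self.paradigm == 1:
            y = np.array([N0, float(E0), 0.0])  # (N, E, Q)
        else:
            y = np.array([N0, 0.0])  # (N, Q)

        times_out: list[np.ndarray] = []
        states_out: list[np.ndarray] = []
        fed_out: list[np.ndarray] = []
        truncated = False

        def hit_floor(t, s, *args):
            return s[0] - n_floor
        hit_floor.terminal = True
        hit_floor.direction = -1

        for a, b in zip(edges[:-1], edges[1:]):
            fed = schedule.fed(0.5 * (a + b))
            seg_mask = (t_grid >= a) & (t_grid <= b)
            seg_t = np.unique(np.concatenate([[a], t_grid[seg_mask], [b]]))
            sol = solve_ivp(self.__rhs, (a, b), y, t_eval=seg_t,
                            args=(fed,), method="RK45", rtol=_RTOL,
                            atol=self.__atol(N0, E0), events=hit_floor,
                            max_step=(b - a))
            keep = np.isin(sol.t, t_grid[seg_mask])
            times_out.append(sol.t[keep])
            states_out.append(sol.y[:, keep])
            fed_out.append(np.full(int(keep.sum()), fed))
            if sol.status == 1:  # floor event
                truncated = True
                break
            y = sol.y[:, -1]

        times = np.concatenate(times_out)
        states = np.hstack(states_out)
        fed_arr = np.concatenate(fed_out)
        # grid points shared by two segments appear once per segment; dedupe
        times, idx = np.unique(times, return_index=True)
        states = states[:, idx]
        fed_arr = fed_arr[idx]

        N = states[0]
        Q = states[-1]
        if self.paradigm == 1:
            E = states[1]
        else:
            E = self.energy_of_cells(N)
        return Trajectory(times=times, N=N, E=E, fed=fed_arr,
                          paradigm=self.paradigm, net_input=Q,
                          truncated=truncated)

    # internals --------------------------------------------------------------
    def __schedule_edges(self, schedule, t0, t1):
        return schedule.breakpoints(t0, t1)

    def __atol(self, N0, E0):
        e_scale = {1: (E0 or 1.0), 2: self.epsilon * N0,
                   3: self.e_ref * N0}[self.paradigm]
        if self.paradigm == 1:
            return np.array([1e-8 * N0, 1e-8 * e_scale, 1e-10 * e_scale])
        return np.array([1e-8 * N0, 1e-10 * e_scale])

    def __rhs(self, t, y, fed):
        N = y[0]
        net = (self.j * (1.0 if fed else 0.0) - self.p) * PW_TO_J_PER_DAY * N
        if self.paradigm == 1:
            E = y[1]
            dN = N * self.k * (E / N - self.e_set)
            return (dN, net, net)
        rate = self.growth_rate(N, fed=fed)
        return (N * rate, net)


@dataclass(frozen=True)
class ScalingPrediction:
    """Predicted scaling exponents of per-cell quantities versus N."""

    paradigm: int
    e_per_n: float | None
    p_per_n: float
    j_per_n: float
    note: str = ""

    def to_dict(self) -> dict:
        return {"paradigm": self.paradigm, "E_per_N": self.e_per_n,
                "P_per_N": self.p_per_n, "J_per_N": self.j_per_n,
                "note": self.note}


# ---------------------------------------------------------------------------
# Paradigm fitting to measured growth/degrowth rates
# ---------------------------------------------------------------------------

_MIN_LOG_SIGMA = 0.05  # floor on the per-point ln|rate| noise scale


def _split_points(points):
    """Extract (lnN, ln|rate|, history_days, ln-variance) from RatePoints."""
    lnN = np.array([math.log(pt.n_mid) for pt in points])
    r = np.array([pt.rate_pct_per_day for pt in points])
    if np.any(r == 0):
        raise EnergyModelError("rate points with rate exactly 0 cannot enter "
                               "a log-space fit")
    lnr = np.log(np.abs(r))
    hist = np.array([7.0 * (pt.history_weeks if pt.history_weeks is not None
                            else 0.0) for pt in points])
    ses = [getattr(pt, "rate_se_pct_per_day", None) for pt in points]
    se = (None if any(s is None for s in ses)
          else np.asarray(ses, dtype=float))
    return lnN, lnr, hist, se


@dataclass(frozen=True)
class ParadigmFitResults:
    """Result of fitting one control paradigm to rate data.

    ``rss`` is the residual sum of squares in ln|rate| space (equal
    point weights), the quantity used for paradigm ranking; ``aic``
    (= n ln(rss/n) + 2k) is reported alongside as a convenience.
    """

    paradigm: int
    params: dict
    rss: float
    aic: float
    n: int
    n_params: int
    converged: bool = True

    def to_dict(self) -> dict:
        return {"paradigm": self.paradigm, "params": dict(self.params),
                "rss": self.rss, "aic": self.aic, "n": self.n,
                "n_params": self.n_params, "converged": self.converged}

    def to_energy_model(self, p: float = 1.0) -> EnergyBalanceModel:
        """Convert a paradigm-3 fit into a parameterised model.

        The degrowth amplitude at N_ref identifies ``e_ref`` given the
        per-cell metabolic rate ``p`` (pW); the growth/degrowth
        amplitude ratio identifies ``(j - p)/p``.
        """
        if self.paradigm != 3:
            raise EnergyModelError("only paradigm-3 fits map onto a closed "
                                   "energy model here")
        c = self.params["c"]
        n_ref = self.params["n_ref"]
        amp_d = math.exp(self.params["ln_amp_degrowth"])  # %/day at N_ref
        e_ref = 100.0 * p * PW_TO_J_PER_DAY / ((1.0 + c) * amp_d)
        j = p
        if "ln_amp_growth" in self.params:
            ratio = math.exp(self.params["ln_amp_growth"]) / amp_d  # (j-p)/p
            j = p * (1.0 + ratio)
        return EnergyBalanceModel.allometric(j=j, p=p, c=c, e_ref=e_ref,
                                             n_ref=n_ref)

    def summary(self) -> str:
        names = {1: "dynamic reserve", 2: "isometric", 3: "allometric"}
        lines = [f"Paradigm {self.paradigm} ({names[self.paradigm]}) rate fit",
                 "=" * 40,
                 f"n points   {self.n}",
                 f"k params   {self.n_params}",
                 f"RSS        {self.rss:.5g}",
                 f"AIC        {self.aic:.5g}"]
        for k, v in self.params.items():
            lines.append(f"  {k:<18}{v: .5g}")
        return "\n".join(lines)


class ParadigmRateModel:
    """Fit competing control paradigms to extracted growth/degrowth rates.

    Parameters
    ----------
    growth_points, degrowth_points : sequences of RatePoint
        Windowed rates (``%`` change in cell number per day); growth
        points must be positive, degrowth points negative.

    All paradigms are fitted by least squares in ``ln |rate|`` space so
    their residual sums of squares are directly comparable. When the
    points carry per-window slope standard errors (as
    :func:`planergy.rates.windowed_rates` provides), every paradigm uses
    the same inverse-variance weights ``1 / sd(ln|rate|)^2``: a window
    whose rate is indistinguishable from zero has enormous log-space
    variance and correspondingly negligible weight, rather than acting
    as an unbounded-leverage outlier. The log-space noise scale of each
    point is ``se_i / rate_hat_i`` with ``rate_hat`` taken from a
    preliminary equal-weight fit — weighting by the *observed* rate
    would overweight upward noise and bias the slope. Without SEs all
    points weigh equally (the correct special case when rate noise is a
    constant multiplicative CV). Weights are normalised to mean 1 so
    RSS values remain on the per-point scale:

    * paradigm 3 shares one allometry exponent ``c`` between regimes
      with separate amplitudes (growth driven by ``j - p``, degrowth by
      ``p``);
    * paradigm 2 predicts one size-independent rate per regime;
    * paradigm 1 predicts a degrowth rate that depends only on the
      starvation history (the per-cell reserve ODE does not involve N)
      plus a constant growth amplitude; its reserve parameters are found
      numerically.
    """

    def __init__(self, growth_points, degrowth_points, n_ref: float = 1e6):
        if len(growth_points) == 0 or len(degrowth_points) == 0:
            raise EnergyModelError("both growth and degrowth points required")
        for pt in growth_points:
            if pt.rate_pct_per_day <= 0:
                raise EnergyModelError("growth points must have rate > 0")
        for pt in degrowth_points:
            if pt.rate_pct_per_day >= 0:
                raise EnergyModelError("degrowth points must have rate < 0")
        self.n_ref = float(n_ref)
        (self.g_lnN, self.g_lnr, self.g_hist,
         g_se) = _split_points(growth_points)
        (self.d_lnN, self.d_lnr, self.d_hist,
         d_se) = _split_points(degrowth_points)
        allN = np.concatenate([self.g_lnN, self.d_lnN])
        if np.ptp(allN) < 1e-12:
            raise EnergyModelError("degenerate data: all points at one size")
        self.n = self.g_lnN.size + self.d_lnN.size
        self.g_w = np.ones(self.g_lnN.size)
        self.d_w = np.ones(self.d_lnN.size)
        if g_se is not None and d_se is not None:
            # predicted rates from a preliminary equal-weight fit set the
            # per-point log-noise scale se_i / rate_hat_i
            _, pred, _ = self.__allometric_lstsq()
            se = np.concatenate([g_se, d_se])
            sigma = np.maximum(se / np.exp(pred), _MIN_LOG_SIGMA)
            w = 1.0 / sigma ** 2
            w *= self.n / w.sum()  # mean-1 normalisation
            self.g_w = w[:self.g_lnN.size]
            self.d_w = w[self.g_lnN.size:]

    # ------------------------------------------------------------------
    def fit(self, paradigm: int, p_fixed: float | None = None
            ) -> ParadigmFitResults:
        if paradigm == 3:
            return self.__fit_allometric()
        if paradigm == 2:
            return self.__fit_isometric()
        if paradigm == 1:
            return self.__fit_dynamic(p_fixed if p_fixed is not None else 1.0)
        raise EnergyModelError(f"unknown paradigm {paradigm}")

    def fit_all(self, p_fixed: float | None = None) -> list[ParadigmFitResults]:
        """Fit every paradigm and return results ranked by RSS."""
        res = [self.fit(k, p_fixed=p_fixed) for k in (1, 2, 3)]
        return sorted(res, key=lambda r: r.rss)

    # ------------------------------------------------------------------
    def __aic(self, rss, k):
        return self.n * math.log(max(rss, 1e-300) / self.n) + 2 * k

    def __allometric_lstsq(self, weights=None):
        """Weighted shared-slope fit: ln|r| = amp_regime - c ln(N/N_ref)."""
        x_g = self.g_lnN - math.log(self.n_ref)
        x_d = self.d_lnN - math.log(self.n_ref)
        X = np.zeros((self.n, 3))
        X[:x_g.size, 0] = 1.0
        X[x_g.size:, 1] = 1.0
        X[:, 2] = -np.concatenate([x_g, x_d])
        yv = np.concatenate([self.g_lnr, self.d_lnr])
        w = (np.ones(self.n) if weights is None else weights)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], yv * sw, rcond=None)
        pred = X @ beta
        rss = float(np.sum(w * (yv - pred) ** 2))
        return beta, pred, rss

    def __fit_allometric(self):
        w = np.concatenate([self.g_w, self.d_w])
        beta, _, rss = self.__allometric_lstsq(w)
        params = {"ln_amp_growth": float(beta[0]),
                  "ln_amp_degrowth": float(beta[1]),
                  "c": float(beta[2]),
                  "n_ref": self.n_ref}
        return ParadigmFitResults(3, params, rss, self.__aic(rss, 3),
                                  self.n, 3)

    def __fit_isometric(self):
        mg = float(np.average(self.g_lnr, weights=self.g_w))
        md = float(np.average(self.d_lnr, weights=self.d_w))
        rss = float(np.sum(self.g_w * (self.g_lnr - mg) ** 2)
                    + np.sum(self.d_w * (self.d_lnr - md) ** 2))
        params = {"ln_amp_growth": mg, "ln_amp_degrowth": md}
        return ParadigmFitResults(2, params, rss, self.__aic(rss, 2),
                                  self.n, 2)

    def __fit_dynamic(self, p_pw: float):
        """Fit (k, e_set, e0) of the reserve ODE plus a growth constant.

        During starvation the per-cell reserve obeys
        ``de/dt = -p~ - e * k (e - e_set)`` (``p~`` in J/day); the
        predicted degrowth magnitude at starvation time ``t`` is
        ``k (e_set - e(t))`` — a function of history alone.
        """
        p_tilde = p_pw * PW_TO_J_PER_DAY
        t_max = float(np.max(self.d_hist)) if self.d_hist.size else 1.0
        t_max = max(t_max, 1.0)

        def degrowth_lnrate(theta):
            ln_k, ln_eset, ln_e0 = theta
            k, e_set, e0 = math.exp(ln_k), math.exp(ln_eset), math.exp(ln_e0)
            # dense RK4 on the scalar reserve ODE
            n_steps = max(int(t_max * 8), 16)
            h = t_max / n_steps
            ts = np.linspace(0.0, t_max, n_steps + 1)
            es = np.empty(n_steps + 1)
            es[0] = e0
            f = lambda e: -p_tilde - e * k * (e - e_set)
            e = e0
            for i in range(n_steps):
                k1 = f(e)
                k2 = f(e + 0.5 * h * k1)
                k3 = f(e + 0.5 * h * k2)
                k4 = f(e + h * k3)
                e = e + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
                e = max(e, 1e-300)
                es[i + 1] = e
            e_at = np.interp(self.d_hist, ts, es)
            mag = 100.0 * k * (e_set - e_at)  # %/day
            return np.log(np.maximum(mag, 1e-12))

        mean_d = float(np.average(self.d_lnr, weights=self.d_w))
        sw_d = np.sqrt(self.d_w)

        def residuals(theta):
            return (degrowth_lnrate(theta) - self.d_lnr) * sw_d

        # initial guesses: steady-state degrowth magnitude near the data mean
        mag0 = math.exp(mean_d) / 100.0  # 1/day
        best = None
        for e_set0 in (1e-6, 1e-5):
            k0 = mag0 / (0.3 * e_set0)
            x0 = np.log([k0, e_set0, 0.9 * e_set0])
            try:
                sol = least_squares(residuals, x0, method="lm", max_nfev=400)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            # fall back to the history-free constant predictor
            rss_d = float(np.sum(self.d_w * (self.d_lnr - mean_d) ** 2))
            params = {"ln_amp_degrowth": mean_d, "p_pw": p_pw,
                      "k": float("nan"), "e_set": float("nan"),
                      "e0": float("nan")}
            converged = False
        else:
            rss_d = float(2.0 * best.cost)
            k_, eset_, e0_ = np.exp(best.x)
            params = {"k": float(k_), "e_set": float(eset_),
                      "e0": float(e0_), "p_pw": p_pw}
            converged = bool(best.success)
        mg = float(np.average(self.g_lnr, weights=self.g_w))
        rss = rss_d + float(np.sum(self.g_w * (self.g_lnr - mg) ** 2))
        params["ln_amp_growth"] = mg
        return ParadigmFitResults(1, params, rss, self.__aic(rss, 4),
                                  self.n, 4, converged=converged)


def fit_paradigm(growth_points, degrowth_points, paradigm: int,
                 p_fixed: float | None = None,
                 n_ref: float = 1e6) -> ParadigmFitResults:
    """Fit one control paradigm to windowed rate points (see
    :class:`ParadigmRateModel`)."""
    return ParadigmRateModel(growth_points, degrowth_points,
                             n_ref=n_ref).fit(paradigm, p_fixed=p_fixed)


def compare_paradigms(growth_points, degrowth_points,
                      p_fixed: float | None = None,
                      n_ref: float = 1e6) -> list[ParadigmFitResults]:
    """Fit all three paradigms; return results sorted best-first by RSS."""
    return ParadigmRateModel(growth_points, degrowth_points,
                             n_ref=n_ref).fit_all(p_fixed=p_fixed)


# ---------------------------------------------------------------------------
# Physiological-energy prediction and assimilation ratio
# ---------------------------------------------------------------------------

def predict_energy_per_cell(degrowth_law: PowerLawResults,
                            c: float | None = None,
                            p: float = 1.0) -> PowerLawResults:
    """Predict the reserve per cell ``e(N)`` from the degrowth-rate law.

    Under the allometric paradigm, starvation gives
    ``(1/N) dN/dt = -p~ / (e (1+c))``, hence
    ``e(N) = p~ / ((1+c) |rate(N)|)`` with the rate as a fraction per
    day and ``p~ = p`` (pW) converted to J/day. ``degrowth_law`` is the
    fitted power law of |rate| (%/day) versus N; its exponent is ``-c``
    (pass ``c`` to override). Returns the predicted ``e(N)`` as a power
    law in J/cell with propagated uncertainty.
    """
    if p <= 0:
        raise EnergyModelError("p must be > 0")
    if c is None:
        c = -degrowth_law.exponent
    if c <= -1:
        raise EnergyModelError("require c > -1")
    scale = math.log(100.0 * p * PW_TO_J_PER_DAY / (1.0 + c))
    return PowerLawResults(
        exponent=-degrowth_law.exponent,
        log_prefactor=scale - degrowth_law.log_prefactor,
        se_exponent=degrowth_law.se_exponent,
        se_log_prefactor=degrowth_law.se_log_prefactor,
        cov_exp_lna=degrowth_law.cov_exp_lna,
        n=degrowth_law.n,
        method=DERIVED,
        derivation=f"energy_per_cell({degrowth_law.derivation})",
    )


def assimilation_ratio(measured_en: PowerLawResults,
                       predicted_e: PowerLawResults | Callable,
                       n_range: tuple[float, float],
                       n_grid: int = 50) -> dict:
    """Gross/physiological energy ratio over a log-spaced size grid.

    ``measured_en`` is the fitted gross E/N versus N law (bomb
    calorimetry); ``predicted_e`` the physiological e(N) prediction.
    Returns the geometric-mean ratio and its (min, max) range across the
    grid — near-constancy of the range is the check that the two laws
    differ only by a factor.
    """
    lo, hi = n_range
    if not (0 < lo < hi):
        raise EnergyModelError("need a non-degenerate positive N range")
    grid = np.geomspace(lo, hi, n_grid)
    meas = measured_en.predict(grid) if hasattr(measured_en, "predict") \
        else np.asarray([measured_en(x) for x in grid])
    pred = predicted_e.predict(grid) if hasattr(predicted_e, "predict") \
        else np.asarray([predicted_e(x) for x in grid])
    if np.any(pred <= 0) or np.any(meas <= 0):
        raise EnergyModelError("non-positive energy values on the grid")
    ratio = meas / pred
    return {
        "geometric_mean": float(np.exp(np.mean(np.log(ratio)))),
        "range": (float(np.min(ratio)), float(np.max(ratio))),
        "n_range": (float(lo), float(hi)),
    }
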