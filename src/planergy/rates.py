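"""Size-resolved growth/degrowth rates from individual animal traces.

A trace is a time series of animal size (plan area or cell count). The
instantaneous relative rate of change is estimated per overlapping time
window as the slope of ``ln N`` versus time (an exponential fit),
expressed as % change in cell number per day. Each window yields one
``RatePoint`` at the geometric-mean size of its endpoints — the data
the control-paradigm fits consume. Plan-area traces are converted to
cell numbers through the cell-number/area scaling law, under which a
relative area rate maps to ``b`` times the cell-number rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .powerlaw import PowerLawModel, PowerLawResults, PowerLawDomainError

__all__ = ["Trace", "RatePoint", "area_to_cells", "windowed_rates",
           "fit_rate_size_law", "history_dependence",
           "GROWTH", "DEGROWTH"]

GROWTH = "growth"
DEGROWTH = "degrowth"


class RateError(ValueError):
    pass


@dataclass(frozen=True)
class Trace:
    """One animal's size time course.

    ``sizes`` may be plan areas (mm^2) or cell counts; ``starved_weeks``
    is the time since the last feeding at ``times[0]`` (degrowth traces).
    """

    animal_id: str
    times: np.ndarray
    sizes: np.ndarray
    regime: str
    feeding_times: tuple[float, ...] = ()
    starved_weeks: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "sizes", np.asarray(self.sizes, dtype=float))
        if self.regime not in (GROWTH, DEGROWTH):
            raise RateError(f"regime must be growth/degrowth, got {self.regime!r}")
        if self.times.size != self.sizes.size or self.times.size < 4:
            raise RateError("a trace needs >= 4 (time, size) points")
        if np.any(np.diff(self.times) <= 0):
            raise RateError("trace times must be strictly increasing")
        if np.any(self.sizes <= 0):
            raise RateError("trace sizes must be > 0")

    @classmethod
    def from_frame(cls, df, animal_id: str | None = None) -> list["Trace"]:
        """Build traces from a long-format traces table (one per animal)."""
        out = []
        for aid, grp in df.groupby("animal_id", sort=False):
            if animal_id is not None and aid != animal_id:
                continue
            regime = GROWTH
            if "regime" in grp.columns and grp["regime"].notna().any():
                regime = str(grp["regime"].dropna().iloc[0])
            sw = 0.0
            if "starved_weeks" in grp.columns and grp["starved_weeks"].notna().any():
                sw = float(grp["starved_weeks"].dropna().iloc[0])
            feed = ()
            if "fed" in grp.columns:
                fed = grp["fed"].fillna(0).to_numpy(dtype=float) > 0
                feed = tuple(grp["time_days"].to_numpy(dtype=float)[fed])
            out.append(cls(animal_id=str(aid),
                           times=grp["time_days"].to_numpy(dtype=float),
                           sizes=grp["plan_area_mm2"].to_numpy(dtype=float),
                           regime=regime, feeding_times=feed,
                           starved_weeks=sw))
        return out


@dataclass(frozen=True)
class RatePoint:
    """A (size, rate) pair extracted from one trace window.

    ``n_mid`` is the geometric mean of the window's first and last cell
    number (the log-space midpoint, matching the log-log fits downstream);
    ``history_weeks`` is the starvation history at the window start.
    """

    n_mid: float
    rate_pct_per_day: float
    window: tuple[float, float]
    animal_id: str
    regime: str
    history_weeks: float | None = None
    history_group: str | None = None
    rate_se_pct_per_day: float | None = None


def area_to_cells(area, n_vs_area: PowerLawResults):
    """Convert plan area (mm^2) to organismal cell number via ``N = a A^b``."""
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise PowerLawDomainError("area must be > 0")
    return n_vs_area.predict(area)


def _window_spans(t0: float, t1: float, n_windows: int, overlap: float):
    """Equal-length windows covering [t0, t1] with fractional overlap."""
    if n_windows < 1:
        raise RateError("n_windows must be >= 1")
    if not 0.0 <= overlap < 1.0:
        raise RateError("overlap_fraction must be in [0, 1)")
    span = t1 - t0
    length = span / (1.0 + (n_windows - 1) * (1.0 - overlap))
    starts = t0 + np.arange(n_windows) * length * (1.0 - overlap)
    return [(float(s), float(s + length)) for s in starts]


def windowed_rates(trace: Trace, n_windows: int | None = None,
                   overlap_fraction: float = 0.5,
                   n_vs_area: PowerLawResults | None = None,
                   min_points: int = 3) -> list[RatePoint]:
    """Extract per-window rates (% change in cell number per day).

    By default growth traces are split into 2 and degrowth traces into 3
    overlapping windows (50% overlap). Per window the rate is
    ``100 * slope of ln N vs t``; windows retaining fewer than
    ``min_points`` points are skipped with a warning. If ``n_vs_area``
    is given the trace sizes are treated as plan areas: ``n_mid`` is
    converted through the law and the rate multiplied by its exponent
    (since ``ln N = ln a + b ln A``).
    """
    if n_windows is None:
        n_windows = 2 if trace.regime == GROWTH else 3
    sizes = trace.sizes
    ln_s = np.log(sizes)
    points: list[RatePoint] = []
    for (t_lo, t_hi) in _window_spans(trace.times[0], trace.times[-1],
                                      n_windows, overlap_fraction):
        mask = (trace.times >= t_lo - 1e-12) & (trace.times <= t_hi + 1e-12)
        if mask.sum() < min_points:
            warnings.warn(f"trace {trace.animal_id}: window ({t_lo:.3g}, "
                          f"{t_hi:.3g}) has < {min_points} points; skipped")
            continue
        tw = trace.times[mask]
        lw = ln_s[mask]
        slope, intercept = np.polyfit(tw, lw, 1)  # 1/day, in size units
        # standard error of the window slope, from its own residuals
        resid = lw - (slope * tw + intercept)
        dof = tw.size - 2
        stt = float(np.sum((tw - tw.mean()) ** 2))
        se_slope = (math.sqrt(float(np.sum(resid ** 2)) / dof / stt)
                    if dof > 0 else 0.0)
        s_mid = math.sqrt(sizes[mask][0] * sizes[mask][-1])
        if n_vs_area is not None:
            rate = 100.0 * slope * n_vs_area.exponent
            rate_se = 100.0 * se_slope * n_vs_area.exponent
            n_mid = float(area_to_cells(s_mid, n_vs_area))
        else:
            rate = 100.0 * slope
            rate_se = 100.0 * se_slope
            n_mid = s_mid
        hist = None
        if trace.regime == DEGROWTH:
            hist = trace.starved_weeks + (t_lo - trace.times[0]) / 7.0
        points.append(RatePoint(
            n_mid=n_mid, rate_pct_per_day=float(rate), window=(t_lo, t_hi),
            animal_id=trace.animal_id, regime=trace.regime,
            history_weeks=hist,
            history_group=(f"{trace.starved_weeks:g}w"
                           if trace.regime == DEGROWTH else None),
            rate_se_pct_per_day=float(rate_se)))
    return points


def fit_rate_size_law(points, method: str = "robust_bisquare"
                      ) -> PowerLawResults:
    """Fit ``|rate| = a * N^b`` to rate points of one sign.

    Under the allometric control paradigm the exponent is ``-c``. Mixed
    signs are rejected: growth and degrowth regimes must be fitted
    separately.
    """
    if len(points) < 3:
        raise RateError("need >= 3 rate points")
    r = np.array([pt.rate_pct_per_day for pt in points])
    if np.any(r == 0) or (np.any(r > 0) and np.any(r < 0)):
        raise RateError("rate points must share one sign; split the "
                        "growth and degrowth regimes before fitting")
    n = np.array([pt.n_mid for pt in points])
    return PowerLawModel(n, np.abs(r)).fit(method=method)


def history_dependence(points, n_permutations: int = 1000,
                       seed: int = 0, method: str = "robust_bisquare") -> dict:
    """Test whether degrowth rates depend on feeding history beyond size.

    Fits the size law to all points, takes residuals of ``ln |rate|``,
    and compares their means between feeding-history groups. The spread
    statistic is the difference of group means (two groups) or the
    max-min spread (more); significance comes from a seeded
    label-shuffling permutation null. A size-controlled spread near 0
    with p > 0.05 is the signature of a purely size-dependent (e.g.
    allometric-reserve) control; a reserve-dependent control leaves a
    history signal.
    """
    groups = [pt.history_group for pt in points]
    if any(g is None for g in groups):
        raise RateError("all points need a history_group annotation")
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise RateError("need >= 2 feeding-history groups")
    law = fit_rate_size_law(points, method=method)
    lnr = np.log(np.abs([pt.rate_pct_per_day for pt in points]))
    resid = lnr - np.log(law.predict(np.array([pt.n_mid for pt in points])))
    garr = np.array(groups)

    def spread(res, lab):
        means = np.array([res[lab == g].mean() for g in labels])
        if len(labels) == 2:
            return means[0] - means[1]
        return means.max() - means.min()

    observed = float(spread(resid, garr))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_permutations)):
        perm = rng.permutation(garr)
        if abs(spread(resid, perm)) >= abs(observed) - 1e-15:
            count += 1
    pval = (count + 1) / (n_permutations + 1)
    return {"statistic": observed, "p_value": float(pval),
            "groups": labels, "n_permutations": int(n_permutations),
            "size_law_exponent": law.exponent}
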