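"""Co-culture design math: doubling times and seeding-ratio calculations.

Two populations growing exponentially at different rates drift in composition
over the assay window; the seeding ratio is chosen so that the endpoint mix
still contains enough of both.  The pilot screen seeds 1500 hepatocytes and
800 HCC cells per well, a 65:35 premix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass
class GrowthEstimate:
    """Doubling time fitted from a growth curve (log2 count vs time)."""

    doubling_time_h: float
    se_h: float
    r_squared: float
    n_points: int

    def summary(self) -> str:
        return (f"doubling time: {self.doubling_time_h:.3g} h "
                f"(SE {self.se_h:.2g} h, R^2 {self.r_squared:.4f}, "
                f"n={self.n_points})")


class GrowthCurveModel:
    """Exponential growth model N(t) = N0 * 2**(t/Td) fitted by regression.

    Least squares on log2(count) vs time gives slope = 1/Td; scale-invariant
    in counts (a common factor only shifts the intercept).
    """

    def __init__(self, times_h: Sequence[float], counts: Sequence[float]):
        t = np.asarray(times_h, dtype=float)
        n = np.asarray(counts, dtype=float)
        if t.size != n.size:
            raise ValueError("times and counts must have equal length")
        if t.size < 3:
            raise ValueError("need >= 3 time points")
        if (n <= 0).any():
            raise ValueError("counts must be > 0")
        self.times_h = t
        self.counts = n

    def fit(self) -> GrowthEstimate:
        res = stats.linregress(self.times_h, np.log2(self.counts))
        if res.slope <= 0:
            raise ValueError("no growth: fitted slope <= 0")
        td = 1.0 / res.slope
        # Td = 1/s, so SE(Td) = SE(s)/s^2 by the delta method
        se = res.stderr / res.slope**2 if res.stderr is not None else float("nan")
        return GrowthEstimate(doubling_time_h=float(td), se_h=float(se),
                              r_squared=float(res.rvalue**2),
                              n_points=int(self.times_h.size))


def estimate_doubling_time(times_h: Sequence[float],
                           counts: Sequence[float]) -> GrowthEstimate:
    """Fit a doubling time from (time, count) growth-curve data."""
    return GrowthCurveModel(times_h, counts).fit()


def predict_final_composition(seed_counts: Dict[str, float],
                              doubling_times_h: Dict[str, float],
                              duration_h: float) -> Dict[str, float]:
    """Endpoint population fractions from seeds and doubling times.

    N_i(T) = n_i * 2**(T/Td_i), normalized to sum to 1.
    """
    if duration_h < 0:
        raise ValueError("duration must be >= 0")
    grown = {}
    for name, n0 in seed_counts.items():
        td = doubling_times_h[name]
        if n0 <= 0 or td <= 0:
            raise ValueError("seed counts and doubling times must be > 0")
        grown[name] = n0 * 2.0 ** (duration_h / td)
    total = sum(grown.values())
    return {name: g / total for name, g in grown.items()}


def design_seeding_ratio(doubling_times_h: Dict[str, float],
                         duration_h: float,
                         target_final_fraction: Dict[str, float]
                         ) -> Dict[str, float]:
    """Seeding fractions that reach a target endpoint composition.

    Closed-form inverse of :func:`predict_final_composition`: divide each
    target fraction by that population's growth factor and renormalize.
    Round-trips with the forward prediction to numerical precision.
    """
    fracs = np.array(list(target_final_fraction.values()), dtype=float)
    if (fracs <= 0).any() or (fracs >= 1).any():
        raise ValueError("target fractions must be in (0, 1)")
    if not np.isclose(fracs.sum(), 1.0):
        raise ValueError("target fractions must sum to 1")
    raw = {}
    for name, f in target_final_fraction.items():
        td = doubling_times_h[name]
        if td <= 0:
            raise ValueError("doubling times must be > 0")
        raw[name] = f / 2.0 ** (duration_h / td)
    total = sum(raw.values())
    return {name: r / total for name, r in raw.items()}
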