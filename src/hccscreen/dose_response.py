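"""Sigmoidal (4PL) dose-response fitting, IC50 and the enhancement ratio.

The hit-confirmation step fits viability data to the four-parameter logistic

    V(c) = bottom + (top - bottom) / (1 + (c / IC50)**hill)

on a log10 dose axis, by constrained least squares with multistart
initialization.  Selectivity between the hepatocyte (reference) and HCC
(target) populations is summarized by the enhancement ratio
IC50ER = IC50_ref / IC50_target; values > 1 indicate HCC-selective toxicity.

The model/results split follows the statsmodels convention:
``FourPLModel(doses, responses).fit()`` returns a :class:`DoseResponseFit`
carrying estimates, standard errors and diagnostics, with ``summary()`` and
``plot()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FourPLModel", "DoseResponseFit", "SelectivityResult",
    "fit_dose_response", "compute_ic50er", "compare_fits",
]

_ZERO_DOSE_DECADES = 3.0  # pseudo-position of the zero-dose control


def four_pl(c, top, bottom, ic50, hill):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        frac = np.where(c > 0, (c / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + frac)


@dataclass
class DoseResponseFit:
    """Results of a constrained 4PL fit."""

    top: float
    bottom: float
    ic50: float
    hill: float
    se: Dict[str, float]
    rss: float
    converged: bool
    n_points: int
    extrapolated: bool = False
    message: str = ""
    model: Optional["FourPLModel"] = None

    def params(self) -> Dict[str, float]:
        return {"top": self.top, "bottom": self.bottom,
                "ic50": self.ic50, "hill": self.hill}

    def predict(self, doses) -> np.ndarray:
        return four_pl(doses, self.top, self.bottom, self.ic50, self.hill)

    def summary(self) -> str:
        lines = ["4PL dose-response fit",
                 f"  n points:   {self.n_points}",
                 f"  converged:  {self.converged}"]
        if self.converged:
            for k, v in self.params().items():
                se = self.se.get(k, float("nan"))
                unit = " M" if k == "ic50" else (" %" if k in ("top", "bottom") else "")
                lines.append(f"  {k:<8s} {v:.6g}{unit}  (SE {se:.3g})")
            lines.append(f"  IC50:       {self.ic50 * 1e6:.4g} uM"
                         + ("  [extrapolated]" if self.extrapolated else ""))
            lines.append(f"  residual SS: {self.rss:.4g}")
        else:
            lines.append(f"  reason: {self.message}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Fitted curve over the data on a log dose axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            ax.semilogx(np.clip(self.model.doses, self.model._pseudo_zero, None),
                        self.model.responses, "o", label="data")
            grid = np.logspace(np.log10(self.model._pseudo_zero),
                               np.log10(self.model.doses.max()), 200)
            ax.semilogx(grid, self.predict(grid), "-", label="4PL fit")
        ax.set_xlabel("dose (M)")
        ax.set_ylabel("viability (%)")
        ax.legend()
        return ax


class FourPLModel:
    """Constrained 4PL model for one compound/population viability series.

    Parameters
    ----------
    doses_m : molar doses; may include one zero-dose (vehicle) control, which
        anchors the top plateau and is placed 3 decades below the lowest
        nonzero dose on the log axis.
    responses : viability in percent.
    fix_hill : optionally pin the slope (e.g. 1.0 for a fixed-slope fit).
    """

    #: bounds: 0 <= bottom <= top <= 120 (slight stimulation allowed),
    #: hill in (0, 10]
    TOP_MAX = 120.0
    HILL_MAX = 10.0

    def __init__(self, doses_m: Sequence[float], responses: Sequence[float],
                 fix_hill: Optional[float] = None):
        doses = np.asarray(doses_m, dtype=float)
        resp = np.asarray(responses, dtype=float)
        if doses.shape != resp.shape:
            raise ValueError("doses and responses must have equal length")
        if (doses < 0).any():
            raise ValueError("negative doses are not allowed")
        if np.unique(doses).size < 5:
            raise ValueError("need >= 5 distinct doses (including the control)")
        order = np.argsort(doses, kind="stable")
        self.doses = doses[order]
        self.responses = resp[order]
        self.fix_hill = fix_hill
        nonzero = self.doses[self.doses > 0]
        self._pseudo_zero = float(nonzero.min() * 10.0 ** (-_ZERO_DOSE_DECADES))
        self._x = np.log10(np.where(self.doses > 0, self.doses, self._pseudo_zero))

    @classmethod
    def from_table(cls, table: pd.DataFrame, compound: Optional[str] = None,
                   **kw) -> "FourPLModel":
        """Build from a viability table (compound,dose_M,replicate,viability_pct)."""
        sub = table if compound is None else table[table["compound"] == compound]
        if sub.empty:
            raise ValueError(f"no rows for compound {compound!r}")
        return cls(sub["dose_M"].to_numpy(), sub["viability_pct"].to_numpy(), **kw)

    # -- fitting ----------------------------------------------------------

    def _residuals(self, theta):
        top, bottom, log_ic50, hill = theta
        pred = bottom + (top - bottom) / (1 + 10 ** ((self._x - log_ic50) * hill))
        return pred - self.responses

    def fit(self, n_multistart: int = 5, seed: int = 0) -> DoseResponseFit:
        """Least-squares fit with multistart jitter on log10 IC50.

        Initialization: top/bottom from the extreme responses, IC50 from the
        dose bracketing the half-maximal response, hill = 1; the additional
        starts jitter log10 IC50 by up to +-1 decade; the lowest residual SS
        wins, ties broken by the lower hill slope.
        """
        y = self.responses
        rng_span = float(y.max() - y.min())
        n = y.size
        if rng_span < 10.0:
            return DoseResponseFit(
                top=float(y.mean()), bottom=float(y.mean()), ic50=float("nan"),
                hill=float("nan"), se={}, rss=float(((y - y.mean()) ** 2).sum()),
                converged=False, n_points=n,
                message="response range < 10 percentage points; no signal",
                model=self)
        top0 = min(float(y.max()), self.TOP_MAX)
        bottom0 = max(float(y.min()), 0.0)
        half = (top0 + bottom0) / 2.0
        below = self._x[y <= half]
        log_ic50_0 = float(below.min()) if below.size else float(np.median(self._x))

        lo_x, hi_x = self._x.min() - 1.0, self._x.max() + 1.0
        fix = self.fix_hill
        rng = np.random.default_rng(seed)
        jitters = [0.0] + list(rng.uniform(-1.0, 1.0, size=max(0, n_multistart - 1)))

        best = None
        for j in jitters:
            theta0 = np.array([top0, bottom0,
                               np.clip(log_ic50_0 + j, lo_x, hi_x),
                               1.0 if fix is None else fix])
            lower = [0.0, 0.0, lo_x, 1e-3 if fix is None else fix - 1e-12]
            upper = [self.TOP_MAX, self.TOP_MAX, hi_x,
                     self.HILL_MAX if fix is None else fix + 1e-12]
            theta0 = np.clip(theta0, lower, upper)
            try:
                sol = optimize.least_squares(self._residuals, theta0,
                                             bounds=(lower, upper))
            except Exception:
                continue
            rss = float(2 * sol.cost)
            if (best is None or rss < best[0] - 1e-12
                    or (abs(rss - best[0]) <= 1e-12 and sol.x[3] < best[1].x[3])):
                best = (rss, sol)
        if best is None:
            return DoseResponseFit(top=np.nan, bottom=np.nan, ic50=np.nan,
                                   hill=np.nan, se={}, rss=np.nan,
                                   converged=False, n_points=n,
                                   message="optimizer failed", model=self)
        rss, sol = best
        top, bottom, log_ic50, hill = sol.x
        if bottom > top:
            top, bottom = bottom, top
        ic50 = float(10 ** log_ic50)
        se = self._standard_errors(sol, rss, n)
        nz = self.doses[self.doses > 0]
        extrapolated = not (nz.min() / 100 <= ic50 <= nz.max() * 100)
        return DoseResponseFit(top=float(top), bottom=float(bottom), ic50=ic50,
                               hill=float(hill), se=se, rss=rss, converged=True,
                               n_points=n, extrapolated=extrapolated, model=self)

    def _standard_errors(self, sol, rss: float, n: int) -> Dict[str, float]:
        # Gauss-Newton covariance: s^2 (J'J)^-1; IC50 SE by the delta method
        # from log10 IC50.
        k = 4 if self.fix_hill is None else 3
        dof = max(n - k, 1)
        s2 = rss / dof
        J = sol.jac
        try:
            cov = s2 * np.linalg.pinv(J.T @ J)
            sd = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            sd = np.full(4, np.nan)
        ic50 = 10 ** sol.x[2]
        return {"top": float(sd[0]), "bottom": float(sd[1]),
                "ic50": float(sd[2] * np.log(10) * ic50), "hill": float(sd[3])}


def fit_dose_response(doses_m: Sequence[float], responses: Sequence[float],
                      fix_hill: Optional[float] = None,
                      n_multistart: int = 5) -> DoseResponseFit:
    """Functional wrapper around :class:`FourPLModel`."""
    return FourPLModel(doses_m, responses, fix_hill=fix_hill).fit(n_multistart)


@dataclass
class SelectivityResult:
    """IC50 enhancement ratio between reference and target populations."""

    compound_id: str
    ic50_ref: float  # hepatocyte (Fa2N-4)
    ic50_target: float  # HCC (Huh7)
    ic50er: float


def compute_ic50er(fit_ref: DoseResponseFit, fit_target: DoseResponseFit,
                   compound_id: str = "") -> SelectivityResult:
    """IC50ER = IC50(reference, hepatocyte) / IC50(target, HCC)."""
    if not (fit_ref.converged and fit_target.converged):
        raise ValueError("IC50ER requires two converged fits")
    return SelectivityResult(compound_id=compound_id,
                             ic50_ref=fit_ref.ic50,
                             ic50_target=fit_target.ic50,
                             ic50er=fit_ref.ic50 / fit_target.ic50)


@dataclass
class FitComparison:
    fold_shift: float  # ic50_b / ic50_a
    t_statistic: Optional[float]
    p_value: Optional[float]
    significant: Optional[bool]
    per_replicate_ic50_a: List[float] = field(default_factory=list)
    per_replicate_ic50_b: List[float] = field(default_factory=list)


def _per_replicate_ic50s(table: pd.DataFrame,
                         fix_hill: Optional[float]) -> List[float]:
    out = []
    for _, sub in table.groupby("replicate"):
        f = FourPLModel(sub["dose_M"].to_numpy(),
                        sub["viability_pct"].to_numpy(),
                        fix_hill=fix_hill).fit()
        if f.converged:
            out.append(f.ic50)
    return out


def compare_fits(fit_a: DoseResponseFit, fit_b: DoseResponseFit,
                 table_a: pd.DataFrame, table_b: pd.DataFrame,
                 fix_hill: Optional[float] = None,
                 alpha: float = 0.05) -> FitComparison:
    """IC50 fold-shift between two conditions with a t-test on replicates.

    The fold shift is ic50_b / ic50_a from the pooled fits; the two-sample
    Student's t-test runs on per-replicate log10 IC50s (skipped, with the
    shift still reported, when either condition has < 3 replicates).
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("compare_fits requires two converged fits")
    fold = fit_b.ic50 / fit_a.ic50
    ic_a = _per_replicate_ic50s(table_a, fix_hill)
    ic_b = _per_replicate_ic50s(table_b, fix_hill)
    if len(ic_a) < 3 or len(ic_b) < 3:
        return FitComparison(fold_shift=fold, t_statistic=None, p_value=None,
                             significant=None, per_replicate_ic50_a=ic_a,
                             per_replicate_ic50_b=ic_b)
    la, lb = np.log10(ic_a), np.log10(ic_b)
    if np.allclose(la.std(), 0) and np.allclose(lb.std(), 0) \
            and np.allclose(la.mean(), lb.mean()):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(la, lb, equal_var=True)
    return FitComparison(fold_shift=fold, t_statistic=float(t),
                         p_value=float(p), significant=bool(p < alpha),
                         per_replicate_ic50_a=ic_a, per_replicate_ic50_b=ic_b)


def fit_table(table: pd.DataFrame, fix_hill: Optional[float] = None
              ) -> pd.DataFrame:
    """Fit every compound in a viability table; one row per compound."""
    rows = []
    for comp, sub in table.groupby("compound"):
        f = FourPLModel.from_table(sub, fix_hill=fix_hill).fit()
        rows.append({
            "compound": comp, "top": f.top, "bottom": f.bottom,
            "ic50_M": f.ic50, "hill": f.hill,
            "se_top": f.se.get("top", np.nan),
            "se_bottom": f.se.get("bottom", np.nan),
            "se_ic50_M": f.se.get("ic50", np.nan),
            "se_hill": f.se.get("hill", np.nan),
            "rss": f.rss, "converged": f.converged,
            "extrapolated": f.extrapolated, "n_points": f.n_points,
        })
    return pd.DataFrame(rows)
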