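"""One-site Hill concentration-response fitting.

Activation curves (e.g. ACh-evoked currents in oocytes expressing nAChRs)
are fit as

    r(c) = top · cⁿ / (cⁿ + EC50ⁿ)

with the bottom fixed at 0 and ``top`` free; inhibition curves (nicotine
suppression of evoked dopamine release, baseline-normalized) as

    r(c) = 1 − (1 − floor) · cⁿ / (cⁿ + IC50ⁿ)

with top fixed at 1 and ``floor`` fixed at 0 unless overridden.  Fitting is
done in log-concentration space, where the Hill function is a logistic —
numerically well behaved for any Hill slope — with multi-start over the
tested doses to avoid local minima.  EC50 confidence intervals come from a
case-resampling bootstrap over replicates (the original report's CI method
being unstated, a percentile bootstrap is the default; see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit


class NormalizationError(ValueError):
    """A replicate with a non-positive maximum cannot be self-normalized."""


class FitError(RuntimeError):
    """Hill fit failed to converge; carries the best attempt."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class BootstrapError(ValueError):
    """Too few replicates to resample."""


@dataclass
class DoseResponseSeries:
    """Long-format replicate observations of normalized response vs dose."""

    concentrations: np.ndarray  # molar, per observation
    responses: np.ndarray  # normalized, per observation
    replicate_ids: np.ndarray  # per observation

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        ids = np.asarray(self.replicate_ids)
        if not (c.shape == r.shape == ids.shape):
            raise ValueError("columns must have equal length")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.unique(c).size < 4:
            raise ValueError("need >= 4 distinct concentrations to fit")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)
        object.__setattr__(self, "replicate_ids", ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DoseResponseSeries":
        return cls(
            df["concentration_molar"].to_numpy(),
            df["response"].to_numpy(),
            df["replicate_id"].to_numpy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate_id": self.replicate_ids,
                "concentration_molar": self.concentrations,
                "response": self.responses,
            }
        )

    def subset(self, replicate_ids) -> "DoseResponseSeries":
        """Concatenate the observations of the given replicates (with
        multiplicity — the bootstrap resampling primitive)."""
        parts = [np.nonzero(self.replicate_ids == rid)[0] for rid in replicate_ids]
        idx = np.concatenate(parts) if parts else np.array([], dtype=int)
        return DoseResponseSeries(
            self.concentrations[idx], self.responses[idx], self.replicate_ids[idx]
        )


@dataclass
class HillFit:
    ec50: float  # molar (IC50 for inhibition fits)
    hill_coefficient: float
    top: float
    direction: str  # "activation" | "inhibition"
    floor: float = 0.0
    ci_low: float | None = None
    ci_high: float | None = None
    residual_rms: float = np.nan
    n_obs: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("activation", "inhibition"):
            raise ValueError("direction must be 'activation' or 'inhibition'")
        if not self.ec50 > 0:
            raise ValueError("ec50 must be positive")


def normalize_responses(raw: pd.DataFrame) -> DoseResponseSeries:
    """Scale each replicate's responses to its own maximum (max → 1.0).

    ``raw`` is long-format with columns (replicate_id, concentration_molar,
    response); responses are raw maxima (e.g. peak currents in μA).
    """
    out = raw.copy()
    for rid, grp in raw.groupby("replicate_id"):
        m = grp["response"].max()
        if not m > 0:
            raise NormalizationError(f"replicate {rid!r} has non-positive maximum")
        out.loc[grp.index, "response"] = grp["response"] / m
    return DoseResponseSeries.from_frame(out)


def _model(logc: np.ndarray, log_ec50: float, n: float, top: float,
           direction: str, floor: float) -> np.ndarray:
    # Hill in log space: top/(1 + (ec50/c)^n) = top*expit(n*(ln c - ln ec50))
    occ = expit(n * (logc - log_ec50))
    if direction == "activation":
        return top * occ
    return top - (top - floor) * occ


def hill_response(
    concentration, ec50: float, hill_coefficient: float, top: float = 1.0,
    direction: str = "activation", floor: float = 0.0,
):
    """Evaluate the Hill model; exact 0 (activation) or top (inhibition) at c=0."""
    c = np.asarray(concentration, dtype=float)
    scalar = c.ndim == 0
    c = np.atleast_1d(c)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = np.empty_like(c, dtype=float)
    pos = c > 0
    with np.errstate(divide="ignore"):
        out[pos] = _model(np.log(c[pos]), np.log(ec50), hill_coefficient, top,
                          direction, floor)
    out[~pos] = 0.0 if direction == "activation" else top
    return float(out[0]) if scalar else out


def predict(fit: HillFit, concentration):
    """Model response at a concentration (scalar or array)."""
    return hill_response(
        concentration, fit.ec50, fit.hill_coefficient, fit.top, fit.direction, fit.floor
    )


def fit_hill(
    series: DoseResponseSeries,
    direction: str,
    floor: float = 0.0,
    top_fixed: float | None = None,
    multi_start: bool = True,
) -> HillFit:
    """Least-squares Hill fit.

    Activation: bottom 0, top free (unless ``top_fixed``).  Inhibition: top
    fixed at 1 (baseline-normalized) and floor fixed (0 by default).  The
    optimizer runs from a half-max-interpolation start and, if requested,
    from every tested dose, keeping the lowest-cost solution.
    """
    if direction not in ("activation", "inhibition"):
        raise ValueError("direction must be 'activation' or 'inhibition'")
    logc = np.log(series.concentrations)
    r = series.responses
    fit_top = direction == "activation" and top_fixed is None
    top_val = 1.0 if top_fixed is None else top_fixed

    def residuals(theta):
        log_ec50, log_n = theta[0], theta[1]
        top = np.exp(theta[2]) if fit_top else top_val
        return _model(logc, log_ec50, np.exp(log_n), top, direction, floor) - r

    # initial EC50: dose whose mean response is nearest half-effect
    df = pd.DataFrame({"logc": logc, "r": r}).groupby("logc")["r"].mean()
    means = df.to_numpy()
    half = (means.max() + means.min()) / 2.0
    start_logc = float(df.index.to_numpy()[np.argmin(np.abs(means - half))])
    starts = [start_logc]
    if multi_start:
        starts += list(np.unique(logc))

    best = None
    for s in starts:
        theta0 = [s, 0.0] + ([np.log(max(r.max(), 1e-6))] if fit_top else [])
        try:
            sol = least_squares(
                residuals, theta0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-14:
            best = sol
        if not multi_start:
            break
        if best.cost < 1e-18:
            break
    if best is None:
        raise FitError("no optimizer start converged")
    log_ec50, log_n = best.x[0], best.x[1]
    top = float(np.exp(best.x[2])) if fit_top else top_val
    rms = float(np.sqrt(2.0 * best.cost / len(r)))
    return HillFit(
        ec50=float(np.exp(log_ec50)),
        hill_coefficient=float(np.exp(log_n)),
        top=top,
        direction=direction,
        floor=floor,
        residual_rms=rms,
        n_obs=len(r),
    )


def confidence_interval(
    fit: HillFit,
    series: DoseResponseSeries,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    method: str = "expanded",
) -> tuple[float, float]:
    """Bootstrap CI for EC50, case-resampling whole replicates.

    ``method="expanded"`` (default) uses Hesterberg's expanded percentile
    interval: the plain percentile interval is known to undercover for small
    replicate counts, so the quantile levels are widened to
    Φ(−t_{α/2,n−1}·√(n/(n−1))), which restores near-nominal coverage at the
    replicate scales typical of oocyte experiments.  ``method="percentile"``
    gives the plain percentile interval.  Deterministic for a fixed seed.
    Refits start from the point estimate (single-start) for speed; resamples
    whose refit fails are skipped.
    """
    from scipy import stats

    rids = np.unique(series.replicate_ids)
    if rids.size < 2:
        raise BootstrapError("need >= 2 replicates to bootstrap")
    if method not in ("expanded", "percentile"):
        raise ValueError("method must be 'expanded' or 'percentile'")
    rng = np.random.default_rng(seed)
    est = []
    for _ in range(n_boot):
        pick = rng.choice(rids, size=rids.size, replace=True)
        try:
            sub = series.subset(pick)
            bf = fit_hill(
                sub, fit.direction, floor=fit.floor,
                top_fixed=None if fit.direction == "activation" else fit.top,
                multi_start=False,
            )
        except (ValueError, FitError):
            continue
        est.append(bf.ec50)
    if not est:
        raise BootstrapError("all bootstrap refits failed")
    alpha = (1.0 - level) / 2.0
    if method == "expanded":
        n = rids.size
        t_crit = stats.t.ppf(1.0 - alpha, n - 1)
        alpha = float(stats.norm.cdf(-t_crit * np.sqrt(n / (n - 1.0))))
    lo, hi = np.quantile(est, [alpha, 1.0 - alpha])
    fit.ci_low, fit.ci_high = float(lo), float(hi)
    return float(lo), float(hi)
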