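"""Fleet assessment by viable-pair Monte-Carlo sampling of Schaefer dynamics.

A fleet's monthly fishing hours A_t are treated as the abundance index of a
stock governed by the Schaefer surplus-production recurrence

    A_{t+1} = A_t + r * A_t * (1 - A_t / kq) - Cq_t

where r is the fleet's intrinsic (monthly) growth rate — how fast it rebuilds
fishing hours after a loss — kq is the maximum number of hours the fleet can
sustain (carrying capacity times catchability; q is implicit and never
estimated separately), and Cq_t is the implied monthly reduction of fishing
hours caused by external stress factors (seasonal bans, decommissioning,
market shocks, lockdowns).

Because the recurrence can be inverted exactly for Cq_t given (r, kq), the
fit proceeds AMSY-style: draw many (r, kq) pairs from a log-uniform prior
box and keep the *viable* ones — those whose implied stress series is
everywhere non-negative and for which the observed effort never exceeds kq.
Point estimates are medians over the viable cloud, uncertainty the central
95% interval. From r and kq follows the maximum sustainable reduction of
fishing hours MSR = r * kq / 4 (the MSY of the Schaefer model), and the
relative stress series Cmsr_t = Cq_t / MSR, whose excursions above 1 mark
over-stressed months.

The statsmodels-style entry point is :class:`FleetResilienceModel`; the
individual steps are also exposed as functions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import EffortSeries

DEFAULT_R_RANGE = (0.05, 2.0)
DEFAULT_N_SAMPLES = 100_000
#: kq prior defaults to (max A, KQ_UPPER_FACTOR * max A)
KQ_UPPER_FACTOR = 4.0
#: tolerance around Cmsr = 1 for the SUSTAINABLE state
SUSTAINABLE_TOL = 1e-9


@dataclass
class PriorConfig:
    """Log-uniform prior box for the viable-pair sampler.

    r_range is in month^-1; kq_range in hours/month (None derives
    (max A, 4 max A) from the series). ``final_depletion``, if given as
    (lo, hi), additionally requires lo <= A_end/kq <= hi (off by default).
    """

    r_range: tuple[float, float] = DEFAULT_R_RANGE
    kq_range: tuple[float, float] | None = None
    n_samples: int = DEFAULT_N_SAMPLES
    seed: int = 0
    final_depletion: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name, rng in (("r_range", self.r_range), ("kq_range", self.kq_range)):
            if rng is None:
                continue
            lo, hi = rng
            if not (0 < lo < hi):
                raise ValueError(f"{name} must satisfy 0 < low < high, got {rng}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def resolve_kq_range(self, hours: np.ndarray) -> tuple[float, float]:
        if self.kq_range is not None:
            return self.kq_range
        top = float(np.max(hours))
        return (top, KQ_UPPER_FACTOR * top)


@dataclass
class FleetTraits:
    """Point estimates and 95% intervals for one fleet's Schaefer traits."""

    r_hat: float
    r_ci: tuple[float, float]
    kq_hat: float
    kq_ci: tuple[float, float]
    n_viable: int

    def __post_init__(self) -> None:
        if not (self.r_ci[0] <= self.r_hat <= self.r_ci[1]):
            raise ValueError("r_hat outside its confidence interval")
        if not (self.kq_ci[0] <= self.kq_hat <= self.kq_ci[1]):
            raise ValueError("kq_hat outside its confidence interval")

    @property
    def msr(self) -> float:
        """Maximum sustainable reduction of fishing hours, r*kq/4."""
        return self.r_hat * self.kq_hat / 4.0

    def to_dict(self) -> dict:
        return {
            "r": self.r_hat,
            "r_ci": list(self.r_ci),
            "kq": self.kq_hat,
            "kq_ci": list(self.kq_ci),
            "msr": self.msr,
            "n_viable": self.n_viable,
        }


def _as_hours(series) -> np.ndarray:
    hours = series.hours if isinstance(series, EffortSeries) else np.asarray(series, dtype=float)
    if hours.ndim != 1 or len(hours) < 2:
        raise ValueError("need a 1-d effort series of length >= 2")
    if not np.all(hours > 0):
        raise ValueError("effort hours must be strictly positive")
    return hours


def implied_catch(series, r: float, kq: float) -> np.ndarray:
    """Invert the Schaefer recurrence for the stress series Cq_t.

    Cq_t = A_t + r*A_t*(1 - A_t/kq) - A_{t+1}, length n-1. Exact algebraic
    inversion: forward simulation with the result reproduces the series.
    """
    if r <= 0 or kq <= 0:
        raise ValueError("r and kq must be positive")
    a = _as_hours(series)
    return a[:-1] + r * a[:-1] * (1.0 - a[:-1] / kq) - a[1:]


def simulate_schaefer(a0: float, r: float, kq: float, catch) -> np.ndarray:
    """Forward-simulate the Schaefer recurrence from a0 under a catch series.

    Returns len(catch)+1 values [A_0, ..., A_n]. Does not enforce positivity;
    callers that need it (e.g. the synthetic generator) check the output.
    """
    catch = np.asarray(catch, dtype=float)
    out = np.empty(len(catch) + 1)
    out[0] = a0
    for t, c in enumerate(catch):
        a = out[t]
        out[t + 1] = a + r * a * (1.0 - a / kq) - c
    return out


def viability_mask(series, r, kq) -> np.ndarray:
    """Vectorized viability test for (r, kq) pairs against an effort series.

    A pair is viable iff every implied Cq_t >= 0 and max(A) <= kq.
    ``r`` and ``kq`` are equal-length arrays; returns a boolean array.
    """
    a = _as_hours(series)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    kq = np.atleast_1d(np.asarray(kq, dtype=float))
    if r.shape != kq.shape:
        raise ValueError("r and kq must have the same shape")
    a0 = a[:-1, None]
    cq = a0 + r[None, :] * a0 * (1.0 - a0 / kq[None, :]) - a[1:, None]
    return (cq >= 0.0).all(axis=0) & (np.max(a) <= kq)


def sample_viable_pairs(series, prior: PriorConfig | None = None) -> pd.DataFrame:
    """Draw (r, kq) pairs log-uniformly from the prior box and keep the viable ones.

    Returns a DataFrame with columns r, kq (one row per viable pair).
    Raises if no pair is viable — the series does not fit Schaefer dynamics
    under this prior and a wider box is needed.
    """
    prior = prior or PriorConfig()
    a = _as_hours(series)
    kq_lo, kq_hi = prior.resolve_kq_range(a)
    rng = np.random.default_rng(prior.seed)
    r_draw = np.exp(rng.uniform(np.log(prior.r_range[0]), np.log(prior.r_range[1]), prior.n_samples))
    kq_draw = np.exp(rng.uniform(np.log(kq_lo), np.log(kq_hi), prior.n_samples))

    keep = np.empty(prior.n_samples, dtype=bool)
    chunk = 50_000  # bound peak memory at ~ chunk * (n-1) floats
    for i in range(0, prior.n_samples, chunk):
        sl = slice(i, i + chunk)
        keep[sl] = viability_mask(a, r_draw[sl], kq_draw[sl])
    if prior.final_depletion is not None:
        lo, hi = prior.final_depletion
        depl = a[-1] / kq_draw
        keep &= (depl >= lo) & (depl <= hi)
    if not keep.any():
        raise ValueError(
            "no viable (r, kq) pairs under the prior "
            f"r in {prior.r_range}, kq in ({kq_lo:.6g}, {kq_hi:.6g}); "
            "the series does not fit Schaefer dynamics under this prior — widen it"
        )
    return pd.DataFrame({"r": r_draw[keep], "kq": kq_draw[keep]})


def estimate_traits(viable: pd.DataFrame) -> FleetTraits:
    """Medians and central-95% intervals over the viable-pair cloud."""
    if len(viable) == 0:
        raise ValueError("viable-pair set is empty")
    r = viable["r"].to_numpy()
    kq = viable["kq"].to_numpy()
    return FleetTraits(
        r_hat=float(np.median(r)),
        r_ci=(float(np.percentile(r, 2.5)), float(np.percentile(r, 97.5))),
        kq_hat=float(np.median(kq)),
        kq_ci=(float(np.percentile(kq, 2.5)), float(np.percentile(kq, 97.5))),
        n_viable=int(len(viable)),
    )


def stress_series(series: EffortSeries, traits: FleetTraits) -> pd.DataFrame:
    """Implied stress Cq_t, relative stress Cmsr_t = Cq_t/MSR and state labels.

    Cq_t is the reduction realized between months t and t+1 and is labelled
    with month t+1 (the month in which the loss of hours shows up). States:
    OVER if Cmsr > 1, UNDER if < 1, SUSTAINABLE if equal within 1e-9.
    """
    if traits.msr <= 0:
        raise ValueError("msr must be positive")
    cq = implied_catch(series, traits.r_hat, traits.kq_hat)
    cmsr = cq / traits.msr
    state = np.where(
        np.abs(cmsr - 1.0) <= SUSTAINABLE_TOL, "SUSTAINABLE", np.where(cmsr > 1.0, "OVER", "UNDER")
    )
    months = series.months[1:]
    return pd.DataFrame(
        {
            "year": months.year,
            "month": months.month,
            "Cq": cq,
            "Cmsr": cmsr,
            "state": state,
        }
    )


class FleetResilienceModel:
    """Schaefer fleet-as-stock model for one fleet's monthly effort series.

    Parameters
    ----------
    series : EffortSeries
        Monthly total fishing hours of the fleet (the abundance index).
    prior : PriorConfig, optional
        Sampling prior for the viable-pair Monte-Carlo; defaults are
        r in (0.05, 2.0) per month and kq in (max A, 4 max A), log-uniform.

    Examples
    --------
    >>> model = FleetResilienceModel.from_dataframe(df, fleet="PS")
    >>> res = model.fit(seed=1)
    >>> res.traits.msr  # doctest: +SKIP
    """

    def __init__(self, series: EffortSeries, prior: PriorConfig | None = None) -> None:
        if len(series) < 2:
            raise ValueError("need at least two months of effort")
        self.series = series
        self.prior = prior or PriorConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fleet: str | None = None, prior: PriorConfig | None = None):
        return cls(EffortSeries.from_dataframe(df, fleet=fleet), prior=prior)

    def fit(self, n_samples: int | None = None, seed: int | None = None) -> "FleetResilienceResults":
        """Run the viable-pair sampler and derive traits and stress series."""
        prior = self.prior
        if n_samples is not None or seed is not None:
            prior = PriorConfig(
                r_range=prior.r_range,
                kq_range=prior.kq_range,
                n_samples=n_samples if n_samples is not None else prior.n_samples,
                seed=seed if seed is not None else prior.seed,
                final_depletion=prior.final_depletion,
            )
        viable = sample_viable_pairs(self.series, prior)
        traits = estimate_traits(viable)
        stress = stress_series(self.series, traits)
        return FleetResilienceResults(self, prior, viable, traits, stress)


class FleetResilienceResults:
    """Fit results: viable pairs, trait estimates with CIs, and stress series."""

    def __init__(self, model, prior, viable, traits, stress) -> None:
        self.model = model
        self.prior = prior
        self.viable = viable
        self.traits = traits
        self.stress = stress

    @property
    def params(self) -> pd.Series:
        return pd.Series({"r": self.traits.r_hat, "kq": self.traits.kq_hat})

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.traits.r_ci, self.traits.kq_ci], index=["r", "kq"], columns=["lower", "upper"]
        )

    @property
    def msr(self) -> float:
        return self.traits.msr

    def implied_stress(self) -> pd.DataFrame:
        return self.stress

    def simulate(self, catch=None) -> np.ndarray:
        """Forward-simulate the fitted dynamics; default catch = implied Cq."""
        cq = self.stress["Cq"].to_numpy() if catch is None else np.asarray(catch, float)
        return simulate_schaefer(self.model.series.hours[0], self.traits.r_hat, self.traits.kq_hat, cq)

    def summary(self) -> str:
        t = self.traits
        s = self.model.series
        n_over = int((self.stress["state"] == "OVER").sum())
        buf = io.StringIO()
        w = buf.write
        w("Fleet resilience fit (Schaefer viable-pair Monte-Carlo)\n")
        w("=" * 56 + "\n")
        w(f"fleet: {s.fleet}    months: {len(s)} ({s.months[0]}..{s.months[-1]})\n")
        w(f"prior: r in {self.prior.r_range} /month, ")
        kq_rng = self.prior.resolve_kq_range(s.hours)
        w(f"kq in ({kq_rng[0]:.5g}, {kq_rng[1]:.5g}) h, log-uniform\n")
        w(f"samples: {self.prior.n_samples}   viable: {t.n_viable}\n")
        w("-" * 56 + "\n")
        w(f"{'trait':<28}{'estimate':>12}{'95% interval':>16}\n")
        w(f"{'r (month^-1)':<28}{t.r_hat:>12.3f}{f'[{t.r_ci[0]:.2f}, {t.r_ci[1]:.2f}]':>16}\n")
        w(f"{'kq (hours/month)':<28}{t.kq_hat:>12.0f}{f'[{t.kq_ci[0]:.0f}, {t.kq_ci[1]:.0f}]':>16}\n")
        w(f"{'MSR = r*kq/4 (hours/month)':<28}{t.msr:>12.0f}\n")
        w("-" * 56 + "\n")
        w(f"over-stressed months (Cmsr > 1): {n_over} of {len(self.stress)}\n")
        return buf.getvalue()

    def to_report(self) -> dict:
        return {
            "fleet": self.model.series.fleet,
            "n_months": len(self.model.series),
            "traits": self.traits.to_dict(),
            "n_over_stressed": int((self.stress["state"] == "OVER").sum()),
        }

    def plot_stress(self, ax=None):
        """Quick-look plot of the Cmsr_t series with the sustainability line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        x = pd.PeriodIndex(
            [pd.Period(year=y, month=m, freq="M") for y, m in zip(self.stress["year"], self.stress["month"])]
        ).to_timestamp()
        ax.plot(x, self.stress["Cmsr"], lw=1.2, label=self.model.series.fleet)
        ax.axhline(1.0, ls="--", c="k", lw=0.8)
        ax.set_ylabel("Cmsr (stress / MSR)")
        ax.legend()
        return ax


def assess_fleet(series: EffortSeries, prior: PriorConfig | None = None) -> dict:
    """One-call fleet assessment: sampler -> traits -> stress, as a report dict."""
    res = FleetResilienceModel(series, prior=prior).fit()
    report = res.to_report()
    report["stress"] = res.stress.to_dict(orient="list")
    return report
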