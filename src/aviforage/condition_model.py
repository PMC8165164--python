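"""Bayesian time-series comparison of orientation dynamics between conditions.

Model
-----
For binned mean orientation-index series ``y_ref`` and ``y_alt`` on a
common time grid ``t = 1..T``::

    y_ref[t] = mu[t]            + eps[t]      eps  ~ N(0, sigma_obs^2)
    y_alt[t] = mu[t] + delta[t] + eps'[t]     eps' ~ N(0, sigma_obs^2)

    mu[t]    ~ N(mu[t-1],    sigma_mu^2)     (first-order random walk)
    delta[t] ~ N(delta[t-1], sigma_delta^2)

``mu`` is the trend the two conditions share; ``delta`` is the
time-varying condition difference.  Half-normal priors sit on all three
scales.  The scalar summary is the posterior of the time-averaged
difference, Delta-bar; "difference periods" are the bins whose pointwise
95% credible interval for ``delta`` excludes zero.

Inference is exact-conditional Gibbs: given the scales, the joint state
(mu, delta) is Gaussian with a banded precision matrix and is drawn in
one block via a banded Cholesky factorization; given the states, each
log-scale is updated by slice sampling.  Missing bins simply contribute
no observation term and are bridged by the state equations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve_banded, cholesky_banded, solve_banded

from .errors import InputError
from .kinematics import index_to_degrees

__all__ = [
    "BinnedSeries",
    "bin_series",
    "ConditionDifferenceModel",
    "ConditionDifferenceResults",
    "fit_condition_model",
    "summarize_difference",
]

MIN_BINS = 20


# --------------------------------------------------------------------------
# binning
# --------------------------------------------------------------------------


@dataclass
class BinnedSeries:
    """Across-session mean orientation per condition on a common time grid."""

    values: pd.DataFrame  # index: bin center (s); columns: condition labels
    n_frames: pd.DataFrame  # contributing frames per bin and condition
    bin_width: float

    @property
    def bin_time(self) -> np.ndarray:
        return self.values.index.to_numpy()


def bin_series(frames: pd.DataFrame, bin_width: float = 1.0) -> BinnedSeries:
    """Bin per-frame orientation: within-bin mean per session, then mean
    across sessions/birds per condition.

    ``frames`` needs columns bird_id, condition, session, time, orientation.
    Bins with no data are marked missing.
    """
    if bin_width <= 0:
        raise InputError("bin_width must be > 0")
    df = frames.dropna(subset=["orientation"]).copy()
    if df.empty:
        raise InputError("no orientation data to bin")
    # nudge guards against x/width landing at 2.999... for exact multiples
    df["bin"] = np.floor(df["time"].to_numpy() / bin_width + 1e-7).astype(int)
    per_session = (
        df.groupby(["condition", "bird_id", "session", "bin"], sort=True)["orientation"]
        .agg(["mean", "size"])
        .reset_index()
    )
    values = per_session.pivot_table(
        index="bin", columns="condition", values="mean", aggfunc="mean"
    )
    counts = per_session.pivot_table(
        index="bin", columns="condition", values="size", aggfunc="sum"
    ).fillna(0).astype(int)
    full = np.arange(values.index.min(), values.index.max() + 1)
    values = values.reindex(full)
    counts = counts.reindex(full, fill_value=0)
    centers = (values.index.to_numpy() + 0.5) * bin_width
    values.index = pd.Index(centers, name="bin_time")
    counts.index = values.index
    return BinnedSeries(values=values, n_frames=counts, bin_width=bin_width)


# --------------------------------------------------------------------------
# sampler internals
# --------------------------------------------------------------------------


def _draw_states(y_ref, y_alt, obs_ref, obs_alt, s_mu, s_delta, s_obs, rng):
    """One joint draw of (mu_1..T, delta_1..T) given the scales.

    States are interleaved (mu_1, delta_1, mu_2, delta_2, ...) so the
    posterior precision is banded with bandwidth 2.  The initial states
    carry a flat prior: the observations anchor both chains, and a flat
    start keeps the delta posterior exactly invariant when a constant is
    added to both series.
    """
    T = len(y_ref)
    N = 2 * T
    q_mu = 1.0 / s_mu**2
    q_de = 1.0 / s_delta**2
    q_ob = 1.0 / s_obs**2

    d0 = np.zeros(N)  # main diagonal
    d1 = np.zeros(N)  # first super-diagonal, entry j couples z[j-1], z[j]
    d2 = np.zeros(N)  # second super-diagonal
    b = np.zeros(N)

    even = np.arange(0, N, 2)
    odd = even + 1

    # random-walk priors: interior states sit in two increments, endpoints in one
    if T > 1:
        d0[even] = q_mu * np.where((even > 0) & (even < N - 2), 2.0, 1.0)
        d0[odd] = q_de * np.where((odd > 1) & (odd < N - 1), 2.0, 1.0)
        d2[even[1:]] -= q_mu  # entry at column 2t couples mu_{t-1}, mu_t
        d2[odd[1:]] -= q_de

    # observations
    d0[even[obs_ref]] += q_ob
    b[even[obs_ref]] += q_ob * y_ref[obs_ref]
    d0[even[obs_alt]] += q_ob
    d0[odd[obs_alt]] += q_ob
    d1[odd[obs_alt]] += q_ob  # mu_t -- delta_t coupling
    b[even[obs_alt]] += q_ob * y_alt[obs_alt]
    b[odd[obs_alt]] += q_ob * y_alt[obs_alt]

    ab = np.vstack([d2, d1, d0])  # upper banded storage, u = 2
    U = cholesky_banded(ab, lower=False)
    mean = cho_solve_banded((U, False), b)
    z = mean + solve_banded((0, 2), U, rng.standard_normal(N))
    return z[even], z[odd]


def _interweave_scale(base, states, resid_terms, s_cur, s_obs, prior_scale, rng):
    """Ancillarity-sufficiency interweaving update of a random-walk scale.

    Re-expresses the walk non-centered, ``state = base + beta * c`` with
    ``c`` the cumulated standardized increments, where the conditional of
    ``beta`` is Gaussian; returns the new scale |beta| and the
    correspondingly rescaled states.  This breaks the funnel that traps
    the centered sampler when the true walk variance is near zero.

    ``resid_terms`` is a list of (residual, observed_mask) pairs whose
    residuals exclude the ``beta * c`` contribution.
    """
    if s_cur < 1e-12:
        return s_cur, states
    c = np.concatenate([[0.0], np.cumsum(np.diff(states))]) / s_cur
    q_ob = 1.0 / s_obs**2
    prec = 1.0 / prior_scale**2
    lin = 0.0
    for resid, obs in resid_terms:
        prec += q_ob * float(np.sum(c[obs] ** 2))
        lin += q_ob * float(np.sum(c[obs] * resid[obs]))
    mean = lin / prec
    beta = rng.normal(mean, 1.0 / np.sqrt(prec))
    return abs(beta), base + beta * c


def _slice_sample_log_scale(theta, n, S, prior_scale, rng, w=0.5, max_steps=50):
    """Slice-sample theta = log(sigma) for a Gaussian scale.

    Target: (1 - n) * theta - S * exp(-2 theta) / 2 - exp(2 theta) / (2 p^2),
    i.e. likelihood sigma^-n exp(-S / (2 sigma^2)) times half-normal(p) prior,
    with the Jacobian of the log transform.
    """

    def logp(th):
        return (1.0 - n) * th - 0.5 * S * np.exp(-2 * th) - np.exp(2 * th) / (
            2 * prior_scale**2
        )

    y = logp(theta) + np.log(rng.random())
    lo = theta - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logp(lo) <= y:
            break
        lo -= w
    for _ in range(max_steps):
        if logp(hi) <= y:
            break
        hi += w
    for _ in range(200):
        prop = rng.uniform(lo, hi)
        if logp(prop) > y:
            return prop
        if prop < theta:
            lo = prop
        else:
            hi = prop
    return theta  # pathological shrinkage; keep the current value


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------


@dataclass
class Priors:
    scale: float = 0.5  # half-normal scale for sigma_mu, sigma_delta, sigma_obs


class ConditionDifferenceModel:
    """State-space comparison of two binned orientation series.

    Parameters
    ----------
    y_ref, y_alt : array-like
        Binned series for the reference and alternative condition on a
        common grid; NaN marks missing bins.
    bin_time : array-like, optional
        Bin centers in seconds (defaults to 0.5, 1.5, ...).
    reference, alternative : str
        Condition labels, used in summaries.
    priors : Priors
        Half-normal prior scale for the three sigmas.
    """

    def __init__(
        self,
        y_ref,
        y_alt,
        bin_time=None,
        reference: str = "reference",
        alternative: str = "alternative",
        priors: Priors | None = None,
    ):
        y_ref = np.asarray(y_ref, dtype=float)
        y_alt = np.asarray(y_alt, dtype=float)
        if y_ref.shape != y_alt.shape or y_ref.ndim != 1:
            raise InputError("y_ref and y_alt must be 1-d arrays of equal length")
        obs_ref = ~np.isnan(y_ref)
        obs_alt = ~np.isnan(y_alt)
        if int(obs_ref.sum()) == 0 or int(obs_alt.sum()) == 0:
            raise InputError("both conditions must have observed bins")
        n_bins = int((obs_ref | obs_alt).sum())
        if n_bins < MIN_BINS:
            raise InputError(
                f"need at least {MIN_BINS} non-missing bins, got {n_bins}"
            )
        self.y_ref = y_ref
        self.y_alt = y_alt
        self.obs_ref = obs_ref
        self.obs_alt = obs_alt
        self.bin_time = (
            np.asarray(bin_time, dtype=float)
            if bin_time is not None
            else np.arange(len(y_ref)) + 0.5
        )
        if len(self.bin_time) != len(y_ref):
            raise InputError("bin_time length must match the series")
        self.reference = reference
        self.alternative = alternative
        self.priors = priors or Priors()

    @classmethod
    def from_binned(
        cls,
        binned: BinnedSeries,
        reference: str,
        alternative: str,
        priors: Priors | None = None,
    ) -> "ConditionDifferenceModel":
        for label in (reference, alternative):
            if label not in binned.values.columns:
                raise InputError(f"condition {label!r} not present in binned series")
        return cls(
            binned.values[reference].to_numpy(),
            binned.values[alternative].to_numpy(),
            bin_time=binned.bin_time,
            reference=reference,
            alternative=alternative,
            priors=priors,
        )

    def fit(
        self,
        draws: int = 1000,
        warmup: int = 1000,
        chains: int = 4,
        seed: int = 0,
    ) -> "ConditionDifferenceResults":
        """Run the Gibbs sampler and return posterior results."""
        T = len(self.y_ref)
        p = self.priors
        delta_draws = np.empty((chains, draws, T))
        mu_draws = np.empty((chains, draws, T))
        scale_draws = np.empty((chains, draws, 3))  # sigma_mu, sigma_delta, sigma_obs

        resid0 = np.nanstd(self.y_alt - self.y_ref) / np.sqrt(2)
        if not np.isfinite(resid0) or resid0 <= 0:
            resid0 = 0.05

        seeds = np.random.SeedSequence(seed).spawn(chains)
        n_obs = int(self.obs_ref.sum() + self.obs_alt.sum())
        for c in range(chains):
            rng = np.random.default_rng(seeds[c])
            # over-dispersed chain initialization
            th = np.log(np.array([0.05, 0.05, resid0])) + rng.normal(0, 0.5, 3)
            s_mu, s_de, s_ob = np.exp(th)
            for it in range(warmup + draws):
                mu, de = _draw_states(
                    self.y_ref,
                    self.y_alt,
                    self.obs_ref,
                    self.obs_alt,
                    s_mu,
                    s_de,
                    s_ob,
                    rng,
                )
                S_mu = float(np.sum(np.diff(mu) ** 2))
                S_de = float(np.sum(np.diff(de) ** 2))
                r = np.concatenate(
                    [
                        (self.y_ref - mu)[self.obs_ref],
                        (self.y_alt - mu - de)[self.obs_alt],
                    ]
                )
                S_ob = float(np.sum(r**2))
                th_mu = _slice_sample_log_scale(np.log(s_mu), T - 1, S_mu, p.scale, rng)
                th_de = _slice_sample_log_scale(np.log(s_de), T - 1, S_de, p.scale, rng)
                th_ob = _slice_sample_log_scale(np.log(s_ob), n_obs, S_ob, p.scale, rng)
                s_mu, s_de, s_ob = np.exp([th_mu, th_de, th_ob])
                # interweaving: re-draw the walk scales non-centered
                s_mu, mu = _interweave_scale(
                    mu[0],
                    mu,
                    [
                        (self.y_ref - mu[0], self.obs_ref),
                        (self.y_alt - mu[0] - de, self.obs_alt),
                    ],
                    s_mu,
                    s_ob,
                    p.scale,
                    rng,
                )
                s_de, de = _interweave_scale(
                    de[0],
                    de,
                    [(self.y_alt - mu - de[0], self.obs_alt)],
                    s_de,
                    s_ob,
                    p.scale,
                    rng,
                )
                if it >= warmup:
                    k = it - warmup
                    mu_draws[c, k] = mu
                    delta_draws[c, k] = de
                    scale_draws[c, k] = (s_mu, s_de, s_ob)

        return ConditionDifferenceResults(
            model=self,
            mu=mu_draws,
            delta=delta_draws,
            scales=scale_draws,
        )


@dataclass
class ConditionDifferenceResults:
    """Posterior draws and summaries of the condition-difference model."""

    model: ConditionDifferenceModel
    mu: np.ndarray  # (chains, draws, T)
    delta: np.ndarray  # (chains, draws, T)
    scales: np.ndarray  # (chains, draws, 3)
    ci_level: float = 0.95
    _rhat: dict = field(default=None, repr=False)

    # -- scalar summary ----------------------------------------------------
    @property
    def delta_bar_draws(self) -> np.ndarray:
        """Time-averaged difference per draw, flattened over chains."""
        return self.delta.mean(axis=2).ravel()

    @property
    def delta_mean(self) -> float:
        return float(self.delta_bar_draws.mean())

    @property
    def delta_ci(self) -> tuple[float, float]:
        a = (1 - self.ci_level) / 2 * 100
        lo, hi = np.percentile(self.delta_bar_draws, [a, 100 - a])
        return float(lo), float(hi)

    @property
    def excludes_zero(self) -> bool:
        lo, hi = self.delta_ci
        return lo > 0 or hi < 0

    # -- per-bin summary ---------------------------------------------------
    def delta_bins(self) -> pd.DataFrame:
        a = (1 - self.ci_level) / 2 * 100
        flat = self.delta.reshape(-1, self.delta.shape[-1])
        lo, hi = np.percentile(flat, [a, 100 - a], axis=0)
        mean = flat.mean(axis=0)
        return pd.DataFrame(
            {
                "bin_time": self.model.bin_time,
                "delta_mean": mean,
                "ci_low": lo,
                "ci_high": hi,
                "excludes_zero": (lo > 0) | (hi < 0),
            }
        )

    @property
    def difference_periods(self) -> np.ndarray:
        """Bin times whose pointwise CI excludes zero."""
        bins = self.delta_bins()
        return bins.loc[bins["excludes_zero"], "bin_time"].to_numpy()

    # -- diagnostics -------------------------------------------------------
    def rhat(self) -> dict[str, float]:
        """Split-R-hat of the scalar quantities (scales and Delta-bar)."""
        if self._rhat is None:
            import arviz as az

            data = {
                "sigma_mu": self.scales[:, :, 0],
                "sigma_delta": self.scales[:, :, 1],
                "sigma_obs": self.scales[:, :, 2],
                "delta_bar": self.delta.mean(axis=2),
            }
            if self.scales.shape[0] == 1:
                # split single chains in two for a split-Rhat analogue
                data = {
                    k: np.stack(np.array_split(v[0], 2)) for k, v in data.items()
                }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ds = az.rhat(az.from_dict(posterior=data))
            self._rhat = {k: float(ds[k].values) for k in data}
        return self._rhat

    @property
    def converged(self) -> bool:
        vals = [v for v in self.rhat().values() if np.isfinite(v)]
        return bool(vals) and max(vals) <= 1.05

    # -- presentation ------------------------------------------------------
    def degrees(self) -> float:
        d = self.delta_mean
        if abs(d) > 1:
            return float("nan")
        return float(index_to_degrees(d))

    def summary(self) -> str:
        lo, hi = self.delta_ci
        lines = [
            "Condition-difference state-space model",
            f"  comparison : {self.model.alternative} - {self.model.reference}",
            f"  bins       : {len(self.model.bin_time)}"
            f" (width {np.median(np.diff(self.model.bin_time)):.3g} s)",
            f"  chains x draws : {self.delta.shape[0]} x {self.delta.shape[1]}",
            f"  Delta-bar  : {self.delta_mean:.3f} ({self.degrees():.2f} deg)",
            f"  95% CI     : ({lo:.3f}, {hi:.3f})"
            + ("  [excludes 0]" if self.excludes_zero else "  [contains 0]"),
            f"  difference periods : {len(self.difference_periods)} bins",
            "  R-hat      : "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.rhat().items()),
            f"  converged  : {self.converged}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """One-row scalar summary (for the pipeline's posterior CSV)."""
        lo, hi = self.delta_ci
        return pd.DataFrame(
            {
                "comparison": [f"{self.model.reference}-{self.model.alternative}"],
                "delta_mean": [self.delta_mean],
                "ci_low": [lo],
                "ci_high": [hi],
                "degrees": [self.degrees()],
                "n_difference_bins": [len(self.difference_periods)],
                "converged": [self.converged],
            }
        )

    def plot(self, ax=None):
        """Ribbon plot of the posterior difference across time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        bins = self.delta_bins()
        ax.fill_between(
            bins["bin_time"], bins["ci_low"], bins["ci_high"], alpha=0.3, lw=0
        )
        ax.plot(bins["bin_time"], bins["delta_mean"])
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("time (s)")
        ax.set_ylabel(
            f"orientation difference\n({self.model.alternative} - {self.model.reference})"
        )
        return ax


def fit_condition_model(
    series: BinnedSeries,
    reference: str,
    alternative: str,
    priors: Priors | None = None,
    mcmc: dict | None = None,
) -> ConditionDifferenceResults:
    """Convenience wrapper: build the model from a binned series and fit it."""
    mcmc = dict(mcmc or {})
    model = ConditionDifferenceModel.from_binned(series, reference, alternative, priors)
    res = model.fit(
        draws=mcmc.get("draws", 1000),
        warmup=mcmc.get("warmup", 1000),
        chains=mcmc.get("chains", 4),
        seed=mcmc.get("seed", 0),
    )
    if not res.converged:
        warnings.warn(
            f"condition model {reference}-{alternative} has R-hat > 1.05; "
            "inspect results.rhat()"
        )
    return res


def summarize_difference(results: ConditionDifferenceResults) -> dict:
    """Scalar posterior summary: mean, central 95% CI, and degrees."""
    lo, hi = results.delta_ci
    return {
        "mean": results.delta_mean,
        "ci_low": lo,
        "ci_high": hi,
        "degrees": results.degrees(),
    }
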