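"""Most-probable-number estimation from dilution-series bioassays.

Infective propagule density is estimated by maximum likelihood under the
Poisson single-propagule infection model: an assay pot at dilution ``d``
with soil volume ``v`` (mL) is colonized with probability
``1 - exp(-lambda * d * v)``, where ``lambda`` is the propagule density
(propagules per mL of undiluted soil).  The log-likelihood over a series
is unimodal in ``lambda``; it is maximized by bounded 1-D search on the
log scale and a 95% profile-likelihood confidence interval is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["DilutionSeries", "MPNEstimate", "mpn_estimate", "mpn_batch"]

_BRACKET = (1e-8, 1e4)          # propagules/mL search range
_CHI2_95_HALF = 1.9207          # chi2(1, 0.95) / 2 for the profile CI


@dataclass
class DilutionSeries:
    """One bioassay: (dilution factor, volume mL, n tested, n positive) rows."""

    dilutions: np.ndarray
    volumes: np.ndarray
    n_tested: np.ndarray
    n_positive: np.ndarray

    @classmethod
    def from_rows(cls, rows: Sequence) -> "DilutionSeries":
        d, v, n, p = (np.asarray(x, dtype=float) for x in zip(*rows))
        return cls(d, v, n, p)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DilutionSeries":
        return cls(df["dilution"].to_numpy(float),
                   df["volume_ml"].to_numpy(float),
                   df["n_tested"].to_numpy(float),
                   df["n_positive"].to_numpy(float))

    def __post_init__(self):
        if np.any(self.n_positive < 0) or np.any(self.n_positive > self.n_tested):
            raise ValueError("n_positive must lie in [0, n_tested]")
        if np.any(self.dilutions <= 0) or np.any(self.volumes <= 0):
            raise ValueError("dilutions and volumes must be positive")
        if len(self.dilutions) > 1 and np.any(np.diff(self.dilutions) >= 0):
            raise ValueError("dilution factors must be strictly decreasing")


@dataclass
class MPNEstimate:
    density: float                 # propagules per mL soil
    loglik: float
    ci_low: float
    ci_high: float
    all_negative: bool = False
    all_positive: bool = False

    def per_gram(self, ml_per_gram: float) -> float:
        """Convert to propagules per gram via a soil mL-per-g factor."""
        return self.density * ml_per_gram


def _loglik(lam: float, s: DilutionSeries) -> float:
    mu = lam * s.dilutions * s.volumes
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(mu > 0, np.log1p(-np.exp(-mu)), -np.inf)
        pos_term = np.where(s.n_positive > 0, s.n_positive * lp, 0.0)
    return float(np.sum(pos_term - (s.n_tested - s.n_positive) * mu))


def mpn_estimate(series) -> MPNEstimate:
    """Maximum-likelihood propagule density with a 95% profile CI.

    All-negative series return density 0 with a one-sided upper bound;
    all-positive series return an infinite point estimate flagged with a
    finite profile lower bound only.
    """
    s = series if isinstance(series, DilutionSeries) else DilutionSeries.from_frame(series)
    pos, tot = s.n_positive.sum(), s.n_tested.sum()

    if pos == 0:
        # L(lambda) is decreasing; upper bound where loglik drops by 1.92
        ll0 = _loglik(0.0, s)
        hi = optimize.brentq(
            lambda lam: _loglik(lam, s) - (ll0 - _CHI2_95_HALF),
            _BRACKET[0], _BRACKET[1])
        return MPNEstimate(0.0, ll0, 0.0, hi, all_negative=True)
    if pos == tot:
        # L increasing in lambda: only a lower confidence bound exists
        ll_sup = 0.0  # supremum as lambda -> inf
        lo = optimize.brentq(
            lambda lam: _loglik(lam, s) - (ll_sup - _CHI2_95_HALF),
            _BRACKET[0], _BRACKET[1])
        return MPNEstimate(math.inf, ll_sup, lo, math.inf, all_positive=True)

    res = optimize.minimize_scalar(
        lambda t: -_loglik(math.exp(t), s),
        bounds=(math.log(_BRACKET[0]), math.log(_BRACKET[1])),
        method="bounded", options={"xatol": 1e-10})
    lam_hat = math.exp(res.x)
    ll_max = -res.fun
    target = ll_max - _CHI2_95_HALF

    def diff(lam):
        return _loglik(lam, s) - target

    lo = (optimize.brentq(diff, _BRACKET[0], lam_hat)
          if diff(_BRACKET[0]) < 0 else _BRACKET[0])
    hi = (optimize.brentq(diff, lam_hat, _BRACKET[1])
          if diff(_BRACKET[1]) < 0 else _BRACKET[1])
    return MPNEstimate(lam_hat, ll_max, lo, hi)


def mpn_batch(df: pd.DataFrame, group: str = "trial",
              replicate: str = "block") -> pd.DataFrame:
    """Per-group mean and standard error of replicate-level MPN estimates.

    ``df`` holds one row per dilution level per replicate (columns
    ``dilution``, ``volume_ml``, ``n_tested``, ``n_positive`` plus the
    grouping columns).  Infinite replicate estimates propagate to the mean.
    """
    rows = []
    for (g, r), sub in df.groupby([group, replicate]):
        est = mpn_estimate(DilutionSeries.from_frame(
            sub.sort_values("dilution", ascending=False)))
        rows.append({group: g, replicate: r, "mpn": est.density})
    per_rep = pd.DataFrame(rows)
    def _se(x):
        x = np.asarray(x, float)
        return x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else np.nan
    out = per_rep.groupby(group)["mpn"].agg(
        mean="mean", se=_se, n="count").reset_index()
    return out
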