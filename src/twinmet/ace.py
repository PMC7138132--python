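"""ACE twin variance decomposition by maximum likelihood.

The classical twin model partitions phenotypic variance into additive
genetic (A), common/shared environment (C) and unique environment (E)
components.  Twin pairs are bivariate normal with a common mean and
variance; the within-pair covariance is ``a2 + c2`` of the total for MZ
pairs and ``a2/2 + c2`` for DZ pairs.  Contrasting the two zygosities
identifies all three fractions.

Estimation is direct boundary-constrained maximum likelihood over the
variance components (mean and total variance profiled alongside), started
from the Falconer moment estimates ``a2 = 2 (rMZ - rDZ)``,
``c2 = 2 rDZ - rMZ``.  90% confidence intervals are computed by profile
likelihood (chi-square(1) cutoff 2.706).  The log-likelihood is evaluated
from per-zygosity sufficient statistics, which makes fits and profile
scans cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

__all__ = ["ace_expected_cov", "ace_loglik", "fit_ace", "ACEEstimate", "ACEModel"]

_LOG2PI = math.log(2.0 * math.pi)
_CHI2_90_CUTOFF = 2.705543454095404  # chi2.ppf(0.90, df=1)


def ace_expected_cov(a2: float, c2: float, e2: float, zygosity: str,
                     total_variance: float = 1.0) -> np.ndarray:
    """Expected 2x2 twin-pair covariance under the ACE model."""
    for name, value in (("a2", a2), ("c2", c2), ("e2", e2)):
        if value < 0:
            raise ValueError(f"variance fraction {name} must be >= 0, got {value}")
    if zygosity not in ("MZ", "DZ"):
        raise ValueError(f"zygosity must be 'MZ' or 'DZ', got {zygosity!r}")
    total = (a2 + c2 + e2) * total_variance
    share = 1.0 if zygosity == "MZ" else 0.5
    cov = (share * a2 + c2) * total_variance
    return np.array([[total, cov], [cov, total]])


@dataclass
class _SuffStats:
    """Per-zygosity sufficient statistics for the pair likelihood."""

    n: int
    s1: float   # sum of (x1 + x2)
    s2: float   # sum of (x1^2 + x2^2)
    s12: float  # sum of x1 * x2

    @classmethod
    def from_pairs(cls, pairs: np.ndarray) -> "_SuffStats":
        x = np.asarray(pairs, float)
        if x.ndim != 2 or x.shape[1] != 2:
            raise ValueError("pairs must be an (n, 2) array")
        if not np.isfinite(x).all():
            raise ValueError("incomplete pairs must be excluded before fitting")
        return cls(
            n=x.shape[0],
            s1=float(x.sum()),
            s2=float((x ** 2).sum()),
            s12=float((x[:, 0] * x[:, 1]).sum()),
        )

    def loglik(self, mu: float, total_var: float, rho: float) -> float:
        """Bivariate-normal log-likelihood with common mean/variance.

        Symmetric in the two pair members by construction (it depends on
        the data only through member-exchange-invariant sums).
        """
        if total_var <= 0 or abs(rho) >= 1.0:
            return -math.inf
        q_sq = self.s2 - 2.0 * mu * self.s1 + 2.0 * self.n * mu * mu
        q_cr = self.s12 - mu * self.s1 + self.n * mu * mu
        quad = (q_sq - 2.0 * rho * q_cr) / (total_var * (1.0 - rho * rho))
        return (-self.n * _LOG2PI
                - 0.5 * self.n * math.log(total_var ** 2 * (1.0 - rho * rho))
                - 0.5 * quad)


def _loglik_components(va: float, vc: float, ve: float, mu: float,
                       mz: _SuffStats, dz: _SuffStats) -> float:
    total = va + vc + ve
    if total <= 0:
        return -math.inf
    rho_mz = (va + vc) / total
    rho_dz = (0.5 * va + vc) / total
    return mz.loglik(mu, total, rho_mz) + dz.loglik(mu, total, rho_dz)


def ace_loglik(a2: float, c2: float, e2: float, total_variance: float, mean: float,
               mz_pairs, dz_pairs) -> float:
    """Log-likelihood of the ACE model at given standardized fractions.

    Returns ``-inf`` (rather than raising) when the implied covariance is
    not positive definite, so optimizers can probe the boundary.
    """
    mz = _SuffStats.from_pairs(np.asarray(mz_pairs, float))
    dz = _SuffStats.from_pairs(np.asarray(dz_pairs, float))
    return _loglik_components(a2 * total_variance, c2 * total_variance,
                              e2 * total_variance, mean, mz, dz)


def _double_entry_corr(pairs: np.ndarray) -> float:
    x = np.r_[pairs[:, 0], pairs[:, 1]]
    y = np.r_[pairs[:, 1], pairs[:, 0]]
    sx = x.std()
    if sx == 0:
        return 0.0
    return float(np.clip(np.corrcoef(x, y)[0, 1], -0.99, 0.99))


@dataclass
class ACEEstimate:
    """Standardized ACE variance fractions with 90% profile CIs."""

    a2: float
    c2: float
    e2: float
    total_variance: float
    mean: float
    loglik: float
    converged: bool
    n_mz_pairs: int
    n_dz_pairs: int
    ci90: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "a2": self.a2, "c2": self.c2, "e2": self.e2,
            "total_variance": self.total_variance, "mean": self.mean,
            "loglik": self.loglik, "converged": self.converged,
            "n_mz_pairs": self.n_mz_pairs, "n_dz_pairs": self.n_dz_pairs,
            "ci90": {k: list(v) for k, v in self.ci90.items()},
        }


def _optimize(fun, x0, bounds):
    res = optimize.minimize(fun, x0, method="L-BFGS-B", bounds=bounds)
    return res


def fit_ace(mz_pairs, dz_pairs, compute_ci: bool = True,
            ci_level: float = 0.90) -> ACEEstimate:
    """Boundary-constrained MLE of the ACE decomposition.

    Parameters
    ----------
    mz_pairs, dz_pairs : (n, 2) arrays of complete twin-pair phenotypes.
    compute_ci : whether to compute profile-likelihood CIs (slower).
    ci_level : confidence level for the profile intervals.
    """
    mz_arr = np.asarray(mz_pairs, float)
    dz_arr = np.asarray(dz_pairs, float)
    mz = _SuffStats.from_pairs(mz_arr)
    dz = _SuffStats.from_pairs(dz_arr)
    if mz.n < 10 or dz.n < 10:
        raise ValueError("at least 10 pairs per zygosity are required")
    allx = np.r_[mz_arr.ravel(), dz_arr.ravel()]
    var0 = float(allx.var())
    if var0 <= 0:
        raise ValueError("zero phenotypic variance; the model is degenerate")
    mu0 = float(allx.mean())

    r_mz = _double_entry_corr(mz_arr)
    r_dz = _double_entry_corr(dz_arr)
    a20 = float(np.clip(2.0 * (r_mz - r_dz), 0.0, 0.95))
    c20 = float(np.clip(2.0 * r_dz - r_mz, 0.0, 0.95 - a20))
    e20 = max(1.0 - a20 - c20, 0.05)
    start = np.array([a20 * var0, c20 * var0, e20 * var0, mu0])
    falconer_ll = _loglik_components(*start[:3], start[3], mz, dz)

    floor = 1e-10 * var0

    def nll(x):
        ll = _loglik_components(x[0], x[1], x[2], x[3], mz, dz)
        return -ll if np.isfinite(ll) else 1e12

    bounds = [(0.0, None), (0.0, None), (floor, None), (None, None)]
    best = _optimize(nll, start, bounds)
    # a couple of alternative starts guard against boundary attraction
    for alt in ([0.3 * var0, 0.3 * var0, 0.4 * var0, mu0],
                [0.05 * var0, 0.05 * var0, 0.9 * var0, mu0]):
        res = _optimize(nll, np.asarray(alt), bounds)
        if res.fun < best.fun:
            best = res
    va, vc, ve, mu = best.x
    total = va + vc + ve
    est = ACEEstimate(
        a2=va / total, c2=vc / total, e2=ve / total,
        total_variance=total, mean=mu, loglik=-best.fun,
        converged=bool(best.success and -best.fun >= falconer_ll - 1e-6),
        n_mz_pairs=mz.n, n_dz_pairs=dz.n,
    )
    if compute_ci:
        cutoff = _CHI2_90_CUTOFF if ci_level == 0.90 else float(_chi2_cutoff(ci_level))
        est.ci90 = {
            name: _profile_ci(name, est, mz, dz, cutoff)
            for name in ("a2", "c2", "e2")
        }
    return est


def _chi2_cutoff(level: float) -> float:
    from scipy.stats import chi2
    return chi2.ppf(level, df=1)


def _profile_loglik(which: str, frac: float, est: ACEEstimate,
                    mz: _SuffStats, dz: _SuffStats) -> float:
    """Maximized log-likelihood with one standardized fraction held fixed."""
    frac = min(max(frac, 0.0), 1.0 - 1e-9)

    def unpack(x):
        t, log_v, mu = x
        v = math.exp(min(max(log_v, -300.0), 300.0))
        rest = (1.0 - frac) * v
        if which == "a2":
            va, vc, ve = frac * v, t * rest, (1.0 - t) * rest
        elif which == "c2":
            va, vc, ve = t * rest, frac * v, (1.0 - t) * rest
        else:
            va, vc, ve = t * rest, (1.0 - t) * rest, frac * v
        return va, vc, ve, mu

    def nll(x):
        va, vc, ve, mu = unpack(x)
        ll = _loglik_components(va, vc, max(ve, 1e-12), mu, mz, dz)
        return -ll if np.isfinite(ll) else 1e12

    fracs = {"a2": est.a2, "c2": est.c2, "e2": est.e2}
    rest_now = max(1.0 - fracs[which], 1e-9)
    others = [f for f in ("a2", "c2", "e2") if f != which]
    t0 = min(max(fracs[others[0]] / rest_now, 1e-6), 1.0 - 1e-6)
    x0 = np.array([t0, math.log(max(est.total_variance, 1e-12)), est.mean])
    best = _optimize(nll, x0, [(0.0, 1.0), (None, None), (None, None)])
    for t_alt in (0.05, 0.5, 0.95):
        res = _optimize(nll, np.array([t_alt, x0[1], x0[2]]),
                        [(0.0, 1.0), (None, None), (None, None)])
        if res.fun < best.fun:
            best = res
    return -best.fun


def _profile_ci(which: str, est: ACEEstimate, mz: _SuffStats, dz: _SuffStats,
                cutoff: float) -> tuple[float, float]:
    """Profile-likelihood interval for one standardized fraction."""
    target = est.loglik - cutoff / 2.0
    point = {"a2": est.a2, "c2": est.c2, "e2": est.e2}[which]

    def g(f):
        return _profile_loglik(which, f, est, mz, dz) - target

    lo = 0.0 if g(0.0) >= 0 else optimize.brentq(g, 0.0, point, xtol=1e-4)
    hi = 1.0 if g(1.0 - 1e-9) >= 0 else optimize.brentq(g, point, 1.0 - 1e-9, xtol=1e-4)
    return (float(lo), float(hi))


class ACEModel:
    """Estimator-style interface to the ACE decomposition.

    Parameters
    ----------
    compute_ci : bool
        Compute profile-likelihood CIs during :meth:`fit`.
    ci_level : float
        Confidence level (default 0.90, the conventional twin-model choice).

    Attributes (after fit)
    ----------------------
    a2_, c2_, e2_ : standardized variance fractions.
    ci90_ : dict of (lower, upper) per fraction.
    loglik_, converged_, total_variance_, mean_ : fit diagnostics.
    """

    def __init__(self, compute_ci: bool = True, ci_level: float = 0.90):
        self.compute_ci = compute_ci
        self.ci_level = ci_level

    def get_params(self, deep: bool = True) -> dict:
        return {"compute_ci": self.compute_ci, "ci_level": self.ci_level}

    def set_params(self, **params) -> "ACEModel":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, mz_pairs, dz_pairs) -> "ACEModel":
        est = fit_ace(mz_pairs, dz_pairs, compute_ci=self.compute_ci,
                      ci_level=self.ci_level)
        self.estimate_ = est
        self.a2_, self.c2_, self.e2_ = est.a2, est.c2, est.e2
        self.total_variance_ = est.total_variance
        self.mean_ = est.mean
        self.loglik_ = est.loglik
        self.converged_ = est.converged
        self.ci90_ = est.ci90
        return self

    def fit_from_table(self, phenotypes) -> "ACEModel":
        """Fit from a long table (family_id, zygosity, phenotype)."""
        import pandas as pd

        df = pd.DataFrame(phenotypes)
        wide = []
        for zyg in ("MZ", "DZ"):
            sub = df[df["zygosity"] == zyg]
            pairs = (sub.sort_values(["family_id"])
                        .groupby("family_id")["phenotype"]
                        .apply(list))
            arr = np.array([p for p in pairs if len(p) == 2 and np.isfinite(p).all()])
            wide.append(arr)
        return self.fit(wide[0], wide[1])
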