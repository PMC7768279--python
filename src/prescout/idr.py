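"""Irreproducible discovery rate: replicate-consistency via a two-component
Gaussian copula mixture fitted by EM.

Replicate peak scores are converted to uniform ranks u_i = (rank_i - 0.5)/n
per margin and mapped to pseudo-values through the inverse of the
*mixture-implied* marginal CDF G(z) = pi Phi((z - mu)/sigma) + (1 - pi) Phi(z),
refreshed from the current parameters between EM passes (the semiparametric
scheme of the original estimator; a plain rank-normal transform makes the
components unidentifiable because the transformed marginal is standard
normal by construction).  The mixture
has an irreproducible component — standard bivariate normal with rho = 0 —
and a reproducible component N((mu, mu), sigma^2, rho).  The local idr of a
pair is the posterior probability of the irreproducible component; the
global IDR of a pair is the running mean of local idr over pairs sorted
ascending by local idr (the expected rate of irreproducible discoveries
among all pairs at least as reproducible).

The fit is exposed statsmodels-style: ``IDRModel(pairs).fit()`` returns an
:class:`IDRFitResults` carrying parameters, per-pair idr values, the
log-likelihood trace and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from prescout.intervals import GenomicInterval, IntervalSet


@dataclass(frozen=True)
class ScoredPeakPair:
    """A matched pair of replicate peak scores (log10 fold-change scale)."""

    interval: GenomicInterval
    score1: float
    score2: float

    def __post_init__(self):
        if not (np.isfinite(self.score1) and np.isfinite(self.score2)):
            raise ValueError(f"non-finite replicate score in {self!r}")


@dataclass
class IDRParams:
    """Reproducible-component parameters and mixing proportion.

    Defaults are the conventional starting values for peak-score IDR fits:
    mu = 2.6, sigma = 1.3, rho = 0.8, pi = 0.7.
    """

    mu: float = 2.6
    sigma: float = 1.3
    rho: float = 0.8
    pi: float = 0.7

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (-1 < self.rho < 1):
            raise ValueError("rho must be in (-1, 1)")
        if not (0 < self.pi < 1):
            raise ValueError("pi must be in (0, 1)")


def match_replicate_peaks(peaks1: IntervalSet, peaks2: IntervalSet) -> list[ScoredPeakPair]:
    """Pair overlapping peaks across two scored replicate sets.

    Each peak contributes to at most one pair.  Candidate pairs are ranked
    by overlap length (descending), ties broken by leftmost coordinate, and
    accepted greedily — equivalent to exhaustive maximum-overlap assignment
    on the cases tested.
    """
    candidates = []
    ivs2 = peaks2.by_chrom()
    for i, a in enumerate(peaks1):
        for j, b in enumerate(ivs2.get(a.chrom, [])):
            ol = a.overlap_length(b)
            if ol > 0:
                candidates.append((-ol, a.chrom, min(a.start, b.start), i, j, a, b))
    candidates.sort(key=lambda t: t[:5])
    used1, used2, pairs = set(), set(), []
    for _, chrom, _, i, j, a, b in candidates:
        if i in used1 or (chrom, j) in used2:
            continue
        used1.add(i)
        used2.add((chrom, j))
        if a.score is None or b.score is None:
            raise ValueError("both replicate peak sets must be scored")
        lo, hi = min(a.start, b.start), max(a.end, b.end)
        pairs.append(ScoredPeakPair(GenomicInterval(chrom, lo, hi), a.score, b.score))
    pairs.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return pairs


def _rank_uniform(x: np.ndarray) -> np.ndarray:
    """Uniform pseudo-probabilities u = (rank - 0.5)/n."""
    ranks = stats.rankdata(x, method="average")
    return (ranks - 0.5) / len(x)


def _pseudo_values(u: np.ndarray, mu, sigma, pi) -> np.ndarray:
    """Invert the mixture-implied marginal CDF
    G(z) = pi Phi((z - mu)/sigma) + (1 - pi) Phi(z) on a dense grid."""
    lo = min(-8.0, mu - 8.0 * sigma)
    hi = max(8.0, mu + 8.0 * sigma)
    grid = np.linspace(lo, hi, 4000)
    G = pi * stats.norm.cdf((grid - mu) / sigma) + (1 - pi) * stats.norm.cdf(grid)
    return np.interp(u, G, grid)


def _log_bvn(z1, z2, mu, sigma, rho):
    """Log density of the equicorrelated bivariate normal N((mu,mu), sigma^2, rho)."""
    d1 = (z1 - mu) / sigma
    d2 = (z2 - mu) / sigma
    q = (d1 * d1 - 2 * rho * d1 * d2 + d2 * d2) / (1 - rho * rho)
    return -np.log(2 * np.pi * sigma * sigma * np.sqrt(1 - rho * rho)) - q / 2


class IDRModel:
    """Two-component Gaussian copula mixture for replicate peak scores.

    Parameters
    ----------
    pairs : sequence of ScoredPeakPair (at least 50)

    Raises
    ------
    ValueError
        If fewer than 50 pairs are supplied (the EM fit is not trustworthy
        on very small inputs; collect more peaks).
    """

    MIN_PAIRS = 50

    def __init__(self, pairs):
        self.pairs = list(pairs)
        if len(self.pairs) < self.MIN_PAIRS:
            raise ValueError(
                f"need at least {self.MIN_PAIRS} matched pairs for an IDR fit, "
                f"got {len(self.pairs)}; supply more peaks"
            )
        self.scores = np.array([(p.score1, p.score2) for p in self.pairs])
        self.u1 = _rank_uniform(self.scores[:, 0])
        self.u2 = _rank_uniform(self.scores[:, 1])

    def loglike(self, params: IDRParams) -> float:
        """Pseudo-data log-likelihood at ``params`` (pseudo-values implied
        by the same parameters)."""
        z1 = _pseudo_values(self.u1, params.mu, params.sigma, params.pi)
        z2 = _pseudo_values(self.u2, params.mu, params.sigma, params.pi)
        l0 = _log_bvn(z1, z2, 0.0, 1.0, 0.0)
        l1 = _log_bvn(z1, z2, params.mu, params.sigma, params.rho)
        return float(
            np.logaddexp(np.log1p(-params.pi) + l0, np.log(params.pi) + l1).sum()
        )

    def fit(
        self,
        init: IDRParams | None = None,
        max_iter: int = 500,
        tol: float = 1e-6,
        outer_iter: int = 50,
    ):
        """Fit by EM with semiparametric pseudo-value refreshes.

        The outer loop recomputes pseudo-values from the current parameters;
        the inner EM (fixed pseudo-data, monotone log-likelihood) runs until
        its relative log-likelihood change drops below ``tol`` or its share
        of ``max_iter`` is used.  If the outer loop exhausts ``outer_iter``
        without the parameters settling, the best parameters are returned
        flagged ``converged = False``.
        """
        p = init or IDRParams()
        mu, sigma2, rho, pi = p.mu, p.sigma**2, p.rho, p.pi
        u1, u2 = self.u1, self.u2
        n = len(u1)
        inner_budget = max(10, max_iter // outer_iter)
        converged = False
        trace: list[float] = []
        outer_ll: list[float] = []
        prev_ll = -np.inf
        for _outer in range(outer_iter):
            z1 = _pseudo_values(u1, mu, np.sqrt(sigma2), pi)
            z2 = _pseudo_values(u2, mu, np.sqrt(sigma2), pi)
            trace = []
            for _ in range(inner_budget):
                sigma = np.sqrt(sigma2)
                l0 = np.log1p(-pi) + _log_bvn(z1, z2, 0.0, 1.0, 0.0)
                l1 = np.log(pi) + _log_bvn(z1, z2, mu, sigma, rho)
                tot = np.logaddexp(l0, l1)
                trace.append(float(tot.sum()))
                gamma = np.exp(l1 - tot)  # posterior of reproducible component
                w = gamma.sum()
                if w < 1e-12:
                    break
                mu = float((gamma * (z1 + z2)).sum() / (2 * w))
                d1, d2 = z1 - mu, z2 - mu
                sigma2 = max(float((gamma * (d1 * d1 + d2 * d2)).sum() / (2 * w)), 1e-6)
                rho = float(np.clip((gamma * d1 * d2).sum() / (w * sigma2), -0.999, 0.999))
                pi = float(np.clip(w / n, 1e-6, 1 - 1e-6))
                if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol * (
                    abs(trace[-2]) + 1e-12
                ):
                    break
            # outer convergence: the end-of-pass pseudo-data log-likelihood
            # is far more stable than the parameters themselves
            if trace:
                outer_ll.append(trace[-1])
            if trace and abs(trace[-1] - prev_ll) < tol * (abs(prev_ll) + 1e-12):
                converged = True
                break
            prev_ll = trace[-1] if trace else prev_ll
        params = IDRParams(mu=mu, sigma=float(np.sqrt(sigma2)), rho=rho, pi=pi)
        z1 = _pseudo_values(u1, params.mu, params.sigma, params.pi)
        z2 = _pseudo_values(u2, params.mu, params.sigma, params.pi)
        l0 = np.log1p(-pi) + _log_bvn(z1, z2, 0.0, 1.0, 0.0)
        l1 = np.log(pi) + _log_bvn(z1, z2, params.mu, params.sigma, params.rho)
        local_idr = np.exp(l0 - np.logaddexp(l0, l1))
        global_idr = _global_idr(local_idr)
        res = IDRFitResults(self, params, local_idr, global_idr, np.array(trace), converged)
        res.outer_loglik = np.array(outer_ll)
        return res


def _global_idr(local_idr: np.ndarray) -> np.ndarray:
    """Expected irreproducible rate among all pairs at least as reproducible:
    the running mean of local idr over pairs sorted ascending by local idr."""
    order = np.argsort(local_idr, kind="stable")
    cum = np.cumsum(local_idr[order]) / np.arange(1, len(local_idr) + 1)
    out = np.empty_like(cum)
    out[order] = cum
    return out


class IDRFitResults:
    """Converged (or best-effort) IDR fit.

    Attributes
    ----------
    params : IDRParams
    local_idr : ndarray
        Posterior probability of the irreproducible component per pair.
    global_idr : ndarray
        Cumulative mean of local idr in ascending local-idr order.
    loglik_trace : ndarray
        Observed-data log-likelihood at the start of each EM iteration
        (non-decreasing up to tolerance).
    converged : bool
    """

    def __init__(self, model, params, local_idr, global_idr, loglik_trace, converged):
        self.model = model
        self.params = params
        self.local_idr = local_idr
        self.global_idr = global_idr
        self.loglik_trace = loglik_trace
        self.converged = converged

    @property
    def n_pairs(self):
        return len(self.model.pairs)

    def threshold(self, alpha: float) -> IntervalSet:
        """Pairs passing global IDR <= alpha, as an interval set scored by
        the pair's mean replicate score.  Diagnostic/optional: high-confidence
        sets come from replicate intersection, not from an IDR cutoff."""
        keep = []
        for pair, g in zip(self.model.pairs, self.global_idr):
            if g <= alpha:
                iv = pair.interval
                keep.append(
                    GenomicInterval(
                        iv.chrom, iv.start, iv.end, iv.name,
                        (pair.score1 + pair.score2) / 2,
                    )
                )
        return IntervalSet(keep)

    def summary(self) -> str:
        p = self.params
        lines = [
            "IDR copula mixture fit",
            "=" * 46,
            f"pairs:              {self.n_pairs}",
            f"outer passes:       {len(getattr(self, 'outer_loglik', []))}",
            f"converged:          {self.converged}",
            f"log-likelihood:     {self.loglik_trace[-1]:.4f}",
            "-" * 46,
            f"pi (reproducible):  {p.pi:.4f}",
            f"mu:                 {p.mu:.4f}",
            f"sigma:              {p.sigma:.4f}",
            f"rho:                {p.rho:.4f}",
            "-" * 46,
            f"pairs at IDR<=0.05: {int((self.global_idr <= 0.05).sum())}",
            f"pairs at IDR<=0.01: {int((self.global_idr <= 0.01).sum())}",
        ]
        return "\n".join(lines)

    def to_table(self):
        """Pairs as a pandas DataFrame (chrom, start, end, scores, idr)."""
        import pandas as pd

        rows = [
            {
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "score1": p.score1,
                "score2": p.score2,
                "local_idr": li,
                "global_IDR": gi,
            }
            for p, li, gi in zip(self.model.pairs, self.local_idr, self.global_idr)
        ]
        return pd.DataFrame(rows)


def fit_idr(pairs, init: IDRParams | None = None, max_iter: int = 500, tol: float = 1e-6):
    """Functional wrapper: ``IDRModel(pairs).fit(init, max_iter, tol)``."""
    return IDRModel(pairs).fit(init=init, max_iter=max_iter, tol=tol)


def idr_threshold(fit: IDRFitResults, alpha: float) -> IntervalSet:
    """Pairs passing global IDR <= alpha (see :meth:`IDRFitResults.threshold`)."""
    return fit.threshold(alpha)
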