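"""The study-level inferential statistics, implemented from first principles.

Decision rules are written out explicitly — Fisher's exact test by
enumeration of the hypergeometric support with the point-probability
two-sided convention, Benjamini-Hochberg as the literal step-up, Tukey HSD
through the studentized-range distribution — with scipy supplying only the
underlying distribution functions.  Also houses the ChIP-qPCR ddCt fold
change and the normalized colocalization ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")


def fisher_exact_2x2(table: ContingencyTable2x2 | tuple) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    With margins fixed, the p-value sums hypergeometric point probabilities
    over every table whose probability is at most that of the observed one
    (point-probability convention), with a relative tolerance of 1e-7 on
    the probability comparison to absorb float ties.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(a, b, c, d)
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, n, k = a + b, a + b + c + d, a + c
    lo, hi = max(0, k - (n - r1)), min(k, r1)
    support = np.arange(lo, hi + 1)
    probs = sps.hypergeom.pmf(support, n, r1, k)
    p_obs = sps.hypergeom.pmf(a, n, r1, k)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum().clip(0, 1))


@dataclass(frozen=True)
class TTestResult:
    """A t statistic with its df and two-sided p; ``degenerate`` marks
    zero-variance input, where t and p are undefined (NaN)."""

    t: float
    df: int
    p: float
    degenerate: bool = False


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """One-sample two-sided t test of mean(values) against mu0."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    mean, sd = x.mean(), x.std(ddof=1)
    df = n - 1
    if sd == 0:
        if mean == mu0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.nan, df, math.nan, degenerate=True)
    t = (mean - mu0) / (sd / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p))


def paired_t(x, y) -> TTestResult:
    """Two-tailed paired t test (a one-sample t on the differences).

    Zero-variance differences (including x identical to y) are flagged
    degenerate: the statistic is undefined, not zero.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if d.size >= 2 and d.std(ddof=1) == 0:
        return TTestResult(math.nan, d.size - 1, math.nan, degenerate=True)
    return one_sample_t(d, 0.0)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    tukey: "list[tuple[int, int, float, float]]"  # (i, j, mean diff, adj p)


def anova_oneway_tukey(groups) -> AnovaResult:
    """One-way ANOVA with Tukey-adjusted pairwise comparisons.

    The F statistic is the between/within mean-square ratio; pairwise
    adjusted p-values come from the studentized range distribution with the
    Tukey-Kramer standard error (exact Tukey HSD at equal n).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    k = len(gs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.size for g in gs])
    if np.any(ns < 2):
        raise ValueError("each group needs at least 2 observations")
    means = np.array([g.mean() for g in gs])
    n_tot = ns.sum()
    grand = np.concatenate(gs).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(gs, means)))
    df_b, df_w = k - 1, int(n_tot - k)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        F = 0.0 if ms_b == 0 else math.inf
        p = 1.0 if ms_b == 0 else 0.0
    else:
        F = ms_b / ms_w
        p = float(sps.f.sf(F, df_b, df_w))
    tukey = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            if ms_w == 0:
                padj = 1.0 if diff == 0 else 0.0
            else:
                se = math.sqrt(ms_w / 2 * (1 / ns[i] + 1 / ns[j]))
                q = abs(diff) / se
                padj = float(sps.studentized_range.sf(q, k, df_w))
            tukey.append((i, j, float(diff), padj))
    return AnovaResult(float(F), df_b, df_w, p, tukey)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


# ---------------------------------------------------------------------------
# ChIP-qPCR ddCt and cell-count normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QPCRMeasurement:
    """Averaged Ct values for one sample: target and control loci measured
    in the ChIP fraction and the matched input fraction."""

    ct_chip_target: float
    ct_chip_control: float
    ct_input_target: float
    ct_input_control: float

    def __post_init__(self):
        for v in (self.ct_chip_target, self.ct_chip_control,
                  self.ct_input_target, self.ct_input_control):
            if not math.isfinite(v):
                raise ValueError("Ct values must be finite")

    @property
    def ddct(self) -> float:
        """ddCt = dCt(ChIP) - dCt(input), with dCt = Ct(target) - Ct(control)."""
        dct_chip = self.ct_chip_target - self.ct_chip_control
        dct_input = self.ct_input_target - self.ct_input_control
        return dct_chip - dct_input

    @property
    def fold_enrichment(self) -> float:
        """Fold enrichment over input = 2^(-ddCt)."""
        return 2.0 ** (-self.ddct)


def ddct_log2_ratio(cin: QPCRMeasurement, noncin: QPCRMeasurement) -> float:
    """log2 of (CIN fold enrichment / non-CIN fold enrichment).

    Equals ddCt(non-CIN) - ddCt(CIN): positive for CIN-enriched loci,
    negative for non-CIN-enriched loci.
    """
    return noncin.ddct - cin.ddct


def normalized_colocalization(
    eyfp_marker: int, eyfp_total: int, tdt_marker: int, tdt_total: int
) -> float:
    """(EYFP+ marker+ / total EYFP+) / (tdTomato+ marker+ / total tdTomato+).

    1.0 means the marker is represented among transduced cells exactly as in
    the reference interneuron population.
    """
    if eyfp_total <= 0 or tdt_total <= 0:
        raise ValueError("total cell counts must be positive")
    if tdt_marker <= 0:
        raise ValueError("reference marker count must be positive for a finite ratio")
    return (eyfp_marker / eyfp_total) / (tdt_marker / tdt_total)
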