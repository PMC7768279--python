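"""Enrichment peak calling and two-condition differential classification.

A deliberately simple, desk-scale stand-in for the broad-peak workflow used
for histone-modification ChIP-seq: per-bin Poisson upper-tail tests against a
locally corrected input expectation with a genome-wide Benjamini-Hochberg
FDR, broad-peak linking, and a signed per-bin Poisson log10 likelihood ratio
(LLR10) between two conditions with a minimum emitted region length.

Coverage lives in fixed-width bins per chromosome (:class:`CoverageTrack`),
raw fragment-overlap counts or RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from prescout.intervals import GenomicInterval, IntervalSet, intersect, subtract, union


class TrackError(ValueError):
    """Raised on invalid or incompatible coverage tracks."""


class CoverageTrack:
    """Fixed-bin per-chromosome genome coverage.

    Parameters
    ----------
    data : mapping of chrom -> 1-D array of non-negative bin values
    bin_size : int
        Bin width in bp.
    total_fragments : int, optional
        Library size used for depth scaling and RPKM.  Defaults to the sum
        of all bin values (exact when fragments span a single bin).
    normalized : bool
        True once values are RPKM rather than raw counts.
    """

    def __init__(self, data, bin_size, total_fragments=None, normalized=False):
        if bin_size <= 0:
            raise TrackError(f"bin_size must be positive, got {bin_size}")
        self.data = {c: np.asarray(v, dtype=float) for c, v in data.items()}
        for chrom, v in self.data.items():
            if v.ndim != 1:
                raise TrackError(f"{chrom}: bin vector must be 1-D")
            if np.any(v < 0):
                raise TrackError(f"{chrom}: negative bin values")
        self.bin_size = int(bin_size)
        if total_fragments is None:
            total_fragments = float(sum(v.sum() for v in self.data.values()))
        self.total_fragments = float(total_fragments)
        self.normalized = bool(normalized)

    @property
    def chroms(self):
        return sorted(self.data)

    def n_bins(self):
        return int(sum(len(v) for v in self.data.values()))

    def genome_mean(self):
        n = self.n_bins()
        return float(sum(v.sum() for v in self.data.values()) / n) if n else 0.0

    def copy(self):
        return CoverageTrack(
            {c: v.copy() for c, v in self.data.items()},
            self.bin_size,
            self.total_fragments,
            self.normalized,
        )

    def _check_compatible(self, other: "CoverageTrack"):
        if self.bin_size != other.bin_size:
            raise TrackError(
                f"bin size mismatch: {self.bin_size} vs {other.bin_size}"
            )
        if self.chroms != other.chroms:
            raise TrackError("chromosome sets differ between tracks")
        for c in self.chroms:
            if len(self.data[c]) != len(other.data[c]):
                raise TrackError(f"{c}: bin counts differ between tracks")


@dataclass
class PeakCallConfig:
    """Thresholds for calling and differential classification.

    q_cutoff / broad_cutoff : genome-wide BH FDR for peak cores and for
        broad linking (defaults 0.01 / 0.01).
    fragment_extension : fragment span laid down by the simulator, bp.
    min_diff_length : minimum emitted differential region, bp (default 150).
    diff_llr10_cutoff : per-bin |LLR10| threshold (default 3.0).
    local_lambda_window : window for the local input mean, bp.
    """

    q_cutoff: float = 0.01
    broad_cutoff: float = 0.01
    fragment_extension: int = 200
    min_diff_length: int = 150
    diff_llr10_cutoff: float = 3.0
    local_lambda_window: int = 1000

    def __post_init__(self):
        if not (0 < self.q_cutoff <= 1) or not (0 < self.broad_cutoff <= 1):
            raise ValueError("q_cutoff and broad_cutoff must be in (0, 1]")
        if self.q_cutoff > self.broad_cutoff:
            raise ValueError("q_cutoff must not exceed broad_cutoff")
        if self.min_diff_length <= 0 or self.fragment_extension <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class DifferentialResult:
    """Three mutually disjoint peak classes from a two-condition comparison."""

    enriched_in_1: IntervalSet
    enriched_in_2: IntervalSet
    common: IntervalSet

    def classes(self):
        return {
            "cond1_enriched": self.enriched_in_1,
            "cond2_enriched": self.enriched_in_2,
            "common": self.common,
        }


def normalize_rpkm(track: CoverageTrack) -> CoverageTrack:
    """Reads/fragments per kilobase of bin per million fragments.

    value = count / (bin_size/1000 * total_fragments/1e6).
    """
    if track.normalized:
        raise TrackError("track is already RPKM-normalized")
    if track.total_fragments <= 0:
        if all(v.sum() == 0 for v in track.data.values()):
            return CoverageTrack(
                {c: v.copy() for c, v in track.data.items()},
                track.bin_size,
                track.total_fragments,
                normalized=True,
            )
        raise TrackError("total_fragments must be positive for RPKM")
    denom = (track.bin_size / 1000.0) * (track.total_fragments / 1e6)
    return CoverageTrack(
        {c: v / denom for c, v in track.data.items()},
        track.bin_size,
        track.total_fragments,
        normalized=True,
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (vector in, vector out)."""
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def _local_lambda(control: CoverageTrack, window_bp: int) -> dict[str, np.ndarray]:
    """Per-bin expected count from the control: max of the bin value, a
    sliding local window mean, and the genome-wide mean (bias floor)."""
    gmean = control.genome_mean()
    w = max(1, int(round(window_bp / control.bin_size)))
    out = {}
    for chrom, v in control.data.items():
        if w > 1 and len(v) >= 1:
            kernel = np.ones(w) / w
            local = np.convolve(v, kernel, mode="same")
        else:
            local = v
        out[chrom] = np.maximum.reduce([v, local, np.full_like(v, gmean)])
    return out


def call_peaks(
    treatment: CoverageTrack,
    control: CoverageTrack,
    cfg: PeakCallConfig | None = None,
    broad: bool = True,
) -> IntervalSet:
    """Call enrichment peaks in ``treatment`` against a matched ``control``.

    Per bin the expected count is the depth-scaled local control expectation;
    the p-value is the Poisson upper tail P(X >= k); q-values come from one
    genome-wide BH pass over all bins.  Core bins satisfy ``q <= q_cutoff``;
    with ``broad=True`` cores are extended through contiguous bins with
    ``q <= broad_cutoff``.  Emitted peaks carry max -log10(q) as score.
    """
    cfg = cfg or PeakCallConfig()
    treatment._check_compatible(control)
    if control.total_fragments <= 0:
        raise TrackError("control library size must be positive")
    scale = treatment.total_fragments / control.total_fragments
    lam = _local_lambda(control, cfg.local_lambda_window)

    pvals, keys = [], []
    for chrom in treatment.chroms:
        k = treatment.data[chrom]
        lam_c = np.maximum(lam[chrom] * scale, 1e-9)
        # P(X >= k) for Poisson; sf(k-1) == sf at ceil(k)-1 for integer k
        p = stats.poisson.sf(np.ceil(k) - 1, lam_c)
        pvals.append(p)
        keys.append(chrom)
    q_by_chrom = {}
    flat = np.concatenate(pvals) if pvals else np.array([])
    qflat = _bh_adjust(flat) if flat.size else flat
    pos = 0
    for chrom, p in zip(keys, pvals):
        q_by_chrom[chrom] = qflat[pos : pos + p.size]
        pos += p.size

    peaks = []
    bs = treatment.bin_size
    for chrom in treatment.chroms:
        q = q_by_chrom[chrom]
        core = q <= cfg.q_cutoff
        link = q <= (cfg.broad_cutoff if broad else cfg.q_cutoff)
        for lo, hi in _runs(link):
            if not core[lo:hi].any():
                continue
            score = float(-np.log10(max(q[lo:hi].min(), 1e-300)))
            peaks.append(GenomicInterval(chrom, lo * bs, hi * bs, None, score))
    return IntervalSet(peaks, merged=True)


def score_peaks_log10_fold(
    treatment: CoverageTrack,
    control: CoverageTrack,
    peaks: IntervalSet,
) -> IntervalSet:
    """Rescore peaks with log10 fold enrichment over the depth-scaled
    control mean — the continuous score replicate-consistency analysis
    expects (q-value scores saturate and tie on strong peaks)."""
    treatment._check_compatible(control)
    scale = treatment.total_fragments / max(control.total_fragments, 1e-9)
    gmean = max(control.genome_mean(), 1e-9)
    bs = treatment.bin_size
    rescored = []
    for iv in peaks:
        b0, b1 = iv.start // bs, max(iv.start // bs + 1, -(-iv.end // bs))
        t_mean = float(treatment.data[iv.chrom][b0:b1].mean())
        c_mean = float(control.data[iv.chrom][b0:b1].mean())
        lam = scale * max(c_mean, gmean)
        fold = (t_mean + 0.5) / (lam + 0.5)
        rescored.append(
            GenomicInterval(iv.chrom, iv.start, iv.end, iv.name, float(np.log10(fold)))
        )
    return IntervalSet(rescored, genome=peaks.genome, merged=peaks.merged)


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of contiguous True runs."""
    if mask.size == 0:
        return
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for lo, hi in zip(edges[::2], edges[1::2]):
        yield int(lo), int(hi)


def _llr10(k1: np.ndarray, k2: np.ndarray) -> np.ndarray:
    """Signed per-bin Poisson log10 likelihood ratio.

    LLR10 = log10[ Pois(k1; k1+) Pois(k2; k2+) / (Pois(k1; m) Pois(k2; m)) ]
    with m = (k1+k2)/2 and a pseudocount floor of 1 on each rate; the
    log-Gamma normalisation cancels in the ratio.  Sign follows k1 - k2.
    """
    k1p = np.maximum(k1, 1.0)
    k2p = np.maximum(k2, 1.0)
    m = np.maximum((k1 + k2) / 2.0, 1.0)
    ll = (
        k1 * np.log(k1p)
        - k1p
        + k2 * np.log(k2p)
        - k2p
        - (k1 + k2) * np.log(m)
        + 2.0 * m
    ) / np.log(10.0)
    return np.sign(k1 - k2) * np.abs(ll)


def classify_differential(
    cond1: CoverageTrack,
    cond2: CoverageTrack,
    cfg: PeakCallConfig | None = None,
    control: CoverageTrack | None = None,
) -> DifferentialResult:
    """Split the genome into condition-1-enriched, condition-2-enriched and
    common peak regions.

    Counts are depth-scaled to the smaller library.  Contiguous same-sign
    runs with |LLR10| >= ``diff_llr10_cutoff`` and total length >=
    ``min_diff_length`` become enriched regions (score = max |LLR10|).
    Bins called as peaks against a shared input in *both* conditions but
    falling below the differential cutoff form the ``common`` class; with no
    input track supplied, a flat pseudo-control at the pooled genome-wide
    mean stands in for it.
    """
    cfg = cfg or PeakCallConfig()
    cond1._check_compatible(cond2)
    if cond1.n_bins() == 0:
        raise TrackError("zero-length coverage tracks")
    t1, t2 = cond1.total_fragments, cond2.total_fragments
    if t1 <= 0 or t2 <= 0:
        raise TrackError("both library sizes must be positive")
    tmin = min(t1, t2)
    s1, s2 = tmin / t1, tmin / t2

    bs = cond1.bin_size
    enr1, enr2 = [], []
    for chrom in cond1.chroms:
        k1 = cond1.data[chrom] * s1
        k2 = cond2.data[chrom] * s2
        llr = _llr10(k1, k2)
        for sign, bucket in ((1, enr1), (-1, enr2)):
            mask = sign * llr >= cfg.diff_llr10_cutoff
            for lo, hi in _runs(mask):
                if (hi - lo) * bs < cfg.min_diff_length:
                    continue
                score = float(np.abs(llr[lo:hi]).max())
                bucket.append(GenomicInterval(chrom, lo * bs, hi * bs, None, score))

    set1 = IntervalSet(enr1, merged=True)
    set2 = IntervalSet(enr2, merged=True)

    if control is None:
        pooled_mean = (
            sum((cond1.data[c] * s1 + cond2.data[c] * s2).sum() for c in cond1.chroms)
            / (2 * cond1.n_bins())
        )
        control = CoverageTrack(
            {c: np.full(len(cond1.data[c]), pooled_mean) for c in cond1.chroms},
            bs,
            total_fragments=tmin,
        )
    peaks1 = call_peaks(_scaled(cond1, s1), control, cfg, broad=True)
    peaks2 = call_peaks(_scaled(cond2, s2), control, cfg, broad=True)
    shared = intersect(peaks1, peaks2)
    common = subtract(shared, union([set1, set2]))
    return DifferentialResult(set1, set2, common)


def _scaled(track: CoverageTrack, s: float) -> CoverageTrack:
    return CoverageTrack(
        {c: v * s for c, v in track.data.items()},
        track.bin_size,
        total_fragments=track.total_fragments * s,
        normalized=track.normalized,
    )


# ---------------------------------------------------------------------------
# bedGraph I/O (fixed-step)
# ---------------------------------------------------------------------------

def read_bedgraph(path, bin_size=None) -> CoverageTrack:
    """Read a fixed-step bedGraph (chrom, start, end, value) into a track.

    Every record must span exactly one bin; gaps are zero-filled.  The bin
    size is inferred from the first record unless given.
    """
    data: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise TrackError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            width = end - start
            if bin_size is None:
                bin_size = width
            if width != bin_size or start % bin_size:
                raise TrackError(
                    f"{path}:{lineno}: record not aligned to fixed {bin_size} bp step"
                )
            data.setdefault(chrom, {})[start // bin_size] = value
    arrays = {}
    for chrom, bins in data.items():
        n = max(bins) + 1
        v = np.zeros(n)
        v[list(bins)] = list(bins.values())
        arrays[chrom] = v
    return CoverageTrack(arrays, bin_size or 1)


def write_bedgraph(track: CoverageTrack, path, write_zero=False) -> None:
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in track.chroms:
            v = track.data[chrom]
            idx = range(len(v)) if write_zero else np.flatnonzero(v)
            for i in idx:
                fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{v[i]:g}\n")
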