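"""Synthetic data with known ground truth for every pipeline stage.

Every generator is a pure function of its specification and a seed.  The
coverage simulator emulates the two-condition (CIN vs non-CIN),
two-replicate histone ChIP design: Poisson fragment starts on a toy genome
with multiplicative enrichment planted in condition-specific and shared
regions, each fragment laid down as a 200 bp span.  The electrophysiology
generator is template-based — every feature the analysis extracts has an
exactly programmed value — rather than a conductance model, so recovery
tests have unambiguous truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from prescout.ephys import CellPhysiology, APFeatures, SweepSet, classify_fs_rs
from prescout.idr import ScoredPeakPair
from prescout.intervals import GenomicInterval, IntervalSet
from prescout.peaks import CoverageTrack
from prescout.stats import QPCRMeasurement

# ---------------------------------------------------------------------------
# Coverage tracks with planted enrichment
# ---------------------------------------------------------------------------

@dataclass
class PlantedRegion:
    interval: GenomicInterval
    specificity: str  # "cond1" | "cond2" | "shared"
    fold: float


@dataclass
class SimulationDesign:
    """The stated world for the coverage simulation.

    Defaults describe a desk-scale version of the study design: a 2 Mb toy
    genome in 50 bp bins, fragment-start rate 2 per bin (~8x base coverage
    after 200 bp extension), 20 condition-1-specific, 20 condition-2-specific
    and 40 shared enriched regions of 1.5-3 kb at 8-12x fold, two replicates
    with slightly different depths.
    """

    genome: dict = field(default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})
    bin_size: int = 50
    background_rate: float = 2.0  # fragment starts per bin
    fragment_extension: int = 200  # bp
    n_cond1: int = 20
    n_cond2: int = 20
    n_shared: int = 40
    region_length: tuple = (1500, 3000)
    fold_range: tuple = (8.0, 12.0)
    min_separation: int = 5000
    depth_factors: tuple = (1.0, 0.85)  # per replicate
    seed: int = 0


@dataclass
class CoverageSimulation:
    """Simulated tracks plus the planted truth."""

    design: SimulationDesign
    tracks: dict  # (condition, replicate) -> CoverageTrack, condition in {1, 2}
    inputs: dict  # replicate -> CoverageTrack
    regions: list  # PlantedRegion
    truth: dict  # class name -> IntervalSet

    def truth_bed(self, path):
        from prescout.intervals import write_bed

        ivs = [
            GenomicInterval(r.interval.chrom, r.interval.start, r.interval.end,
                            r.specificity, r.fold)
            for r in self.regions
        ]
        write_bed(IntervalSet(ivs), path)


def _plant_regions(design: SimulationDesign, rng: np.random.Generator) -> list[PlantedRegion]:
    labels = (
        ["cond1"] * design.n_cond1
        + ["cond2"] * design.n_cond2
        + ["shared"] * design.n_shared
    )
    chroms = sorted(design.genome)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    regions = []
    for lab in labels:
        for _ in range(10_000):
            chrom = chroms[rng.integers(len(chroms))]
            length = int(rng.integers(design.region_length[0], design.region_length[1] + 1))
            length = max(design.bin_size, (length // design.bin_size) * design.bin_size)
            start = int(rng.integers(0, design.genome[chrom] - length))
            start = (start // design.bin_size) * design.bin_size
            end = start + length
            sep = design.min_separation
            if all(end + sep <= s or e + sep <= start for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                fold = float(rng.uniform(*design.fold_range))
                regions.append(PlantedRegion(GenomicInterval(chrom, start, end), lab, fold))
                break
        else:
            raise RuntimeError("could not place planted regions; genome too small")
    return regions


def gen_coverage(design: SimulationDesign | None = None, seed: int | None = None) -> CoverageSimulation:
    """Simulate per-condition, per-replicate treatment tracks and matched
    inputs with planted multiplicative enrichment.

    Fragment starts per bin are Poisson(background x depth x fold); each
    fragment covers ``fragment_extension`` bp downstream, so bin coverage is
    the rolling sum of starts over the extension window.
    """
    design = design or SimulationDesign()
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    regions = _plant_regions(design, rng)
    ext_bins = max(1, design.fragment_extension // design.bin_size)
    kernel = np.ones(ext_bins)

    fold_maps = {}
    for cond in (1, 2):
        fm = {
            c: np.ones(design.genome[c] // design.bin_size)
            for c in design.genome
        }
        for r in regions:
            if r.specificity in (f"cond{cond}", "shared"):
                b0 = r.interval.start // design.bin_size
                b1 = r.interval.end // design.bin_size
                fm[r.interval.chrom][b0:b1] = r.fold
        fold_maps[cond] = fm

    tracks, inputs = {}, {}
    for rep, depth in enumerate(design.depth_factors, start=1):
        for cond in (1, 2):
            data, total = {}, 0.0
            for chrom, fm in fold_maps[cond].items():
                starts = rng.poisson(design.background_rate * depth * fm)
                total += starts.sum()
                cov = np.convolve(starts, kernel)[: len(fm)]
                data[chrom] = cov
            tracks[(cond, rep)] = CoverageTrack(data, design.bin_size, total_fragments=total)
        data, total = {}, 0.0
        for chrom in sorted(design.genome):
            n = design.genome[chrom] // design.bin_size
            starts = rng.poisson(design.background_rate * depth, size=n)
            total += starts.sum()
            data[chrom] = np.convolve(starts, kernel)[:n]
        inputs[rep] = CoverageTrack(data, design.bin_size, total_fragments=total)

    truth = {
        "cond1_enriched": IntervalSet(
            [r.interval for r in regions if r.specificity == "cond1"], genome=design.genome
        ),
        "cond2_enriched": IntervalSet(
            [r.interval for r in regions if r.specificity == "cond2"], genome=design.genome
        ),
        "common": IntervalSet(
            [r.interval for r in regions if r.specificity == "shared"], genome=design.genome
        ),
    }
    return CoverageSimulation(design, tracks, inputs, regions, truth)


# ---------------------------------------------------------------------------
# IDR score pairs from the copula mixture
# ---------------------------------------------------------------------------

def gen_idr_pairs(pi=0.7, rho=0.8, mu=2.6, sigma=1.3, n=2000, seed=0):
    """Replicate score pairs from the two-component Gaussian mixture.

    Reproducible pairs (probability ``pi``) are bivariate normal with mean
    (mu, mu), SD sigma and correlation rho; irreproducible pairs are
    standard bivariate normal with zero correlation.

    Returns (pairs, labels) with labels[i] = 1 for the reproducible component.
    """
    rng = np.random.default_rng(seed)
    labels = rng.random(n) < pi
    z = rng.standard_normal((n, 2))
    # correlate the reproducible draws
    z_rep = np.empty_like(z)
    z_rep[:, 0] = z[:, 0]
    z_rep[:, 1] = rho * z[:, 0] + np.sqrt(1 - rho * rho) * z[:, 1]
    scores = np.where(labels[:, None], mu + sigma * z_rep, z)
    pairs = [
        ScoredPeakPair(
            GenomicInterval("chr1", 1000 * i, 1000 * i + 500),
            float(scores[i, 0]),
            float(scores[i, 1]),
        )
        for i in range(n)
    ]
    return pairs, labels.astype(int)


# ---------------------------------------------------------------------------
# Sequences with planted motifs
# ---------------------------------------------------------------------------

def gen_motif_sequences(
    n_target=500,
    n_background=500,
    motif_consensus="TAATTA",
    target_rate=0.4,
    background_rate=0.05,
    length=200,
    seed=0,
):
    """FASTA-style record lists with motif occurrences planted at controlled
    per-sequence rates (one planted copy, random strand and position).

    Returns (targets, background, truth) where truth maps record name -> bool
    (planted or not).  Background sequence is uniform ACGT, so chance
    occurrences add to the planted rate exactly as in real data.
    """
    from prescout.enrichment import IUPAC, reverse_complement

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def concrete(consensus):
        return "".join(rng.choice(list(IUPAC[c])) for c in consensus)

    def make(n, rate, prefix):
        records, truth = [], {}
        for i in range(n):
            seq = "".join(rng.choice(bases, size=length))
            planted = bool(rng.random() < rate)
            if planted:
                site = concrete(motif_consensus)
                if rng.random() < 0.5:
                    site = reverse_complement(site)
                pos = int(rng.integers(0, length - len(site) + 1))
                seq = seq[:pos] + site + seq[pos + len(site):]
            name = f"{prefix}{i}"
            records.append((name, seq))
            truth[name] = planted
        return records, truth

    targets, t_truth = make(n_target, target_rate, "t")
    background, b_truth = make(n_background, background_rate, "b")
    return targets, background, {**t_truth, **b_truth}


# ---------------------------------------------------------------------------
# Template-based current-clamp cells
# ---------------------------------------------------------------------------

@dataclass
class EphysTemplateSpec:
    """Programmed ground truth for one synthetic cell.

    FS presets satisfy all four classifier criteria with margin; RS presets
    satisfy none.  Waveform shape parameters (ramp, rise/fall times) are
    derived from the programmed features so the extracted values have exact
    targets.
    """

    cell_class: str  # "FS" | "RS"
    threshold: float  # mV
    amplitude: float  # mV
    half_width: float  # ms
    fahp: float  # mV
    rheobase: float  # pA
    fi_gain: float  # Hz per pA above rheobase
    sfa: float  # programmed last/first ISI ratio
    rmp: float = -70.0  # mV
    r_mohm: float = 150.0
    tau_ms: float = 10.0
    noise_sd: float = 0.3  # mV


def fs_template_spec(rng: np.random.Generator) -> EphysTemplateSpec:
    """A fast-spiking basket-cell-like preset with per-cell variability."""
    return EphysTemplateSpec(
        cell_class="FS",
        threshold=float(rng.normal(-42.0, 1.5)),
        amplitude=float(rng.normal(80.0, 4.0)),
        half_width=float(np.clip(rng.normal(0.30, 0.04), 0.20, 0.42)),
        fahp=float(np.clip(rng.normal(20.0, 1.5), 17.0, 25.0)),
        rheobase=float(rng.choice([75.0, 100.0, 125.0])),
        fi_gain=float(rng.normal(0.30, 0.03)),
        sfa=float(rng.uniform(1.1, 1.6)),
        rmp=float(rng.normal(-70.0, 2.0)),
        r_mohm=float(rng.normal(150.0, 20.0)),
        tau_ms=float(rng.normal(10.0, 1.0)),
    )


def rs_template_spec(rng: np.random.Generator) -> EphysTemplateSpec:
    """A regular-spiking (adapting, broad-AP) preset with variability."""
    return EphysTemplateSpec(
        cell_class="RS",
        threshold=float(rng.normal(-44.0, 1.5)),
        amplitude=float(rng.normal(70.0, 4.0)),
        half_width=float(np.clip(rng.normal(0.80, 0.10), 0.60, 1.10)),
        fahp=float(np.clip(rng.normal(8.0, 1.5), 4.0, 11.0)),
        rheobase=float(rng.choice([75.0, 100.0])),
        fi_gain=float(np.clip(rng.normal(0.08, 0.01), 0.05, 0.105)),
        sfa=float(rng.uniform(2.8, 4.0)),
        rmp=float(rng.normal(-68.0, 2.0)),
        r_mohm=float(rng.normal(180.0, 25.0)),
        tau_ms=float(rng.normal(15.0, 1.5)),
    )


@dataclass
class EphysProtocol:
    sampling_rate: float = 50_000.0  # Hz
    stim_onset: float = 0.2  # s
    stim_duration: float = 0.8  # s (firing protocol)
    tail: float = 0.1  # s after the step
    currents: tuple = tuple(float(c) for c in range(25, 501, 25))  # pA


RIN_PROTOCOL = EphysProtocol(
    stim_duration=0.5, currents=tuple(float(c) for c in range(-50, 21, 10))
)


def _planned_spike_counts(spec: EphysTemplateSpec, protocol: EphysProtocol):
    """Deterministic f-I rule: count = round(gain * (I - rheobase) * T) for
    I >= rheobase, at least 1."""
    counts = {}
    for cur in protocol.currents:
        if cur < spec.rheobase:
            counts[cur] = 0
        else:
            counts[cur] = max(
                1, int(round(spec.fi_gain * (cur - spec.rheobase) * protocol.stim_duration))
            )
    return counts


def _spike_peak_times(n, spec, protocol):
    """Peak times for n spikes in the step window; geometric ISIs so that
    last/first ISI equals the programmed SFA exactly (needs n >= 3)."""
    t0 = protocol.stim_onset + 0.020
    span = protocol.stim_duration - 0.040
    if n == 1:
        return np.array([t0])
    if n == 2:
        return np.array([t0, t0 + span / 2])
    q = spec.sfa ** (1.0 / (n - 2))
    isis = q ** np.arange(n - 1)
    isis = isis * (span / isis.sum())
    return t0 + np.concatenate([[0.0], np.cumsum(isis)])


def gen_ephys_cell(
    spec: EphysTemplateSpec,
    protocol: EphysProtocol | None = None,
    seed: int = 0,
) -> tuple[SweepSet, CellPhysiology]:
    """Render a cell's firing-protocol sweep set plus its programmed truth.

    Subthreshold response is an RC step (V = rmp + I R (1 - e^(-t/tau)))
    clipped 5 mV below threshold; each spike is a piecewise-linear waveform
    (slow 1.5 ms ramp to threshold, fast linear rise to the peak, linear
    fall to the fAHP trough, exponential recovery) whose rise/fall times are
    chosen so the half-width at half amplitude equals the programmed value.
    Gaussian noise of ``noise_sd`` mV is added throughout.
    """
    protocol = protocol or EphysProtocol()
    rng = np.random.default_rng(seed)
    fs = protocol.sampling_rate
    n_samp = int(round((protocol.stim_onset + protocol.stim_duration + protocol.tail) * fs))
    t = np.arange(n_samp) / fs
    on, dur = protocol.stim_onset, protocol.stim_duration

    theta, A, F = spec.threshold, spec.amplitude, spec.fahp
    hw_s = spec.half_width / 1000.0
    t_ramp = 1.5e-3
    t_rise = hw_s  # rising half-crossing sits t_rise/2 before the peak
    t_fall = hw_s * (A + F) / A  # falling half-crossing t_fall*A/(2(A+F)) after
    tau_rec = 2e-3

    counts = _planned_spike_counts(spec, protocol)
    sweeps = []
    for cur in protocol.currents:
        i_na = cur / 1000.0
        v = np.full(n_samp, spec.rmp)
        in_step = (t >= on) & (t < on + dur)
        dt_step = t[in_step] - on
        v[in_step] = spec.rmp + i_na * spec.r_mohm * (1 - np.exp(-dt_step * 1000.0 / spec.tau_ms))
        after = t >= on + dur
        v_end = spec.rmp + i_na * spec.r_mohm * (1 - np.exp(-dur * 1000.0 / spec.tau_ms))
        v[after] = spec.rmp + (v_end - spec.rmp) * np.exp(-(t[after] - on - dur) * 1000.0 / spec.tau_ms)
        n_spk = counts[cur]
        if n_spk == 0:
            v = np.minimum(v, theta - 5.0)
        else:
            # spiking sweeps ride a fast depolarized plateau held safely
            # above the fAHP trough so the programmed trough is the minimum
            plateau = theta - min(4.0, 0.8 * F)
            v_base = np.full(n_samp, spec.rmp)
            tau_dep = 5e-3
            v_base[in_step] = spec.rmp + (plateau - spec.rmp) * (
                1 - np.exp(-dt_step / tau_dep)
            )
            v_base[after] = spec.rmp + (plateau - spec.rmp) * np.exp(
                -(t[after] - on - dur) * 1000.0 / spec.tau_ms
            )
            v = v_base.copy()
            for tp in _spike_peak_times(n_spk, spec, protocol):
                i_p = int(round(tp * fs))
                i_0 = int(round((tp - t_rise) * fs))
                i_r = int(round((tp - t_rise - t_ramp) * fs))
                i_f = int(round((tp + t_fall) * fs))
                i_e = min(n_samp, i_f + int(round(8 * tau_rec * fs)))
                if i_r < 0 or i_f >= n_samp:
                    continue
                base_at = v_base[i_r]
                v[i_r:i_0] = np.linspace(base_at, theta, max(1, i_0 - i_r), endpoint=False)
                v[i_0:i_p] = theta + (A) * (np.arange(i_p - i_0) / max(1, i_p - i_0))
                v[i_p] = theta + A
                fall_n = i_f - i_p
                v[i_p:i_f] = (theta + A) + (-(A + F)) * (np.arange(fall_n) / max(1, fall_n))
                v[i_f] = theta - F
                rec_t = (np.arange(i_e - i_f)) / fs
                v[i_f:i_e] = v_base[i_f:i_e] + (theta - F - v_base[i_f:i_e]) * np.exp(
                    -rec_t / tau_rec
                )
        v = v + rng.normal(0.0, spec.noise_sd, size=n_samp)
        sweeps.append(v)

    sweep_set = SweepSet(fs, on, dur, list(protocol.currents), np.vstack(sweeps))

    max_count = max(counts.values())
    maxf = max_count / dur if max_count else None
    best = max(counts, key=lambda c: (counts[c], -c))
    truth = CellPhysiology(
        rmp=spec.rmp,
        rin=spec.r_mohm,
        rheobase=spec.rheobase if max_count else None,
        firing_counts=dict(counts),
        max_firing_frequency=maxf,
        sfa=spec.sfa if counts[best] >= 3 else None,
        ap=APFeatures(theta, A / (t_rise * 1000.0), A, spec.half_width, F),
    )
    truth.classification, truth.criteria_met = classify_fs_rs(
        spec.half_width, maxf if maxf is not None else 0.0, F,
        truth.sfa,
    )
    return sweep_set, truth


def gen_rin_sweeps(spec: EphysTemplateSpec, seed: int = 0) -> SweepSet:
    """Subthreshold -50..+20 pA (step 10) protocol for RMP/Rin analysis."""
    sweeps, _ = gen_ephys_cell(
        replace(spec, rheobase=1e9), RIN_PROTOCOL, seed=seed
    )
    return sweeps


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def gen_qpcr(true_log2_ratios: dict, ct_noise_sd: float = 0.0, seed: int = 0):
    """Ct tables whose noise-free ddCt log2 ratio equals the stated truth.

    ``true_log2_ratios`` maps locus name -> true log2(CIN fold / non-CIN
    fold).  The non-CIN sample is constructed at ddCt = 0 and the CIN
    sample at ddCt = -truth; independent Gaussian noise of ``ct_noise_sd``
    cycles is added to every Ct.

    Returns (measurements, truth) where measurements maps locus ->
    (cin: QPCRMeasurement, noncin: QPCRMeasurement).
    """
    rng = np.random.default_rng(seed)
    out = {}
    for locus, truth in true_log2_ratios.items():
        def ct(base, ddct_target):
            # input fraction: target/control at equal offset; ChIP fraction
            # shifted so that ddCt comes out at ddct_target
            ct_in_ctrl = base + rng.uniform(-1, 1)
            ct_in_tgt = ct_in_ctrl + rng.uniform(-0.5, 0.5)
            dct_in = ct_in_tgt - ct_in_ctrl
            ct_ch_ctrl = base + rng.uniform(-1, 1)
            ct_ch_tgt = ct_ch_ctrl + dct_in + ddct_target
            vals = np.array([ct_ch_tgt, ct_ch_ctrl, ct_in_tgt, ct_in_ctrl])
            vals = vals + rng.normal(0.0, ct_noise_sd, size=4)
            return QPCRMeasurement(*vals)

        base = float(rng.uniform(20, 28))
        cin = ct(base, -truth)
        noncin = ct(base, 0.0)
        out[locus] = (cin, noncin)
    return out, dict(true_log2_ratios)


# ---------------------------------------------------------------------------
# Evidence tracks derived from the planted truth (for end-to-end runs)
# ---------------------------------------------------------------------------

def gen_evidence(
    sim: CoverageSimulation,
    tf_names=("DLX2", "LHX6", "NKX2-1"),
    tf_hit_rate=0.6,
    conserved_rate=0.7,
    accessibility_rates={"PV": 0.5, "VIP": 0.3},
    n_decoys=50,
    seed: int = 0,
):
    """Synthetic TF-binding, conservation and accessibility interval sets.

    Each evidence set covers a random subset of the planted
    condition-1-specific regions (a narrow site near the region centre) at
    the stated rate, plus ``n_decoys`` random background intervals, so the
    multi-evidence annotation and its bookkeeping have a known truth.
    """
    rng = np.random.default_rng(seed)
    genome = sim.design.genome
    chroms = sorted(genome)
    cond1 = [r.interval for r in sim.regions if r.specificity == "cond1"]

    def site_in(iv, width=400):
        mid = (iv.start + iv.end) // 2
        jitter = int(rng.integers(-200, 201))
        s = max(0, mid + jitter - width // 2)
        return GenomicInterval(iv.chrom, s, s + width)

    def decoys(n, width=400):
        out = []
        for _ in range(n):
            chrom = chroms[rng.integers(len(chroms))]
            s = int(rng.integers(0, genome[chrom] - width))
            out.append(GenomicInterval(chrom, s, s + width))
        return out

    def subset_set(rate):
        hits = [site_in(iv) for iv in cond1 if rng.random() < rate]
        return IntervalSet(hits + decoys(n_decoys), genome=genome)

    tf_sets = {tf: subset_set(tf_hit_rate) for tf in tf_names}
    conserved = subset_set(conserved_rate)
    accessibility = {ct: subset_set(rate) for ct, rate in accessibility_rates.items()}
    return tf_sets, conserved, accessibility


def gen_tss_table(sim: CoverageSimulation, n_genes=40, seed: int = 0):
    """Random gene TSS records (gene, chrom, tss) on the simulated genome."""
    rng = np.random.default_rng(seed)
    genome = sim.design.genome
    chroms = sorted(genome)
    rows = []
    for i in range(n_genes):
        chrom = chroms[rng.integers(len(chroms))]
        rows.append((f"gene{i:03d}", chrom, int(rng.integers(0, genome[chrom]))))
    return rows
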