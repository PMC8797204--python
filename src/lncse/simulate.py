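"""Synthetic genome generator with planted ground truth.

Emulates the inputs of the full prioritization pipeline on one synthetic
chromosome: a gene annotation with protein-coding and lncRNA biotypes and GO
sets; clustered H3K27ac peaks forming super-enhancers, some containing a
lncRNA TSS; a correlated ATAC signal track; a symmetric contact map with
power-law distance decay plus planted SE-promoter loops; negative-binomial
two-group RNA-seq counts with planted differential lncRNAs; and a PPI edge
list containing a seed interactome. Exactly one planted "candidate"
lncRNA-SE is simultaneously (a) a super-enhancer containing a lncRNA TSS,
(b) looped to a coding promoter, (c) differentially expressed, and (d) its
looped target carries the designated matrix-organization-like GO term — so
the downstream funnel has a unique known answer.

Every generator is deterministic under a fixed seed (independent child
streams per stage), and all planted objects round-trip through the module's
writers and readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import (
    AnnotationSet,
    Gene,
    GenomicInterval,
    Peak,
    write_annotation,
    write_bed_intervals,
    write_bed_peaks,
    write_go_map,
)
from .loops import ContactMatrix, write_contacts
from .tracks import SignalTrack, write_signal_track
from .de import write_counts

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "SimulatedData",
    "generate_annotation",
    "simulate_peaks_and_signal",
    "simulate_contact_map",
    "simulate_counts",
    "simulate_ppi",
    "sample_atac_peaks",
    "simulate_dataset",
]

CHROM = "chrS"
DESIGNATED_GO_TERM = "GO:SIM_MATRIX_ORG"  # matrix-organization-like set

_LOOP_MIN_SEP = 60_000  # planted SE-promoter separations bracket ~180 kb
_LOOP_MAX_SEP = 400_000


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults describe one 20 Mb chromosome profiled at 5 kb contact
    resolution, 30 planted SEs of which 10 carry a lncRNA TSS, an ATAC
    enrichment of 5-fold over SEs, loops at 8-fold over the distance-decay
    expectation, and a 10 + 10 two-group RNA-seq design with a planted
    |log2 FC| of 2 on 20% of lncRNAs.
    """

    seed: int = 0
    genome_length: int = 20_000_000
    n_coding_genes: int = 300
    n_lncrna: int = 100
    n_se: int = 30
    n_lncrna_se: int = 10
    peaks_per_se: int = 5
    bg_peak_count: int = 600
    se_peak_signal: float = 8.0
    bg_peak_signal: float = 1.0
    atac_se_fold: float = 5.0
    contact_binsize: int = 5_000
    decay_exponent: float = 1.0
    loop_fold: float = 8.0
    n_samples_per_group: int = 10
    nb_dispersion: float = 0.2
    de_log2fc: float = 2.0
    frac_de_lncrna: float = 0.2
    # generator plumbing
    signal_binsize: int = 200
    contact_mu1: float = 200.0  # mean raw count at one-bin separation
    n_atac_peaks: int = 2_000
    n_go_terms: int = 12
    n_de_lncrna_se: int = 5  # lncRNA-SEs whose lncRNA is planted DE
    n_looped_de_lncrna_se: int = 3  # of those, how many get a planted loop
    n_looped_other_se: int = 5  # loops on non-DE lncRNA-SEs and R-SEs
    stitch_guard: int = 12_500  # background peaks stay this far from SE spans

    def __post_init__(self) -> None:
        if self.n_lncrna_se > self.n_se:
            raise ValueError("n_lncrna_se must be <= n_se")
        if self.n_lncrna_se > self.n_lncrna:
            raise ValueError("n_lncrna_se must be <= n_lncrna")
        if self.peaks_per_se < 3:
            raise ValueError("peaks_per_se must be >= 3")
        for name in ("n_coding_genes", "n_lncrna", "n_se", "bg_peak_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.genome_length % self.contact_binsize != 0:
            raise ValueError("contact_binsize must divide genome_length")
        if not (0.0 <= self.frac_de_lncrna <= 1.0):
            raise ValueError("frac_de_lncrna must lie in [0, 1]")
        if self.n_de_lncrna_se > self.n_lncrna_se:
            raise ValueError("n_de_lncrna_se must be <= n_lncrna_se")
        if self.n_looped_de_lncrna_se > self.n_de_lncrna_se:
            raise ValueError("n_looped_de_lncrna_se must be <= n_de_lncrna_se")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    @classmethod
    def compact(cls, seed: int = 0, **overrides) -> "SimConfig":
        """A reduced 5 Mb preset for quick runs and repeated-seed calibration."""
        base = dict(
            genome_length=5_000_000,
            n_coding_genes=80,
            n_lncrna=30,
            n_se=8,
            n_lncrna_se=3,
            bg_peak_count=150,
            n_de_lncrna_se=2,
            n_looped_de_lncrna_se=1,
            n_looped_other_se=1,
        )
        base.update(overrides)
        return cls(seed=seed, **base)


@dataclass
class SimulationTruth:
    """Everything the generator planted, for truth-aware tests."""

    se_intervals: list[tuple[int, int]]  # index order = SE id
    se_peak_layout: list[list[tuple[int, int]]]  # per SE, member peak intervals
    lncrna_se_map: dict[int, str]  # SE id -> lncRNA gene id (first n_lncrna_se SEs)
    loops: list[dict]  # {se_id, se_bin, promoter_bin, target_gene}
    de_lncrnas: dict[str, float]  # gene id -> signed log2 FC
    candidate_lncrna: str
    candidate_se: int
    candidate_target: str
    designated_go_term: str
    ppi_seeds: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["lncrna_se_map"] = {str(k): v for k, v in d["lncrna_se_map"].items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["lncrna_se_map"] = {int(k): v for k, v in d["lncrna_se_map"].items()}
        d["se_intervals"] = [tuple(x) for x in d["se_intervals"]]
        d["se_peak_layout"] = [[tuple(p) for p in se] for se in d["se_peak_layout"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# annotation + truth planning


def _plan_se_spans(cfg: SimConfig, rng: np.random.Generator):
    """Non-overlapping SE spans with their member-peak layout.

    Peak widths ~ U[800, 2000), inter-peak gaps ~ U[3000, 8000) (< 12.5 kb so
    each cluster stitches into exactly one region). Placement reserves one
    guarded slot per SE and spreads the remaining slack uniformly, so feasible
    configurations always place; infeasible ones error out explicitly.
    """
    guard = cfg.stitch_guard + 5_000
    layouts = []
    for _ in range(cfg.n_se):
        widths = rng.integers(800, 2000, cfg.peaks_per_se)
        gaps = rng.integers(3000, 8000, cfg.peaks_per_se - 1)
        span_len = int(widths.sum() + gaps.sum())
        layouts.append((widths, gaps, span_len))
    max_len = max(l[2] for l in layouts)
    # guaranteed-separation placement: sorted uniform starts in the slack
    # left after reserving one (span + 2*guard) slot per SE
    sep = max_len + 2 * guard
    slack = cfg.genome_length - 2 * guard - cfg.n_se * sep
    if slack < 0:
        raise ValueError("genome too small to place the requested SEs")
    offsets = np.sort(rng.uniform(0, slack, cfg.n_se))
    starts = (guard + offsets + np.arange(cfg.n_se) * sep).astype(np.int64)
    order = rng.permutation(cfg.n_se)  # decouple SE id from genomic order
    spans = []
    peak_layout = []
    for se_id in range(cfg.n_se):
        pos = order[se_id]
        widths, gaps, span_len = layouts[pos]
        s = int(starts[pos])
        peaks = []
        cur = s
        for w_i, g_i in zip(widths, np.append(gaps, 0)):
            peaks.append((cur, cur + int(w_i)))
            cur += int(w_i) + int(g_i)
        spans.append((s, s + span_len))
        peak_layout.append(peaks)
    return spans, peak_layout


def generate_annotation(cfg: SimConfig) -> tuple[AnnotationSet, SimulationTruth]:
    """Place genes and plan the full planted truth.

    Returns the annotation together with the truth record: the two are planned
    jointly because lncRNA-SE membership, loop targets, the DE set and the
    designated GO term all constrain gene placement.
    """
    rng = cfg.rng(1)
    spans, peak_layout = _plan_se_spans(cfg, rng) if cfg.n_se else ([], [])

    bs = cfg.contact_binsize
    n_bins = cfg.genome_length // bs
    se_bins = set()
    for s, e in spans:
        se_bins.update(range(s // bs, (e - 1) // bs + 1))
    free_bins = np.array(sorted(set(range(2, n_bins - 2)) - se_bins))
    n_other = cfg.n_coding_genes + (cfg.n_lncrna - cfg.n_lncrna_se)
    if n_other > len(free_bins):
        raise ValueError("genome too small to place all genes without TSS collisions")

    genes: list[Gene] = []
    # lncRNAs transcribed from SEs: TSS inside the first n_lncrna_se SE spans
    for k in range(cfg.n_lncrna_se):
        s, e = spans[k]
        tss = int(rng.integers(s + 200, e - 200))
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(1_000, 5_000))
        gid = f"LNC{k:04d}"
        if strand == "+":
            iv = GenomicInterval(CHROM, tss, min(tss + length, cfg.genome_length), "+")
        else:
            iv = GenomicInterval(CHROM, max(0, tss - length + 1), tss + 1, "-")
        genes.append(Gene(gid, gid, "lncRNA", iv))

    chosen = rng.choice(free_bins, size=n_other, replace=False)
    coding_bins, other_lnc_bins = chosen[: cfg.n_coding_genes], chosen[cfg.n_coding_genes :]

    for i, b in enumerate(sorted(map(int, coding_bins))):
        tss = b * bs + bs // 2
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(2_000, 30_000))
        gid = f"PC{i:04d}"
        if strand == "+":
            iv = GenomicInterval(CHROM, tss, min(tss + length, cfg.genome_length), "+")
        else:
            iv = GenomicInterval(CHROM, max(0, tss - length + 1), tss + 1, "-")
        genes.append(Gene(gid, gid, "protein_coding", iv))

    for i, b in enumerate(sorted(map(int, other_lnc_bins))):
        tss = b * bs + bs // 2
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(1_000, 10_000))
        gid = f"LNC{cfg.n_lncrna_se + i:04d}"
        if strand == "+":
            iv = GenomicInterval(CHROM, tss, min(tss + length, cfg.genome_length), "+")
        else:
            iv = GenomicInterval(CHROM, max(0, tss - length + 1), tss + 1, "-")
        genes.append(Gene(gid, gid, "lncRNA", iv))

    ann_wo_go = AnnotationSet(genes)
    coding_ids = [g.gene_id for g in ann_wo_go.coding_genes]

    # ----- DE plan: which lncRNA-SEs carry a DE lncRNA, which get loops
    lncrna_se_map = {k: f"LNC{k:04d}" for k in range(cfg.n_lncrna_se)}
    de_se_ids = list(rng.choice(cfg.n_lncrna_se, size=cfg.n_de_lncrna_se, replace=False)) \
        if cfg.n_de_lncrna_se else []
    looped_de_se_ids = de_se_ids[: cfg.n_looped_de_lncrna_se]
    candidate_se = int(looped_de_se_ids[0]) if looped_de_se_ids else -1

    other_se_pool = [k for k in range(cfg.n_se) if k not in looped_de_se_ids]
    n_other_loops = min(cfg.n_looped_other_se, len(other_se_pool))
    looped_other = list(rng.choice(other_se_pool, size=n_other_loops, replace=False)) \
        if n_other_loops else []

    # ----- planted loops: SE-centre bin <-> coding-promoter bin, 60-400 kb apart
    from .intervals import tss_of

    coding_tss = {g.gene_id: tss_of(g) for g in ann_wo_go.coding_genes}
    loops = []
    used_targets: set[str] = set()
    for se_id in list(map(int, looped_de_se_ids)) + list(map(int, looped_other)):
        s, e = spans[se_id]
        centre = (s + e) // 2
        eligible = [
            gid
            for gid, t in coding_tss.items()
            if _LOOP_MIN_SEP <= abs(t - centre) <= _LOOP_MAX_SEP and gid not in used_targets
        ]
        if not eligible:
            raise ValueError(
                f"no coding gene within {_LOOP_MIN_SEP}-{_LOOP_MAX_SEP} bp of SE {se_id}"
            )
        target = str(rng.choice(sorted(eligible)))
        used_targets.add(target)
        loops.append(
            {
                "se_id": se_id,
                "se_bin": centre // bs,
                "promoter_bin": coding_tss[target] // bs,
                "target_gene": target,
            }
        )

    candidate_target = next(
        (l["target_gene"] for l in loops if l["se_id"] == candidate_se), ""
    )

    # ----- GO terms: generic terms on coding genes + the designated set
    go_map: dict[str, set[str]] = {}
    terms = [f"GO:SIM{i:04d}" for i in range(cfg.n_go_terms)]
    for gid in coding_ids:
        for t in rng.choice(terms, size=int(rng.integers(1, 4)), replace=False):
            go_map.setdefault(str(t), set()).add(gid)
    excluded = {l["target_gene"] for l in loops} - {candidate_target}
    pool = [g for g in coding_ids if g not in excluded and g != candidate_target]
    n_members = max(1, int(0.1 * len(coding_ids)))
    members = set(map(str, rng.choice(pool, size=min(n_members, len(pool)), replace=False)))
    if candidate_target:
        members.add(candidate_target)
    go_map[DESIGNATED_GO_TERM] = members

    annotation = AnnotationSet(genes, go_map)

    # ----- DE lncRNAs: the chosen SE lncRNAs plus background lncRNAs
    n_de_total = int(round(cfg.frac_de_lncrna * cfg.n_lncrna))
    de_lncrnas: dict[str, float] = {}
    for j, se_id in enumerate(de_se_ids):
        sign = 1.0 if (se_id == candidate_se or j % 2 == 0) else -1.0
        de_lncrnas[lncrna_se_map[int(se_id)]] = sign * cfg.de_log2fc
    non_se_lnc = [g.gene_id for g in annotation.lncrnas if g.gene_id not in de_lncrnas
                  and g.gene_id not in lncrna_se_map.values()]
    extra = max(0, n_de_total - len(de_lncrnas))
    for j, gid in enumerate(map(str, rng.choice(non_se_lnc, size=min(extra, len(non_se_lnc)),
                                                replace=False))):
        de_lncrnas[gid] = cfg.de_log2fc * (1.0 if j % 2 == 0 else -1.0)

    seeds = [candidate_target] if candidate_target else []
    seed_pool = [g for g in coding_ids if g not in seeds]
    seeds += list(map(str, rng.choice(seed_pool, size=min(4, len(seed_pool)), replace=False)))

    truth = SimulationTruth(
        se_intervals=[(int(s), int(e)) for s, e in spans],
        se_peak_layout=[[(int(a), int(b)) for a, b in se] for se in peak_layout],
        lncrna_se_map=lncrna_se_map,
        loops=loops,
        de_lncrnas=de_lncrnas,
        candidate_lncrna=lncrna_se_map.get(candidate_se, ""),
        candidate_se=candidate_se,
        candidate_target=candidate_target,
        designated_go_term=DESIGNATED_GO_TERM,
        ppi_seeds=seeds,
    )
    return annotation, truth


# ---------------------------------------------------------------------------
# peaks + signal tracks


def simulate_peaks_and_signal(
    cfg: SimConfig, annotation: AnnotationSet, truth: SimulationTruth
) -> tuple[list[Peak], list[GenomicInterval], SignalTrack, SignalTrack]:
    """Peaks, blacklist, H3K27ac track and ATAC track.

    Planted SE peaks follow the truth layout with signal ~ se_peak_signal;
    background peaks are scattered uniformly outside the SE neighbourhoods
    (span +/- stitch guard) with signal ~ bg_peak_signal; a handful of strong
    artifact peaks sit inside blacklist regions to exercise removal. The ATAC
    track is elevated atac_se_fold-fold inside planted SE spans.
    """
    rng = cfg.rng(2)
    peaks: list[Peak] = []
    for se_id, layout in enumerate(truth.se_peak_layout):
        for k, (s, e) in enumerate(layout):
            sig = float(rng.gamma(100.0, cfg.se_peak_signal / 100.0))
            q = float(10.0 ** -rng.uniform(6.0, 12.0))
            peaks.append(Peak(GenomicInterval(CHROM, s, e), f"se{se_id}_p{k}", sig, q))

    guard = cfg.stitch_guard + 2_000
    forbidden = [(max(0, s - guard), e + guard) for s, e in truth.se_intervals]
    # background peaks also stay clear of lncRNA promoters: a stitched
    # background cluster must never cover a lncRNA TSS, so the planted
    # lncRNA-SE set is exactly the classifier's truth
    from .intervals import tss_of

    for g in annotation.lncrnas:
        t = tss_of(g)
        forbidden.append((max(0, t - guard), t + guard))

    def _free(pos: int, width: int) -> bool:
        return not any(s < pos + width and pos < e for s, e in forbidden)

    # blacklist regions in otherwise empty territory, with artifact peaks inside
    blacklist: list[GenomicInterval] = []
    n_bl = 5
    attempts = 0
    while len(blacklist) < n_bl and attempts < 1000:
        attempts += 1
        pos = int(rng.integers(0, cfg.genome_length - 20_000))
        if _free(pos, 20_000):
            blacklist.append(GenomicInterval(CHROM, pos, pos + 20_000))
            forbidden.append((pos - guard, pos + 20_000 + guard))
    for k, bl in enumerate(blacklist[: max(1, n_bl // 2) + 1]):
        s = bl.start + 5_000
        sig = float(rng.gamma(100.0, cfg.se_peak_signal / 100.0))
        peaks.append(
            Peak(GenomicInterval(CHROM, s, s + 1_500), f"artifact{k}", sig, 1e-9)
        )

    n_pass = int(round(0.85 * cfg.bg_peak_count))
    placed = 0
    attempts = 0
    while placed < cfg.bg_peak_count and attempts < 100 * max(1, cfg.bg_peak_count):
        attempts += 1
        width = int(rng.integers(500, 2000))
        pos = int(rng.integers(0, cfg.genome_length - width))
        if not _free(pos, width):
            continue
        sig = float(rng.gamma(25.0, cfg.bg_peak_signal / 25.0))
        if placed < n_pass:
            q = float(10.0 ** -rng.uniform(5.05, 9.0))
        else:
            q = float(10.0 ** -rng.uniform(2.0, 4.9))
        peaks.append(Peak(GenomicInterval(CHROM, pos, pos + width), f"bg{placed}", sig, q))
        placed += 1
    if placed < cfg.bg_peak_count:
        raise ValueError("could not place background peaks; genome too crowded")

    # H3K27ac density track: low noise floor plus peak signal
    sb = cfg.signal_binsize
    n_sbins = -(-cfg.genome_length // sb)
    h3k = rng.exponential(0.02, n_sbins) + 0.05
    for p in peaks:
        b0, b1 = p.interval.start // sb, (p.interval.end - 1) // sb
        h3k[b0 : b1 + 1] += p.signal
    h3k_track = SignalTrack(CHROM, sb, h3k)

    # ATAC density: unit-mean noise, scaled atac_se_fold inside SE spans
    atac = rng.gamma(4.0, 0.25, n_sbins)
    for s, e in truth.se_intervals:
        atac[s // sb : (e - 1) // sb + 1] *= cfg.atac_se_fold
    atac_track = SignalTrack(CHROM, sb, atac)

    return peaks, blacklist, h3k_track, atac_track


def sample_atac_peaks(cfg: SimConfig, atac_track: SignalTrack, width: int = 400) -> list[Peak]:
    """ATAC peak calls sampled with probability proportional to the ATAC signal."""
    rng = cfg.rng(6)
    p = atac_track.values / atac_track.values.sum()
    bins = rng.choice(len(atac_track.values), size=cfg.n_atac_peaks, replace=True, p=p)
    bs = atac_track.binsize
    out = []
    for k, b in enumerate(map(int, bins)):
        start = max(0, min(b * bs + bs // 2 - width // 2, atac_track.length - width))
        out.append(Peak(GenomicInterval(CHROM, start, start + width), f"atac{k}", 1.0, 1e-6))
    return out


# ---------------------------------------------------------------------------
# contact map


def simulate_contact_map(cfg: SimConfig, truth: SimulationTruth) -> ContactMatrix:
    """Poisson contact map with power-law decay and planted loops.

    The expected count at bin separation k is ``contact_mu1 * k**-decay``;
    planted loop pairs receive an independent extra Poisson component of mean
    ``(loop_fold - 1) * expected`` so their total is Poisson with mean
    ``loop_fold * expected``.
    """
    rng = cfg.rng(3)
    bs = cfg.contact_binsize
    n_bins = cfg.genome_length // bs
    b1_parts, b2_parts, c_parts = [], [], []
    for k in range(n_bins):
        mu = cfg.contact_mu1 * (k**-cfg.decay_exponent) if k > 0 else cfg.contact_mu1
        counts = rng.poisson(mu, n_bins - k)
        nz = np.nonzero(counts)[0]
        if len(nz):
            b1_parts.append(nz)
            b2_parts.append(nz + k)
            c_parts.append(counts[nz])
    bin1 = np.concatenate(b1_parts) if b1_parts else np.array([], dtype=np.int64)
    bin2 = np.concatenate(b2_parts) if b2_parts else np.array([], dtype=np.int64)
    cnt = np.concatenate(c_parts) if c_parts else np.array([], dtype=np.int64)

    if truth.loops and cfg.loop_fold > 1.0:
        key = bin1 * n_bins + bin2
        order = np.argsort(key)
        key_sorted = key[order]
        extra_i, extra_j, extra_c = [], [], []
        for loop in truth.loops:
            i, j = sorted((int(loop["se_bin"]), int(loop["promoter_bin"])))
            d = j - i
            mu = cfg.contact_mu1 * (d**-cfg.decay_exponent) if d > 0 else cfg.contact_mu1
            boost = int(rng.poisson((cfg.loop_fold - 1.0) * mu))
            if boost == 0:
                continue
            k = int(np.searchsorted(key_sorted, i * n_bins + j))
            if k < len(key_sorted) and key_sorted[k] == i * n_bins + j:
                cnt[order[k]] += boost
            else:
                extra_i.append(i)
                extra_j.append(j)
                extra_c.append(boost)
        if extra_i:
            bin1 = np.concatenate([bin1, extra_i])
            bin2 = np.concatenate([bin2, extra_j])
            cnt = np.concatenate([cnt, extra_c])
    return ContactMatrix(CHROM, bs, n_bins, bin1, bin2, cnt)


# ---------------------------------------------------------------------------
# RNA-seq counts


def simulate_counts(
    cfg: SimConfig, annotation: AnnotationSet, truth: SimulationTruth
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial two-group counts with planted DE lncRNAs.

    Library sizes vary log-uniformly over a 4-fold range (making TMM
    non-trivial); planted DE genes are shifted by their signed log2 FC in the
    case group; all other genes are null. Baselines of planted DE lncRNAs are
    floored so the planted effects are detectable at the design size.
    """
    if cfg.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    rng = cfg.rng(4)
    gene_ids = [g.gene_id for g in annotation.genes]
    n_genes = len(gene_ids)
    baseline = 2.0 ** rng.normal(5.0, 1.5, n_genes)
    idx = {g: i for i, g in enumerate(gene_ids)}
    for gid in truth.de_lncrnas:
        baseline[idx[gid]] = max(baseline[idx[gid]], 32.0)

    n = cfg.n_samples_per_group
    rel_lib = np.exp(rng.uniform(np.log(1.0), np.log(4.0), 2 * n))
    rel_lib /= rel_lib.mean()
    fc = np.ones((n_genes, 2 * n))
    for gid, lfc in truth.de_lncrnas.items():
        fc[idx[gid], n:] = 2.0**lfc
    mu = baseline[:, None] * rel_lib[None, :] * fc
    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    samples = [f"ctl_{i + 1}" for i in range(n)] + [f"cavd_{i + 1}" for i in range(n)]
    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    groups = pd.Series(["control"] * n + ["case"] * n, index=samples, name="group")
    return df, groups


# ---------------------------------------------------------------------------
# PPI edge list


def simulate_ppi(cfg: SimConfig, annotation: AnnotationSet, truth: SimulationTruth,
                 n_background_edges: int = 300) -> pd.DataFrame:
    """Random PPI edge list guaranteed to contain a seed interactome.

    Each seed gene gets 8-15 partners; background edges connect random coding
    gene pairs. No self-loops, no duplicate edges.
    """
    rng = cfg.rng(5)
    coding = [g.gene_id for g in annotation.coding_genes]
    edges: set[tuple[str, str]] = set()
    for seed in truth.ppi_seeds:
        partners = rng.choice([g for g in coding if g != seed],
                              size=int(rng.integers(8, 16)), replace=False)
        for p in map(str, partners):
            edges.add(tuple(sorted((seed, p))))
    while len(edges) < n_background_edges + sum(1 for _ in truth.ppi_seeds) * 8:
        a, b = map(str, rng.choice(coding, size=2, replace=False))
        edges.add(tuple(sorted((a, b))))
    df = pd.DataFrame(sorted(edges), columns=["protein_a", "protein_b"])
    return df


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimulatedData:
    cfg: SimConfig
    annotation: AnnotationSet
    truth: SimulationTruth
    peaks: list[Peak]
    blacklist: list[GenomicInterval]
    h3k27ac: SignalTrack
    atac: SignalTrack
    contacts: ContactMatrix
    counts: pd.DataFrame
    groups: pd.Series
    ppi_edges: pd.DataFrame

    def write_all(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bed_peaks(self.peaks, outdir / "h3k27ac_peaks.bed")
        write_bed_intervals(self.blacklist, outdir / "blacklist.bed")
        write_signal_track(self.h3k27ac, outdir / "h3k27ac.tsv")
        write_signal_track(self.atac, outdir / "atac.tsv")
        write_contacts(self.contacts, outdir / "contacts.tsv")
        write_counts(self.counts, outdir / "counts.tsv")
        self.groups.to_csv(outdir / "groups.tsv", sep="\t")
        write_annotation(self.annotation, outdir / "annotation.tsv")
        write_go_map(self.annotation.go_map, outdir / "go.tsv")
        self.ppi_edges.to_csv(outdir / "ppi_edges.tsv", sep="\t", index=False)
        self.truth.to_json(outdir / "truth.json")


def simulate_dataset(cfg: SimConfig | None = None) -> SimulatedData:
    """Generate every pipeline input under one seed."""
    cfg = cfg or SimConfig()
    annotation, truth = generate_annotation(cfg)
    peaks, blacklist, h3k, atac = simulate_peaks_and_signal(cfg, annotation, truth)
    contacts = simulate_contact_map(cfg, truth)
    counts, groups = simulate_counts(cfg, annotation, truth)
    ppi = simulate_ppi(cfg, annotation, truth)
    return SimulatedData(cfg, annotation, truth, peaks, blacklist, h3k, atac,
                         contacts, counts, groups, ppi)
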