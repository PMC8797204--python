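"""ROSE-style super-enhancer identification and lncRNA-SE classification.

The procedure mirrors the rank-ordering-of-super-enhancers recipe: q-value
filtering and blacklist removal of H3K27ac peaks, stitching of nearby peaks
(12.5 kb default, no TSS exclusion), total-signal scoring, and the
hockey-stick cutoff at the point where the min-max-scaled rank curve first
attains slope 1. Super-enhancers from which at least one lncRNA is
transcribed (lncRNA TSS inside the SE span) are classified as lncRNA-SEs;
the rest are regular SEs (R-SEs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import (
    AnnotationSet,
    GenomicInterval,
    Peak,
    subtract_blacklist,
    tss_of,
)
from .tracks import SignalTrack

logger = logging.getLogger(__name__)

__all__ = [
    "SECallConfig",
    "StitchedRegion",
    "SuperEnhancerSet",
    "filter_peaks",
    "stitch_peaks",
    "score_regions",
    "find_cutoff",
    "classify_lncrna_se",
    "call_super_enhancers",
    "hockey_stick_plot",
]


@dataclass
class SECallConfig:
    peak_q_threshold: float = 1e-5
    stitch_distance: int = 12_500
    tss_exclusion: bool = False  # config stub; not applied by default
    use_input: bool = False

    def __post_init__(self) -> None:
        if self.stitch_distance < 0:
            raise ValueError("stitch_distance must be >= 0")
        if not (0.0 < self.peak_q_threshold <= 1.0):
            raise ValueError("peak_q_threshold must lie in (0, 1]")


@dataclass
class StitchedRegion:
    interval: GenomicInterval
    member_names: list[str]
    score: float = 0.0
    rank: int = 0
    is_se: bool = False
    is_lncrna_se: bool = False
    lncrna_ids: list[str] = field(default_factory=list)


@dataclass
class SuperEnhancerSet:
    """Ranked stitched regions with the hockey-stick cutoff applied."""

    regions: list[StitchedRegion]
    cutoff_score: float

    @property
    def super_enhancers(self) -> list[StitchedRegion]:
        return [r for r in self.regions if r.is_se]

    @property
    def lncrna_ses(self) -> list[StitchedRegion]:
        return [r for r in self.regions if r.is_lncrna_se]

    @property
    def regular_ses(self) -> list[StitchedRegion]:
        return [r for r in self.regions if r.is_se and not r.is_lncrna_se]


def filter_peaks(
    peaks: Sequence[Peak],
    cfg: SECallConfig,
    blacklist: Sequence[GenomicInterval] = (),
) -> list[Peak]:
    """Keep peaks with q <= threshold and no blacklist overlap (whole-peak removal)."""
    kept = [p for p in peaks if p.qvalue <= cfg.peak_q_threshold]
    return subtract_blacklist(kept, blacklist)


def stitch_peaks(peaks: Sequence[Peak], stitch_distance: int) -> list[StitchedRegion]:
    """Merge peaks whose gap (next.start - prev.end) is <= stitch_distance.

    Transitive closure over the gap graph; the region interval spans the
    leftmost start to the rightmost end of its members.
    """
    if not peaks:
        return []
    ordered = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    regions: list[StitchedRegion] = []
    cur = [ordered[0]]
    cur_end = ordered[0].interval.end
    for p in ordered[1:]:
        same = p.interval.chrom == cur[0].interval.chrom
        if same and p.interval.start - cur_end <= stitch_distance:
            cur.append(p)
            cur_end = max(cur_end, p.interval.end)
        else:
            regions.append(_make_region(cur, cur_end))
            cur = [p]
            cur_end = p.interval.end
    regions.append(_make_region(cur, cur_end))
    return regions


def _make_region(members: list[Peak], end: int) -> StitchedRegion:
    iv = GenomicInterval(members[0].interval.chrom, members[0].interval.start, end)
    return StitchedRegion(iv, [m.name for m in members])


def score_regions(
    regions: Sequence[StitchedRegion],
    h3k27ac: SignalTrack,
    input_track: SignalTrack | None = None,
) -> list[StitchedRegion]:
    """Score = integral over the region of max(signal - input, 0).

    With a binned density track this is sum over bins of the (input-subtracted,
    floored at zero) density times the covered width. Regions are ranked
    descending by score, ties broken by genomic position (leftmost first).
    """
    for r in regions:
        iv = r.interval
        if iv.end > h3k27ac.length:
            raise ValueError(f"track gap under region [{iv.start}, {iv.end})")
        if input_track is None:
            r.score = h3k27ac.region_sum(iv.start, iv.end)
        else:
            if input_track.binsize != h3k27ac.binsize:
                raise ValueError("signal and input tracks must share a bin size")
            diff = SignalTrack(
                h3k27ac.chrom,
                h3k27ac.binsize,
                np.maximum(h3k27ac.values - input_track.values, 0.0),
            )
            r.score = diff.region_sum(iv.start, iv.end)
    ordered = sorted(regions, key=lambda r: (-r.score, r.interval.chrom, r.interval.start))
    for rank, r in enumerate(ordered, start=1):
        r.rank = rank
    return ordered


def find_cutoff(scores: Sequence[float]) -> float:
    """Hockey-stick cutoff score.

    Scores are sorted ascending and min-max scaled to the unit square together
    with their ranks; the cutoff is the (unscaled) score at the first point,
    scanning from the low end, where the centred-secant slope reaches 1 —
    the tangency point of a slope-1 line slid onto a convex increasing curve.
    Regions scoring strictly above the cutoff are super-enhancers.

    Degenerate curves (all scores equal, or slope >= 1 from the start as on a
    straight line) yield a cutoff equal to the maximum score, i.e. zero SEs.
    """
    s = np.sort(np.asarray(scores, dtype=float))
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 regions to locate a cutoff")
    lo, hi = s[0], s[-1]
    if hi == lo:
        logger.warning("all region scores equal; degenerate rank curve, 0 SEs")
        return float(hi)
    x = np.arange(n) / (n - 1)
    y = (s - lo) / (hi - lo)
    # centred secant with a 1-rank window: slope[i] over (i-1, i+1)
    slope = (y[2:] - y[:-2]) / (x[2:] - x[:-2])
    crossing = np.nonzero(slope >= 1.0)[0]
    if len(crossing) == 0:
        logger.warning("rank-curve slope never reaches 1; 0 SEs")
        return float(hi)
    i = int(crossing[0])
    if i == 0:
        # slope >= 1 from the very first evaluable point: no below-1 approach,
        # e.g. a straight line with slope 1 everywhere
        logger.warning("rank-curve slope >= 1 from the low end; degenerate, 0 SEs")
        return float(hi)
    return float(s[i + 1])  # slope index i corresponds to rank i + 1


def classify_lncrna_se(se_set: SuperEnhancerSet, annotation: AnnotationSet) -> SuperEnhancerSet:
    """Flag each SE containing >= 1 lncRNA TSS (half-open containment)."""
    lnc = [(g.gene_id, g.interval.chrom, tss_of(g)) for g in annotation.lncrnas]
    for r in se_set.regions:
        r.lncrna_ids = [
            gid
            for gid, chrom, tss in lnc
            if r.is_se and chrom == r.interval.chrom and r.interval.contains(tss)
        ]
        r.is_lncrna_se = bool(r.lncrna_ids)
    return se_set


def call_super_enhancers(
    peaks: Sequence[Peak],
    h3k27ac: SignalTrack,
    annotation: AnnotationSet | None = None,
    blacklist: Sequence[GenomicInterval] = (),
    cfg: SECallConfig | None = None,
    input_track: SignalTrack | None = None,
) -> SuperEnhancerSet:
    """Full pipeline: filter -> stitch -> score -> cutoff -> classify."""
    cfg = cfg or SECallConfig()
    kept = filter_peaks(peaks, cfg, blacklist)
    regions = stitch_peaks(kept, cfg.stitch_distance)
    if len(regions) < 3:
        raise ValueError(f"only {len(regions)} stitched regions; cannot call SEs")
    ranked = score_regions(
        regions, h3k27ac, input_track if cfg.use_input else None
    )
    cutoff = find_cutoff([r.score for r in ranked])
    for r in ranked:
        r.is_se = r.score > cutoff
    se_set = SuperEnhancerSet(ranked, cutoff)
    if annotation is not None:
        classify_lncrna_se(se_set, annotation)
    return se_set


def hockey_stick_plot(se_set: SuperEnhancerSet, path: str | Path) -> None:
    """Rank vs score curve with the slope-1 cutoff marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.sort([r.score for r in se_set.regions])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(np.arange(1, len(scores) + 1), scores, lw=1.2, color="#2c5f8a")
    ax.axhline(se_set.cutoff_score, color="#c23b22", ls="--", lw=1,
               label=f"cutoff = {se_set.cutoff_score:.1f}")
    n_se = len(se_set.super_enhancers)
    ax.set_xlabel("stitched enhancers ranked by H3K27ac signal")
    ax.set_ylabel("region signal")
    ax.set_title(f"{n_se} super-enhancers / {len(se_set.regions)} regions")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_se_table(se_set: SuperEnhancerSet, path: str | Path) -> None:
    """TSV: chrom, start, end, score, rank, is_SE, is_lncRNA_SE, lncRNA ids."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tscore\trank\tis_SE\tis_lncRNA_SE\tlncrna_ids\n")
        for r in sorted(se_set.regions, key=lambda r: r.rank):
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.score!r}\t{r.rank}\t"
                f"{int(r.is_se)}\t{int(r.is_lncrna_se)}\t{','.join(r.lncrna_ids)}\n"
            )


def read_se_table(path: str | Path) -> SuperEnhancerSet:
    regions = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            f = line.rstrip("\n").split("\t")
            r = StitchedRegion(
                GenomicInterval(f[0], int(f[1]), int(f[2])),
                member_names=[],
                score=float(f[3]),
                rank=int(f[4]),
                is_se=bool(int(f[5])),
                is_lncrna_se=bool(int(f[6])),
                lncrna_ids=[x for x in f[7].split(",") if x],
            )
            regions.append(r)
    regions.sort(key=lambda r: r.rank)
    se_scores = [r.score for r in regions if r.is_se]
    non_se = [r.score for r in regions if not r.is_se]
    cutoff = max(non_se) if non_se else (min(se_scores) if se_scores else 0.0)
    return SuperEnhancerSet(regions, cutoff)
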