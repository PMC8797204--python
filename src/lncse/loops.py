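"""Contact-matrix handling, VC-sqrt normalization, virtual 4C and loop calling.

The loop caller is a deliberately simple distance-decay model: the expected
count of a bin pair is the empirical mean count of its distance stratum
(equal-width strata in log distance) times a coverage-bias correction
``b_i * b_j``, where ``b_i`` is the bin's observed marginal divided by its
positional expectation under the fitted decay (a raw ``c_i c_j / c_bar**2``
term would deflate expectations at the chromosome edges, whose marginals are
low only because they have fewer partners). Significance is a Poisson upper
tail with Benjamini-Hochberg control over all in-range bin pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pathlib import Path
from scipy import stats

from .intervals import AnnotationSet, GenomicInterval, promoter_window, overlaps
from .se import SuperEnhancerSet

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "LoopCallConfig",
    "bin_contacts",
    "vc_sqrt_normalize",
    "virtual_4c",
    "call_loops",
    "map_loops_to_promoters",
    "read_contacts",
    "write_contacts",
]


@dataclass
class ContactMatrix:
    """Symmetric binned intra-chromosomal contacts, stored as upper-triangle COO.

    ``bin1 <= bin2`` for every stored entry; values are raw counts (ints) or
    normalized reals. Bin ``i`` covers ``[i * binsize, (i + 1) * binsize)``.
    """

    chrom: str
    binsize: int
    n_bins: int
    bin1: np.ndarray
    bin2: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        self.bin1 = np.asarray(self.bin1, dtype=np.int64)
        self.bin2 = np.asarray(self.bin2, dtype=np.int64)
        self.count = np.asarray(self.count)
        if np.any(self.bin1 > self.bin2):
            raise ValueError("upper-triangle storage requires bin1 <= bin2")
        if np.any(self.count < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.count.sum())

    def coverage(self) -> np.ndarray:
        """Per-bin marginal (row sum of the full symmetric matrix)."""
        cov = np.zeros(self.n_bins, dtype=float)
        np.add.at(cov, self.bin1, self.count)
        off = self.bin1 != self.bin2
        np.add.at(cov, self.bin2[off], self.count[off])
        return cov

    def row(self, i: int) -> np.ndarray:
        """Symmetrized row i as a dense vector of length n_bins."""
        out = np.zeros(self.n_bins, dtype=float)
        m1 = self.bin1 == i
        np.add.at(out, self.bin2[m1], self.count[m1])
        m2 = (self.bin2 == i) & (self.bin1 != i)
        np.add.at(out, self.bin1[m2], self.count[m2])
        return out


@dataclass
class LoopCallConfig:
    fdr: float = 0.01
    min_dist: int = 20_000
    max_dist: int = 2_000_000
    # narrow strata (factor ~1.05 in distance) keep the within-stratum decay
    # negligible; near the diagonal each stratum holds a single offset
    n_strata: int = 100
    min_pairs_per_stratum: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must lie in (0, 1)")
        if self.min_dist >= self.max_dist:
            raise ValueError("min_dist must be < max_dist")


def bin_contacts(
    pairs: np.ndarray, binsize: int, genome_length: int, chrom: str = "chrS"
) -> ContactMatrix:
    """Accumulate raw position pairs into an unordered binned contact matrix."""
    pairs = np.asarray(pairs, dtype=np.int64)
    if pairs.size == 0:
        n_bins = -(-genome_length // binsize)
        z = np.array([], dtype=np.int64)
        return ContactMatrix(chrom, binsize, n_bins, z, z, z)
    if pairs.min() < 0:
        raise ValueError("negative coordinates in contact pairs")
    if pairs.max() >= genome_length:
        raise ValueError("contact pair coordinate beyond genome_length")
    n_bins = -(-genome_length // binsize)
    b = pairs // binsize
    lo = np.minimum(b[:, 0], b[:, 1])
    hi = np.maximum(b[:, 0], b[:, 1])
    key = lo * n_bins + hi
    uniq, counts = np.unique(key, return_counts=True)
    return ContactMatrix(
        chrom, binsize, n_bins, uniq // n_bins, uniq % n_bins, counts.astype(np.int64)
    )


def vc_sqrt_normalize(M: ContactMatrix) -> ContactMatrix:
    """Vanilla-coverage square-root normalization: M'_ij = M_ij / sqrt(r_i r_j).

    Bins with zero coverage stay zero (masked; their rows are untouched).
    """
    cov = M.coverage()
    n_masked = int((cov == 0).sum())
    if n_masked:
        logger.info("vc_sqrt_normalize: %d zero-coverage bins left masked", n_masked)
    denom = np.sqrt(cov[M.bin1] * cov[M.bin2])
    vals = np.zeros(len(M.count), dtype=float)
    ok = denom > 0
    vals[ok] = M.count[ok] / denom[ok]
    return ContactMatrix(M.chrom, M.binsize, M.n_bins, M.bin1.copy(), M.bin2.copy(), vals)


def virtual_4c(M: ContactMatrix, anchor_position: int) -> np.ndarray:
    """Interaction profile of the bin containing the anchor: one value per bin.

    Conventionally run on the VC-sqrt-normalized matrix. Raises if the anchor
    bin has zero coverage (masked).
    """
    if not (0 <= anchor_position < M.n_bins * M.binsize):
        raise ValueError("anchor outside genome")
    k = anchor_position // M.binsize
    if M.coverage()[k] == 0:
        raise ValueError(f"anchor bin {k} is masked (zero coverage)")
    return M.row(int(k))


def _diagonal_stats(M: ContactMatrix, offsets: np.ndarray, unmasked: np.ndarray):
    """Per-offset sum of counts and number of unmasked bin pairs."""
    d = M.bin2 - M.bin1
    kmin, kmax = int(offsets[0]), int(offsets[-1])
    sel = (d >= kmin) & (d <= kmax)
    sums = np.bincount(
        d[sel] - kmin, weights=M.count[sel].astype(float), minlength=len(offsets)
    )
    npairs = np.array(
        [int(np.sum(unmasked[:-k] & unmasked[k:])) if k > 0 else int(unmasked.sum())
         for k in offsets],
        dtype=np.int64,
    )
    return sums, npairs


def _coverage_bias(M: ContactMatrix, cov: np.ndarray, unmasked: np.ndarray) -> np.ndarray:
    """Per-bin coverage bias: observed marginal over its positional expectation.

    The expectation at position i sums the genome-wide per-offset mean counts
    over i's actual partner offsets, so edge bins (fewer partners) are not
    mistaken for low-propensity bins. Normalized to mean 1 over unmasked bins.
    """
    n = M.n_bins
    d = M.bin2 - M.bin1
    mu_all = np.bincount(d, weights=M.count.astype(float), minlength=n)
    denom = n - np.arange(n, dtype=float)  # pairs per offset
    mu_all = mu_all / denom
    s = np.concatenate([[0.0], np.cumsum(mu_all[1:])])  # s[k] = sum of mu over 1..k
    idx = np.arange(n)
    exp_cov = mu_all[0] + s[idx] + s[n - 1 - idx]
    bias = np.ones(n)
    ok = unmasked & (exp_cov > 0)
    bias[ok] = cov[ok] / exp_cov[ok]
    m = bias[unmasked].mean() if unmasked.any() else 1.0
    return bias / m


def call_loops(M: ContactMatrix, cfg: LoopCallConfig | None = None) -> pd.DataFrame:
    """Call significant loops on a raw contact matrix.

    Returns a BEDPE-like frame (one row per significant bin pair at
    ``q <= cfg.fdr``): chrom, a_start, a_end, b_start, b_end, count, expected,
    p, q, distance. BH is applied over *all* in-range unmasked bin pairs, so
    zero-count pairs (p = 1) count toward the number of tests.
    """
    cfg = cfg or LoopCallConfig()
    bs = M.binsize
    kmin = max(1, -(-cfg.min_dist // bs))
    kmax = min(M.n_bins - 1, cfg.max_dist // bs)
    if kmin > kmax:
        raise ValueError("distance window excludes every bin pair")
    offsets = np.arange(kmin, kmax + 1)
    cov = M.coverage()
    unmasked = cov > 0
    sums, npairs = _diagonal_stats(M, offsets, unmasked)

    # equal-width strata in log distance, merging sparse strata rightward
    log_d = np.log(offsets * bs)
    edges = np.linspace(log_d[0], log_d[-1] + 1e-9, cfg.n_strata + 1)
    stratum_of_offset = np.clip(np.searchsorted(edges, log_d, side="right") - 1, 0, cfg.n_strata - 1)
    stratum_pairs = np.zeros(cfg.n_strata, dtype=np.int64)
    stratum_sums = np.zeros(cfg.n_strata)
    np.add.at(stratum_pairs, stratum_of_offset, npairs)
    np.add.at(stratum_sums, stratum_of_offset, sums)
    merged_id = np.arange(cfg.n_strata)
    for s in range(cfg.n_strata):
        if 0 < stratum_pairs[s] < cfg.min_pairs_per_stratum or (
            stratum_pairs[s] == 0 and np.any(stratum_of_offset == s)
        ):
            tgt = s - 1 if s > 0 else s + 1
            if 0 <= tgt < cfg.n_strata:
                tgt = int(merged_id[tgt])  # follow earlier merges
                logger.info("call_loops: stratum %d sparse; merged with %d", s, tgt)
                stratum_pairs[tgt] += stratum_pairs[s]
                stratum_sums[tgt] += stratum_sums[s]
                stratum_pairs[s] = 0
                merged_id[merged_id == s] = tgt
    with np.errstate(invalid="ignore"):
        mu = np.where(stratum_pairs > 0, stratum_sums / np.maximum(stratum_pairs, 1), np.nan)
    mu_of_offset = mu[merged_id[stratum_of_offset]]

    bias = _coverage_bias(M, cov, unmasked)
    d = M.bin2 - M.bin1
    in_range = (d >= kmin) & (d <= kmax) & unmasked[M.bin1] & unmasked[M.bin2] & (M.count > 0)
    i, j, c = M.bin1[in_range], M.bin2[in_range], M.count[in_range].astype(float)
    exp = mu_of_offset[d[in_range] - kmin] * bias[i] * bias[j]
    p = stats.poisson.sf(c - 1, exp)
    m_tests = int(npairs.sum())

    # BH step-up with explicit m (the implicit zero-count pairs all have p = 1)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m_tests / np.arange(1, len(p) + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)

    keep = q <= cfg.fdr
    df = pd.DataFrame(
        {
            "chrom": M.chrom,
            "a_start": i[keep] * bs,
            "a_end": (i[keep] + 1) * bs,
            "b_start": j[keep] * bs,
            "b_end": (j[keep] + 1) * bs,
            "count": c[keep].astype(int),
            "expected": exp[keep],
            "p": p[keep],
            "q": q[keep],
        }
    )
    df["distance"] = df["b_start"] - df["a_start"]
    return df.sort_values("q", kind="stable").reset_index(drop=True)


def map_loops_to_promoters(
    loops: pd.DataFrame,
    se_set: SuperEnhancerSet,
    annotation: AnnotationSet,
    halfwidth: int = 1000,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Map SEs to coding genes through significant loops.

    SE ``s`` maps to coding gene ``g`` iff some loop has one anchor bin
    overlapping ``s`` and the other overlapping ``g``'s promoter window
    (TSS +/- halfwidth). Returns the mapping table and a summary with the mean
    number of coding promoters looped per R-SE and per lncRNA-SE and the mean
    anchor-centre distance over mapped pairs.
    """
    promoters = [(g, promoter_window(g, halfwidth)) for g in annotation.coding_genes]
    ses = se_set.super_enhancers
    rows = []
    for _, loop in loops.iterrows():
        a = GenomicInterval(loop["chrom"], int(loop["a_start"]), int(loop["a_end"]))
        b = GenomicInterval(loop["chrom"], int(loop["b_start"]), int(loop["b_end"]))
        for anchor_se, anchor_prom in ((a, b), (b, a)):
            se_hits = [s for s in ses if overlaps(anchor_se, s.interval)]
            if not se_hits:
                continue
            gene_hits = [g for g, pw in promoters if overlaps(anchor_prom, pw)]
            dist = abs(
                (anchor_se.start + anchor_se.end) // 2 - (anchor_prom.start + anchor_prom.end) // 2
            )
            for s in se_hits:
                for g in gene_hits:
                    rows.append(
                        {
                            "se_chrom": s.interval.chrom,
                            "se_start": s.interval.start,
                            "se_end": s.interval.end,
                            "se_rank": s.rank,
                            "is_lncrna_se": s.is_lncrna_se,
                            "gene_id": g.gene_id,
                            "anchor_distance": dist,
                            "loop_q": float(loop["q"]),
                        }
                    )
    mapping = pd.DataFrame(
        rows,
        columns=[
            "se_chrom", "se_start", "se_end", "se_rank", "is_lncrna_se",
            "gene_id", "anchor_distance", "loop_q",
        ],
    ).drop_duplicates(subset=["se_rank", "gene_id", "anchor_distance"])

    per_se = mapping.groupby("se_rank")["gene_id"].nunique().to_dict()

    def _mean_genes(regions) -> float:
        if not regions:
            return 0.0
        return float(np.mean([per_se.get(r.rank, 0) for r in regions]))

    summary = {
        "mean_coding_promoters_per_r_se": _mean_genes(se_set.regular_ses),
        "mean_coding_promoters_per_lncrna_se": _mean_genes(se_set.lncrna_ses),
        "mean_anchor_distance": float(mapping["anchor_distance"].mean()) if len(mapping) else 0.0,
    }
    return mapping.reset_index(drop=True), summary


def write_contacts(M: ContactMatrix, path: str | Path) -> None:
    """BEDPE-like TSV: bin1_start, bin2_start, count (header comments carry metadata)."""
    with open(path, "w") as fh:
        fh.write(f"# chrom={M.chrom} binsize={M.binsize} n_bins={M.n_bins}\n")
        pd.DataFrame(
            {"a": M.bin1 * M.binsize, "b": M.bin2 * M.binsize, "count": M.count}
        ).to_csv(fh, sep="\t", header=False, index=False, float_format="%.17g")


def read_contacts(path: str | Path) -> ContactMatrix:
    chrom, binsize, n_bins = "chrS", None, None
    b1, b2, cnt = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=")
                        if k == "chrom":
                            chrom = v
                        elif k == "binsize":
                            binsize = int(v)
                        elif k == "n_bins":
                            n_bins = int(v)
                continue
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            b1.append(int(f[0]))
            b2.append(int(f[1]))
            cnt.append(float(f[2]))
    if binsize is None:
        raise ValueError("contact file missing binsize metadata")
    b1a = np.asarray(b1, dtype=np.int64) // binsize
    b2a = np.asarray(b2, dtype=np.int64) // binsize
    cnta = np.asarray(cnt)
    if np.allclose(cnta, np.round(cnta)):
        cnta = cnta.astype(np.int64)
    if n_bins is None:
        n_bins = int(max(b1a.max(), b2a.max())) + 1 if len(b1a) else 1
    return ContactMatrix(chrom, binsize, n_bins, b1a, b2a, cnta)
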