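"""Candidate prioritization: the lncRNA-SE funnel and PPI subnetwork extraction.

The funnel narrows super-enhancers to a ranked candidate list in five stages:
(1) all SEs, (2) SEs transcribing a lncRNA, (3) those whose lncRNA is
differentially expressed, (4) those with a significant chromatin loop to a
protein-coding promoter (TSS +/- 1 kb), (5) those whose looped target belongs
to a designated GO set. Each stage is a subset of the previous one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import AnnotationSet, GenomicInterval, overlaps, promoter_window
from .se import SuperEnhancerSet

__all__ = [
    "FunnelReport",
    "PPINetwork",
    "run_funnel",
    "ppi_subnetwork",
    "mean_anchor_distance",
    "write_report",
    "read_report",
]

STAGES = (
    "super_enhancers",
    "lncrna_se",
    "de_lncrna_se",
    "de_lncrna_se_with_loops",
    "candidates_in_go_term",
)

_CANDIDATE_COLUMNS = [
    "lncrna_id", "se_chrom", "se_start", "se_end", "target_gene",
    "anchor_distance", "direction", "q",
]


@dataclass
class FunnelReport:
    stage_counts: dict[str, int]
    candidates: pd.DataFrame  # stage-5 rows
    mean_anchor_distance: float  # over stage-4 SE-promoter pairs
    go_term: str

    def __post_init__(self) -> None:
        counts = [self.stage_counts[s] for s in STAGES]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError("funnel stage counts must be non-increasing")


@dataclass
class PPINetwork:
    nodes: set[str]
    edges: set[tuple[str, str]]
    seeds: list[str]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-loop in PPI network")


def run_funnel(
    se_set: SuperEnhancerSet,
    de_result: pd.DataFrame,
    loops: pd.DataFrame,
    annotation: AnnotationSet,
    go_term: str,
    de_q_threshold: float = 0.05,
    promoter_halfwidth: int = 1000,
) -> FunnelReport:
    """Run the five-stage prioritization funnel.

    ``de_result`` is indexed by gene id with columns logFC and q; ``loops`` is
    the significant-loop table from the loop caller. A loop links an SE to a
    gene when one anchor bin overlaps the SE interval itself and the other
    overlaps the gene's promoter window. Candidates are sorted by DE q then
    anchor distance.
    """
    if go_term not in annotation.go_map:
        raise ValueError(
            f"unknown GO term {go_term!r}; available: {sorted(annotation.go_map)}"
        )
    go_genes = annotation.go_map[go_term]

    ses = se_set.super_enhancers
    stage2 = [s for s in ses if s.is_lncrna_se]
    de_q = de_result["q"]

    def _de_lncrnas_of(se) -> list[str]:
        return [
            gid for gid in se.lncrna_ids
            if gid in de_q.index and de_q[gid] < de_q_threshold
        ]

    stage3 = [s for s in stage2 if _de_lncrnas_of(s)]

    promoters = [(g, promoter_window(g, promoter_halfwidth)) for g in annotation.coding_genes]
    pair_rows = []  # one row per (stage-3 SE, looped coding gene)
    for s in stage3:
        for _, loop in loops.iterrows():
            a = GenomicInterval(loop["chrom"], int(loop["a_start"]), int(loop["a_end"]))
            b = GenomicInterval(loop["chrom"], int(loop["b_start"]), int(loop["b_end"]))
            for se_anchor, prom_anchor in ((a, b), (b, a)):
                if not overlaps(se_anchor, s.interval):
                    continue
                dist = abs(
                    (se_anchor.start + se_anchor.end) // 2
                    - (prom_anchor.start + prom_anchor.end) // 2
                )
                for g, pw in promoters:
                    if overlaps(prom_anchor, pw):
                        pair_rows.append((s, g.gene_id, dist))
    pairs = {}
    for s, gid, dist in pair_rows:
        key = (s.rank, gid)
        if key not in pairs or dist < pairs[key][2]:
            pairs[key] = (s, gid, dist)
    stage4_ranks = sorted({rank for rank, _ in pairs})
    stage4 = [s for s in stage3 if s.rank in stage4_ranks]

    cand_rows = []
    for s, gid, dist in pairs.values():
        if gid not in go_genes:
            continue
        for lnc in _de_lncrnas_of(s):
            lfc = float(de_result.loc[lnc, "logFC"])
            cand_rows.append(
                {
                    "lncrna_id": lnc,
                    "se_chrom": s.interval.chrom,
                    "se_start": s.interval.start,
                    "se_end": s.interval.end,
                    "target_gene": gid,
                    "anchor_distance": dist,
                    "direction": "up" if lfc > 0 else "down",
                    "q": float(de_q[lnc]),
                }
            )
    candidates = pd.DataFrame(cand_rows, columns=_CANDIDATE_COLUMNS)
    if len(candidates):
        candidates = candidates.sort_values(
            ["q", "anchor_distance"], kind="stable"
        ).reset_index(drop=True)
    stage5_ses = {
        (r["se_chrom"], r["se_start"], r["se_end"]) for _, r in candidates.iterrows()
    }

    distances = [dist for _, _, dist in pairs.values()]
    report = FunnelReport(
        stage_counts={
            "super_enhancers": len(ses),
            "lncrna_se": len(stage2),
            "de_lncrna_se": len(stage3),
            "de_lncrna_se_with_loops": len(stage4),
            "candidates_in_go_term": len(stage5_ses),
        },
        candidates=candidates,
        mean_anchor_distance=mean_anchor_distance(distances) if distances else 0.0,
        go_term=go_term,
    )
    return report


def mean_anchor_distance(distances: Sequence[float]) -> float:
    """Arithmetic mean separation of SE-anchor and promoter-anchor bin centres."""
    if len(distances) == 0:
        raise ValueError("mean anchor distance undefined for zero pairs")
    return float(np.mean(distances))


def ppi_subnetwork(
    edges: Iterable[tuple[str, str]] | pd.DataFrame,
    tpm: Mapping[str, float] | pd.Series,
    seeds: Sequence[str],
    percentile: float = 10.0,
) -> PPINetwork:
    """Seed-incident PPI subnetwork over expressed genes.

    A gene is expressed when its TPM is strictly greater than the
    ``percentile``-th percentile (linear interpolation) of all TPM values.
    Kept edges have both endpoints expressed and at least one endpoint in the
    seed list; nodes are the endpoints of kept edges.
    """
    if not seeds:
        raise ValueError("seed list must be non-empty")
    if isinstance(edges, pd.DataFrame):
        edge_iter = [tuple(r) for r in edges.iloc[:, :2].itertuples(index=False)]
    else:
        edge_iter = list(edges)
    tpm_s = pd.Series(tpm, dtype=float)
    cutoff = float(np.percentile(tpm_s.to_numpy(), percentile))
    expressed = set(tpm_s.index[tpm_s > cutoff])
    seed_set = set(seeds)
    missing = seed_set - {g for e in edge_iter for g in e}
    if missing:
        import logging

        logging.getLogger(__name__).warning(
            "seeds absent from the edge list contribute nothing: %s", sorted(missing)
        )
    kept = set()
    for a, b in edge_iter:
        if a == b:
            continue
        if a in expressed and b in expressed and (a in seed_set or b in seed_set):
            kept.add(tuple(sorted((a, b))))
    nodes = {g for e in kept for g in e}
    return PPINetwork(nodes, kept, list(seeds))


def write_report(report: FunnelReport, outdir: str | Path) -> None:
    """TSV candidates + JSON report + human-readable summary (deterministic order)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    payload = {
        "stage_counts": {s: int(report.stage_counts[s]) for s in STAGES},
        "mean_anchor_distance": report.mean_anchor_distance,
        "go_term": report.go_term,
        "candidates": report.candidates.to_dict(orient="records"),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    with open(outdir / "summary.txt", "w") as fh:
        for s in STAGES:
            fh.write(f"{s}\t{report.stage_counts[s]}\n")
        for _, row in report.candidates.iterrows():
            fh.write(
                f"candidate\t{row['lncrna_id']}\t{row['target_gene']}\t"
                f"{row['anchor_distance']}\t{row['direction']}\t{row['q']:.3g}\n"
            )


def read_report(path: str | Path) -> FunnelReport:
    with open(Path(path) / "report.json") as fh:
        payload = json.load(fh)
    candidates = pd.DataFrame(payload["candidates"], columns=_CANDIDATE_COLUMNS)
    return FunnelReport(
        stage_counts=payload["stage_counts"],
        candidates=candidates,
        mean_anchor_distance=payload["mean_anchor_distance"],
        go_term=payload["go_term"],
    )
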