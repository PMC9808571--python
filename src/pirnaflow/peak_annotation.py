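"""Peak-summit-to-TSS distances and replicate-consensus binding calls.

A gene is scored against each transcription factor by the distance from its
TSS to the nearest peak summit (absolute value, same chromosome only).  A
factor is called *bound* at a promoter when a peak summit lies within
``window_bp`` (default 500, inclusive) of the TSS under the replicate
consensus:

* TCFL5 — a within-window CUT&RUN peak in **both** replicates; or in one of
  the two CUT&RUN replicates together with a within-window ChIP-seq peak in
  at least two of three ChIP replicates.
* A-MYB — the same rule, with the single ChIP-seq replicate standing in for
  the two-of-three requirement.

Distances are reported from the pooled (all assays, all replicates) peak
sets and are never strand-signed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import enrichment_stats
from .io_formats import GeneAnnotation, PeakCall

WINDOW_BP = 500


@dataclass(frozen=True)
class OccupancyRecord:
    gene_id: str
    factor: str
    distance_bp: int | None  # absolute TSS->nearest-summit; None if no peak
    bound: bool
    evidence: str  # cutrun_both | cutrun_plus_chip | none

    def __post_init__(self) -> None:
        if self.bound and self.evidence == "none":
            raise ValueError("bound requires supporting evidence")


def nearest_peak_distance(
    gene: GeneAnnotation, peaks: Iterable[PeakCall]
) -> int | None:
    """Minimum |summit − TSS| over same-chromosome peaks; ties break toward
    the leftmost summit.  ``None`` when no same-chromosome peak exists."""
    best: tuple[int, int] | None = None  # (distance, summit)
    for p in peaks:
        if p.chrom != gene.chrom:
            continue
        d = abs(p.summit - gene.tss)
        cand = (d, p.summit)
        if best is None or cand < best:
            best = cand
    return best[0] if best else None


def _within(gene: GeneAnnotation, peaks: Iterable[PeakCall], window_bp: int) -> bool:
    d = nearest_peak_distance(gene, peaks)
    return d is not None and d <= window_bp


def is_bound_consensus(
    gene: GeneAnnotation,
    factor: str,
    cutrun_reps: Sequence[Sequence[PeakCall]],
    chip_reps: Sequence[Sequence[PeakCall]],
    window_bp: int = WINDOW_BP,
) -> OccupancyRecord:
    """Apply the replicate-consensus binding rule for one gene and factor.

    Requires exactly 2 CUT&RUN replicates, and 3 ChIP replicates for TCFL5
    or 1 for A-MYB.
    """
    if len(cutrun_reps) != 2:
        raise ValueError(f"expected 2 CUT&RUN replicates, got {len(cutrun_reps)}")
    n_chip_expected = 3 if factor == "TCFL5" else 1
    if len(chip_reps) != n_chip_expected:
        raise ValueError(
            f"expected {n_chip_expected} ChIP replicates for {factor}, "
            f"got {len(chip_reps)}"
        )
    cut = [_within(gene, reps, window_bp) for reps in cutrun_reps]
    chip = [_within(gene, reps, window_bp) for reps in chip_reps]
    chip_ok = sum(chip) >= (2 if factor == "TCFL5" else 1)
    if all(cut):
        bound, evidence = True, "cutrun_both"
    elif any(cut) and chip_ok:
        bound, evidence = True, "cutrun_plus_chip"
    else:
        bound, evidence = False, "none"
    pooled = [p for reps in (*cutrun_reps, *chip_reps) for p in reps]
    return OccupancyRecord(
        gene_id=gene.gene_id,
        factor=factor,
        distance_bp=nearest_peak_distance(gene, pooled),
        bound=bound,
        evidence=evidence,
    )


def annotate_genes(
    genes: Sequence[GeneAnnotation],
    peak_sets: Mapping[tuple[str, str, int], Sequence[PeakCall]],
    window_bp: int = WINDOW_BP,
) -> tuple[pd.DataFrame, dict]:
    """Occupancy table (gene × factor) plus per-gene-class distance summaries.

    ``peak_sets`` maps (factor, assay, replicate) -> peaks, with assay in
    {CUTRUN, CHIP}.  Factors are taken from the keys.  Missing replicate
    files are treated as empty peak sets so the consensus arithmetic stays
    well-defined.
    """
    factors = sorted({k[0] for k in peak_sets})
    rows = []
    for factor in factors:
        cutrun = [
            peak_sets.get((factor, "CUTRUN", r), []) for r in (1, 2)
        ]
        n_chip = 3 if factor == "TCFL5" else 1
        chip = [
            peak_sets.get((factor, "CHIP", r), []) for r in range(1, n_chip + 1)
        ]
        for gene in genes:
            rec = is_bound_consensus(gene, factor, cutrun, chip, window_bp)
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "gene_class": gene.gene_class,
                    "factor": factor,
                    "distance_bp": rec.distance_bp,
                    "bound": rec.bound,
                    "evidence": rec.evidence,
                }
            )
    table = pd.DataFrame(rows)
    summaries: dict = {}
    for (factor, gene_class), sub in table.groupby(["factor", "gene_class"]):
        d = sub["distance_bp"].dropna()
        if len(d):
            summaries[(factor, gene_class)] = enrichment_stats.box_stats(d)
    return table, summaries
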