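"""Count normalization, spike-in absolute quantification, and dependence classes.

Normalization follows sequencing-depth conventions: rpm is reads per million
genome-mapping reads; RPKM additionally divides by feature length in kb.
Absolute abundance uses the ERCC spike-in proportionality -- each library
received a known number of spike molecules (default 623,291,645), so

    molecules/cell = reads_gene * ercc_molecules / (n_cells * reads_ercc).

Dependence classification combines promoter occupancy with mutant/wild-type
fold-changes of precursor and mature piRNA abundance:

* ``TCFL5_dependent`` — promoter occupied by TCFL5 and both precursor and
  piRNA abundance reduced more than ``threshold``-fold (default 2) in the
  mutant.
* ``AMYB_dependent`` — promoter occupied by A-MYB and precursor abundance
  essentially unchanged (within ``threshold``-fold either way).
* ``AMYB_dependent_biogenesis_defect`` — A-MYB-dependent by the rule above
  but with piRNA abundance reduced ``threshold``-fold or more: transcription
  persists while piRNA production fails, the signature of a lost initiator.
* otherwise ``unassigned``.  ``TCFL5_dependent`` takes precedence when a
  gene satisfies both definitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

ERCC_MOLECULES = 623_291_645

CLASS_TCFL5 = "TCFL5_dependent"
CLASS_AMYB = "AMYB_dependent"
CLASS_AMYB_DEFECT = "AMYB_dependent_biogenesis_defect"
CLASS_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class DependenceCall:
    gene_id: str
    tcfl5_bound: bool
    amyb_bound: bool
    fc_precursor: float | None
    fc_pirna: float | None
    dependence_class: str


def rpm(counts, total_mapped: float):
    """reads-per-million: count * 1e6 / total genome-mapping reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / total_mapped


def rpkm(count: float, gene_length_nt: float, total_mapped: float) -> float:
    """reads per million mapped per kb of feature: count*1e9/(total*length)."""
    if gene_length_nt <= 0:
        raise ValueError("gene length must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count * 1e9 / (total_mapped * gene_length_nt)


def molecules_per_cell(
    gene_reads: float,
    ercc_reads: float,
    n_cells: float,
    ercc_molecules: float = ERCC_MOLECULES,
) -> float:
    """Absolute abundance from the ERCC spike-in proportionality."""
    if ercc_reads <= 0:
        raise ValueError("ercc_reads must be positive")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    return gene_reads * ercc_molecules / (n_cells * ercc_reads)


def fold_change(wt: float, mut: float, pseudocount: float = 0.1) -> float | None:
    """(mut + pc) / (wt + pc); ``None`` when both are zero with pc = 0."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if wt + pseudocount == 0:
        return None  # undefined: nothing observed in either genotype
    return (mut + pseudocount) / (wt + pseudocount)


def classify_dependence(
    gene_id: str,
    tcfl5_bound: bool,
    amyb_bound: bool,
    fc_precursor: float | None,
    fc_pirna: float | None,
    threshold: float = 2.0,
) -> DependenceCall:
    """Assign the dependence class for one gene (see module docstring)."""
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    lo = 1.0 / threshold
    cls = CLASS_UNASSIGNED
    fp, fq = fc_precursor, fc_pirna
    if (
        tcfl5_bound
        and fp is not None
        and fq is not None
        and fp < lo
        and fq < lo
    ):
        cls = CLASS_TCFL5
    elif amyb_bound and fp is not None and lo <= fp <= threshold:
        if fq is not None and fq <= lo:
            cls = CLASS_AMYB_DEFECT
        else:
            cls = CLASS_AMYB
    return DependenceCall(gene_id, tcfl5_bound, amyb_bound, fp, fq, cls)


def classify_table(
    occupancy: pd.DataFrame,
    fc_precursor: dict[str, float | None],
    fc_pirna: dict[str, float | None],
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Vector version of :func:`classify_dependence` over an occupancy table.

    ``occupancy`` is the gene × factor table from
    :func:`pirnaflow.peak_annotation.annotate_genes`.
    """
    bound = occupancy.pivot_table(
        index="gene_id", columns="factor", values="bound", aggfunc="first"
    )
    rows = []
    for gene_id in bound.index:
        call = classify_dependence(
            gene_id,
            bool(bound.loc[gene_id].get("TCFL5", False)),
            bool(bound.loc[gene_id].get("A-MYB", False)),
            fc_precursor.get(gene_id),
            fc_pirna.get(gene_id),
            threshold,
        )
        rows.append(vars(call))
    return pd.DataFrame(rows)


def gene_fold_changes(
    counts: pd.DataFrame,
    wt_col: str,
    mut_col: str,
    total_wt: float,
    total_mut: float,
    pseudocount: float = 0.1,
    by: str = "gene_id",
) -> dict[str, float | None]:
    """Per-gene mutant/WT fold-change of rpm-normalized summed counts."""
    agg = counts.groupby(by)[[wt_col, mut_col]].sum()
    out: dict[str, float | None] = {}
    for gene_id, row in agg.iterrows():
        wt_rpm = float(rpm([row[wt_col]], total_wt)[0])
        mut_rpm = float(rpm([row[mut_col]], total_mut)[0])
        out[str(gene_id)] = fold_change(wt_rpm, mut_rpm, pseudocount)
    return out
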