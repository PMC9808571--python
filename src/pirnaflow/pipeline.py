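"""Orchestrate simulate → annotate → quantify → predict → stats as one run.

Each stage writes its table under the output directory; the run finishes
with a machine-readable ``report.json`` plus a one-page ``summary.txt``.
The configuration is a flat key-value YAML file; unknown keys are an error
(typos in a threshold must not pass silently).  All randomness flows from
``seed``, so a run is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment_stats, peak_annotation, quantification, synthetic_data
from .enrichment_stats import ContingencyTable
from .io_formats import write_table
from .quantification import CLASS_AMYB, CLASS_AMYB_DEFECT, CLASS_TCFL5
from .synthetic_data import COUNT_COLS, SimConfig, generate_cohort, load_cohort
from .target_prediction import SiteParams, predict_network

logger = logging.getLogger("pirnaflow")


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "pirnaflow_run"
    input_dir: str | None = None  # load a written cohort instead of simulating
    window_bp: int = 500
    min_pairs: int = 10
    fc_threshold: float = 2.0
    pseudocount: float = 0.1
    allow_wobble: bool = False
    count_noise: str = "poisson"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _setup_logging() -> None:
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(h)
    logger.setLevel(logging.INFO)


def _direction_fisher(edges, truth_classes: pd.DataFrame) -> dict:
    """Eutherian-vs-not 2x2 over the source and target gene sets of a
    direction's verified edges, tested with two-sided Fisher's exact test."""
    cons = dict(zip(truth_classes["gene_id"], truth_classes["conservation"]))
    src = sorted({e.source_gene for e in edges})
    tgt = sorted({e.target_gene for e in edges})
    if not src or not tgt:
        return {"p": None, "table": None}
    src_eu = sum(cons.get(g) == "eutherian" for g in src)
    tgt_eu = sum(cons.get(g) == "eutherian" for g in tgt)
    table = ContingencyTable(
        src_eu, len(src) - src_eu, tgt_eu, len(tgt) - tgt_eu
    )
    return {
        "p": enrichment_stats.fisher_exact_two_sided(table),
        "table": [[table.a, table.b], [table.c, table.d]],
    }


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline; returns the report dict (also written out)."""
    _setup_logging()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run parameters: %s", dataclasses.asdict(config))

    # ------------------------------------------------------------------ data
    if config.input_dir:
        indir = Path(config.input_dir)
        if not indir.exists():
            raise FileNotFoundError(f"input directory not found: {indir}")
        logger.info("loading cohort from %s", indir)
        data = load_cohort(indir)
        truth_classes = data["truth_classes"]
    else:
        logger.info("simulating cohort (seed=%d)", config.seed)
        sim = generate_cohort(
            SimConfig(
                seed=config.seed,
                count_noise=config.count_noise,
                window_bp=config.window_bp,
                min_pairs=config.min_pairs,
            )
        )
        simdir = outdir / "cohort"
        sim.write(simdir)
        data = load_cohort(simdir)
        truth_classes = data["truth_classes"]

    genes = data["genes"]
    transcripts = data["transcripts"]
    pirnas = data["pirnas"]

    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    # ------------------------------------------------------------- occupancy
    logger.info("annotating %d genes against %d peak sets", len(genes), len(data["peaks"]))
    occupancy, _summaries = peak_annotation.annotate_genes(
        genes, data["peaks"], config.window_bp
    )
    write_table(occupancy, outdir / "occupancy.tsv")

    # --------------------------------------------------------- quantification
    wt_col, mut_col = COUNT_COLS
    fc_pirna = quantification.gene_fold_changes(
        pirnas,
        wt_col,
        mut_col,
        data["totals"][("smallRNA", "WT")],
        data["totals"][("smallRNA", "Tcfl5_hom")],
        config.pseudocount,
        by="source_gene",
    )
    fc_prec = quantification.gene_fold_changes(
        data["precursor_counts"],
        wt_col,
        mut_col,
        data["totals"][("longRNA", "WT")],
        data["totals"][("longRNA", "Tcfl5_hom")],
        config.pseudocount,
        by="gene_id",
    )
    pirna_gene_ids = {g.gene_id for g in genes if g.gene_class == "pachytene_piRNA"}
    occ_pirna = occupancy[occupancy["gene_id"].isin(pirna_gene_ids)]
    calls = quantification.classify_table(
        occ_pirna, fc_prec, fc_pirna, config.fc_threshold
    )
    ercc_total_wt = float(data["ercc_counts"][wt_col].sum())
    prec = data["precursor_counts"].copy()
    prec["molecules_per_cell_WT"] = [
        quantification.molecules_per_cell(
            c, ercc_total_wt, synthetic_data.SimConfig().n_cells
        )
        for c in prec[wt_col]
    ]
    write_table(prec, outdir / "precursor_quant.tsv")
    write_table(calls, outdir / "dependence_classes.tsv")

    # ------------------------------------------------------ network prediction
    cls_map = dict(zip(calls["gene_id"], calls["dependence_class"]))
    tcfl5_dep = {g for g, c in cls_map.items() if c == CLASS_TCFL5}
    amyb_dep = {g for g, c in cls_map.items() if c in (CLASS_AMYB, CLASS_AMYB_DEFECT)}
    amyb_defect = {g for g, c in cls_map.items() if c == CLASS_AMYB_DEFECT}

    ds = synthetic_data.SyntheticDataset(
        config=SimConfig(seed=config.seed),
        genes=genes,
        transcripts=transcripts,
        pirnas=pirnas,
        peaks=data["peaks"],
        precursor_counts=data["precursor_counts"],
        ercc_counts=data["ercc_counts"],
        totals=data["totals"],
        truth_cleavage=data["truth_cleavage"],
        truth_occupancy=data["truth_occupancy"],
        truth_classes=truth_classes,
    )
    ends = ds.observed_5p_ends()
    params = SiteParams(min_pairs=config.min_pairs, allow_wobble=config.allow_wobble)
    by_gene = {t.source_gene or t.transcript_id: t for t in transcripts}

    def run_direction(guide_genes: set, target_genes: set, name: str):
        guides = ds.pirna_objects(guide_genes)
        targets = [by_gene[g] for g in sorted(target_genes) if g in by_gene]
        edges, summary = predict_network(guides, targets, ends, params)
        logger.info("%s direction: %s", name, summary)
        return edges, summary

    fwd_edges, fwd_summary = run_direction(tcfl5_dep, amyb_defect, "forward")
    rev_edges, rev_summary = run_direction(amyb_dep, tcfl5_dep, "reverse")

    site_rows = [
        {
            "direction": direction,
            "source_gene": s.guide_gene,
            "target_gene": s.target_gene,
            "guide_sequence": s.guide_sequence,
            "t1": s.t1,
            "pairs_8_21": s.pairs_8_21,
            "responder_5p": s.responder_5p,
        }
        for direction, edges in (("forward", fwd_edges), ("reverse", rev_edges))
        for e in edges
        for s in e.sites
    ]
    write_table(
        pd.DataFrame(
            site_rows,
            columns=[
                "direction",
                "source_gene",
                "target_gene",
                "guide_sequence",
                "t1",
                "pairs_8_21",
                "responder_5p",
            ],
        ),
        outdir / "verified_sites.tsv",
    )
    edge_rows = [
        {
            "direction": direction,
            "source_gene": e.source_gene,
            "target_gene": e.target_gene,
            "n_guides": e.n_guides,
            "n_sites": len(e.sites),
        }
        for direction, edges in (("forward", fwd_edges), ("reverse", rev_edges))
        for e in edges
    ]
    write_table(
        pd.DataFrame(
            edge_rows,
            columns=["direction", "source_gene", "target_gene", "n_guides", "n_sites"],
        ),
        outdir / "edges.tsv",
    )

    # ------------------------------------------------------------------ stats
    fisher_fwd = _direction_fisher(fwd_edges, truth_classes)
    fisher_rev = _direction_fisher(rev_edges, truth_classes)

    bio = occupancy[
        (occupancy["gene_class"] == "piRNA_biogenesis")
        & (occupancy["factor"] == "TCFL5")
    ]
    bg = occupancy[
        (occupancy["gene_class"].isin(["other_coding", "other_noncoding"]))
        & (occupancy["factor"] == "TCFL5")
    ]
    if len(bio) and len(bg):
        chi_stat, chi_p = enrichment_stats.chi_square_enrichment(
            int(bio["bound"].sum()), len(bio), int(bg["bound"].sum()), len(bg)
        )
    else:
        chi_stat, chi_p = None, None

    occ_counts = (
        occupancy.groupby(["factor", "gene_class"])["bound"]
        .agg(["sum", "count"])
        .reset_index()
        .rename(columns={"sum": "n_bound", "count": "n_genes"})
    )
    occ_counts["n_bound"] = occ_counts["n_bound"].astype(int)

    report = {
        "config": dataclasses.asdict(config),
        "occupancy_by_class": occ_counts.to_dict(orient="records"),
        "dependence_class_tallies": {
            str(k): int(v)
            for k, v in calls["dependence_class"].value_counts().sort_index().items()
        },
        "network": {"forward": fwd_summary, "reverse": rev_summary},
        "fisher_conservation": {"forward": fisher_fwd, "reverse": fisher_rev},
        "chi_square_biogenesis_tcfl5": {"statistic": chi_stat, "p": chi_p},
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    with open(outdir / "summary.txt", "w") as fh:
        fh.write("pirnaflow run summary\n=====================\n\n")
        fh.write("Promoter occupancy (bound / total per gene class):\n")
        for rec in report["occupancy_by_class"]:
            fh.write(
                f"  {rec['factor']:>6} {rec['gene_class']:<18} "
                f"{rec['n_bound']}/{rec['n_genes']}\n"
            )
        fh.write("\nDependence classes:\n")
        for k, v in report["dependence_class_tallies"].items():
            fh.write(f"  {k:<34} {v}\n")
        for name, summ, fish in (
            ("forward (TCFL5-dep guides -> A-MYB-dep targets)", fwd_summary, fisher_fwd),
            ("reverse (A-MYB-dep guides -> TCFL5-dep targets)", rev_summary, fisher_rev),
        ):
            fh.write(f"\nInitiator->responder network, {name}:\n")
            fh.write(
                f"  {summ['n_distinct_guides']} distinct guide piRNAs from "
                f"{summ['n_source_genes']} source genes target "
                f"{summ['n_target_genes']} precursor genes "
                f"({summ['n_verified_sites']} verified sites)\n"
            )
            if fish["p"] is not None:
                fh.write(
                    f"  conservation (eutherian vs not) Fisher p = {fish['p']:.4g}\n"
                )
        if chi_p is not None:
            fh.write(
                f"\nTCFL5 at piRNA-biogenesis promoters vs background: "
                f"chi-square = {chi_stat:.3f}, p = {chi_p:.3g}\n"
            )
    logger.info("report written to %s", outdir / "report.json")
    return report
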