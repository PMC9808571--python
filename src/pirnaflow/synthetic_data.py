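"""Download-free synthetic cohort with planted ground truth for every stage.

The generator emulates the statistical structure of a pachytene piRNA study:
~100 piRNA-producing loci with 26-30 nt piRNAs, a piRNA-biogenesis gene set
and background genes; two genotypes (wild-type and a transcription-factor
mutant) related by per-gene fold-changes; CUT&RUN and ChIP-seq peak sets per
factor and replicate placed at controlled distances from TSSs; ERCC spike-in
counts; and a set of planted guide→target cleavage pairs, including decoys
that sit just below the pairing thresholds (nine pairs in g8-g21, or a
broken seed).

Everything is drawn from a single seeded generator, so a given configuration
is byte-reproducible.  Planted truth is constructed to satisfy the
target-prediction rules *exactly*: after planting, a scrub pass scans every
non-self guide-gene → target-gene combination and breaks, by a single
seed-opposite substitution outside any reserved window, any chance site that
would otherwise pass and verify.  Planted windows themselves are reserved
and never touched, so the verified sites recoverable from the cohort are
precisely the planted ones.

Background precursor sequence is uniform over {A,C,G,U}; per-locus abundance
is log-normal (the field reports heavy-tailed locus abundances but no
specific law); count noise is Poisson, or suppressed entirely
(``count_noise="none"``) for parameter-recovery checks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io_formats, quantification
from .io_formats import GeneAnnotation, PeakCall, PrecursorTranscript
from .quantification import (
    CLASS_AMYB,
    CLASS_AMYB_DEFECT,
    CLASS_TCFL5,
    CLASS_UNASSIGNED,
)
from .target_prediction import MIN_GUIDE_NT, PiRNA, encode, pair_profile, scan_pairing

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_BASES = np.array(list("ACGU"))

GENOTYPES = ("WT", "Tcfl5_hom")
COUNT_COLS = ("count_WT", "count_Tcfl5_hom")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort (defaults are the analysis
    conditions; see the methods note for rationale)."""

    seed: int = 1
    n_pirna_genes: int = 100
    n_biogenesis_genes: int = 14
    n_other_genes: int = 40
    precursor_length: int = 800
    pirna_length_range: tuple[int, int] = (26, 30)
    n_pirnas_per_gene: int = 25
    conservation_mix: dict = field(
        default_factory=lambda: {"eutherian": 0.21, "murine": 0.50, "mouse_only": 0.29}
    )
    class_counts: dict = field(
        default_factory=lambda: {
            CLASS_TCFL5: 30,
            CLASS_AMYB: 25,
            CLASS_AMYB_DEFECT: 10,
            CLASS_UNASSIGNED: 35,
        }
    )
    n_planted_edges: int = 10  # forward: TCFL5-dependent -> A-MYB-dependent
    n_reverse_edges: int = 5  # reverse direction
    n_decoy_9pairs: int = 3  # seed intact, only 9 pairs in g8-g21
    n_decoy_broken_seed: int = 3  # 14 pairs but one seed mismatch
    count_noise: str = "poisson"  # "poisson" | "none"
    median_gene_reads: float = 2000.0  # piRNA reads per locus (log-normal median)
    lognormal_sigma: float = 1.0
    median_precursor_reads: float = 500.0
    precursor_sigma: float = 0.5
    total_mapped_smallrna: float = 2.0e7  # genome-mapping reads, per genotype
    total_mapped_longrna: float = 2.0e7
    n_ercc: int = 20
    median_ercc_reads: float = 5000.0
    n_cells: int = 10000
    ercc_molecules: int = quantification.ERCC_MOLECULES
    window_bp: int = 500
    min_pairs: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.pirna_length_range
        if not (18 <= lo <= hi <= 34):
            raise ValueError("pirna_length_range must lie within [18, 34]")
        if abs(sum(self.conservation_mix.values()) - 1.0) > 1e-9:
            raise ValueError("conservation_mix proportions must sum to 1")
        if sum(self.class_counts.values()) != self.n_pirna_genes:
            raise ValueError("class_counts must sum to n_pirna_genes")
        if self.count_noise not in ("poisson", "none"):
            raise ValueError("count_noise must be 'poisson' or 'none'")
        if self.precursor_length < MIN_GUIDE_NT:
            raise ValueError("precursor_length must be >= 21")


@dataclass
class SyntheticDataset:
    """In-memory cohort; ``write`` emits exactly the formats io_formats reads."""

    config: SimConfig
    genes: list[GeneAnnotation]
    transcripts: list[PrecursorTranscript]
    pirnas: pd.DataFrame  # sequence, source_gene, start, length, count_*
    peaks: dict  # (factor, assay, replicate) -> list[PeakCall]
    precursor_counts: pd.DataFrame
    ercc_counts: pd.DataFrame
    totals: dict  # (library, genotype) -> total mapped reads
    truth_cleavage: pd.DataFrame
    truth_occupancy: pd.DataFrame
    truth_classes: pd.DataFrame

    def observed_5p_ends(self) -> dict[str, frozenset[int]]:
        """Observed piRNA 5' ends per gene (genotypes pooled, count > 0)."""
        mask = self.pirnas[list(COUNT_COLS)].sum(axis=1) > 0
        sub = self.pirnas[mask]
        return {
            gene: frozenset(int(s) for s in grp["start"])
            for gene, grp in sub.groupby("source_gene")
        }

    def pirna_objects(self, genes: set[str] | None = None) -> list[PiRNA]:
        rows = self.pirnas
        if genes is not None:
            rows = rows[rows["source_gene"].isin(genes)]
        return [
            PiRNA(
                r.sequence,
                r.source_gene,
                {"WT": r.count_WT, "Tcfl5_hom": r.count_Tcfl5_hom},
                int(r.start),
            )
            for r in rows.itertuples()
        ]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io_formats.write_fasta(self.transcripts, outdir / "transcripts.fa")
        io_formats.write_table(self.pirnas, outdir / "pirna_counts.tsv")
        io_formats.write_table(self.precursor_counts, outdir / "precursor_counts.tsv")
        io_formats.write_table(self.ercc_counts, outdir / "ercc_counts.tsv")
        io_formats.write_gene_annotations(self.genes, outdir / "genes.bed")
        peakdir = outdir / "peaks"
        peakdir.mkdir(exist_ok=True)
        for (factor, assay, rep) in sorted(self.peaks):
            calls = self.peaks[(factor, assay, rep)]
            safe = factor.replace("-", "")
            if assay == "CHIP":
                path = peakdir / f"{safe}_CHIP_rep{rep}.narrowPeak"
                with open(path, "w") as fh:
                    for p in sorted(calls, key=lambda q: (q.chrom, q.start)):
                        offset = p.summit - 1 - p.start
                        fh.write(
                            f"{p.chrom}\t{p.start}\t{p.end}\tpeak\t{p.score:.0f}\t."
                            f"\t0\t-1\t-1\t{offset}\n"
                        )
            else:
                path = peakdir / f"{safe}_CUTRUN_rep{rep}.bed"
                with open(path, "w") as fh:
                    for p in sorted(calls, key=lambda q: (q.chrom, q.start)):
                        fh.write(
                            f"{p.chrom}\t{p.start}\t{p.end}\tpeak\t{p.score:.0f}\t.\n"
                        )
        totals_rows = [
            {"library": lib, "genotype": gt, "total_mapped": tot}
            for (lib, gt), tot in sorted(self.totals.items())
        ]
        io_formats.write_table(pd.DataFrame(totals_rows), outdir / "totals.tsv")
        io_formats.write_table(self.truth_cleavage, outdir / "truth_cleavage.tsv")
        io_formats.write_table(self.truth_occupancy, outdir / "truth_occupancy.tsv")
        io_formats.write_table(self.truth_classes, outdir / "truth_classes.tsv")
        with open(outdir / "sim_config.yaml", "w") as fh:
            cfg = dataclasses.asdict(self.config)
            cfg["pirna_length_range"] = list(cfg["pirna_length_range"])
            yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# planting primitives


class _Reservations:
    """Per-transcript 1-based inclusive intervals that later edits must avoid."""

    def __init__(self) -> None:
        self._by_tid: dict[str, list[tuple[int, int]]] = {}

    def overlaps(self, tid: str, lo: int, hi: int) -> bool:
        return any(
            not (hi < a or lo > b) for (a, b) in self._by_tid.get(tid, [])
        )

    def add(self, tid: str, lo: int, hi: int) -> None:
        self._by_tid.setdefault(tid, []).append((lo, hi))

    def is_free(self, tid: str, pos: int) -> bool:
        return not self.overlaps(tid, pos, pos)


def plant_cleavage_pair(
    guide_seq: str,
    target_seq: list[str],
    anchor_t1: int,
    n_pairs_8_21: int,
    seed_intact: bool,
    rng: np.random.Generator,
) -> None:
    """Edit ``target_seq`` (mutable list of bases) in place so that the guide
    has exactly the requested pairing profile at ``anchor_t1``.

    Unpaired positions receive the guide's own base, which can pair under
    neither the Watson-Crick nor the G:U wobble policy.
    """
    if not (MIN_GUIDE_NT <= anchor_t1 <= len(target_seq)):
        raise ValueError(
            f"anchor_t1={anchor_t1} out of bounds for transcript of "
            f"length {len(target_seq)}"
        )
    if not (0 <= n_pairs_8_21 <= 14):
        raise ValueError("n_pairs_8_21 must be within [0, 14]")
    if len(guide_seq) < MIN_GUIDE_NT:
        raise ValueError("guide shorter than 21 nt")
    paired: set[int] = set()
    if seed_intact:
        paired.update(range(2, 8))
    else:
        broken = int(rng.integers(2, 8))
        paired.update(i for i in range(2, 8) if i != broken)
    paired.update(
        int(i) for i in rng.choice(np.arange(8, 22), size=n_pairs_8_21, replace=False)
    )
    for i in range(2, 22):
        pos = anchor_t1 - (i - 1)  # 1-based target position facing guide i
        base = guide_seq[i - 1]
        target_seq[pos - 1] = _COMPLEMENT[base] if i in paired else base


def plant_peaks(
    gene: GeneAnnotation,
    factor: str,
    distances: Mapping[str, Sequence[int | None]],
) -> list[PeakCall]:
    """Peak records with summits at TSS + distance, per assay and replicate.

    ``distances`` maps assay ("CUTRUN"/"CHIP") to one signed distance per
    replicate; ``None`` means no peak in that replicate.
    """
    out: list[PeakCall] = []
    for assay, ds in distances.items():
        for rep, d in enumerate(ds, start=1):
            if d is None:
                continue
            summit = gene.tss + d  # 1-based
            s0 = summit - 1
            if assay == "CUTRUN":
                start, end = s0 - 150, s0 + 150  # midpoint == summit
            else:
                start, end = s0 - 120, s0 + 120
            out.append(
                PeakCall(
                    chrom=gene.chrom,
                    start=max(0, start),
                    end=end,
                    summit=summit,
                    score=100.0,
                    factor=factor,
                    assay=assay,
                    replicate=rep,
                )
            )
    return out


def consensus_from_distances(
    factor: str,
    cutrun: Sequence[int | None],
    chip: Sequence[int | None],
    window_bp: int = 500,
) -> tuple[bool, str]:
    """The replicate-consensus rule applied directly to planted distances."""
    cut = [d is not None and abs(d) <= window_bp for d in cutrun]
    chip_in = [d is not None and abs(d) <= window_bp for d in chip]
    chip_ok = sum(chip_in) >= (2 if factor == "TCFL5" else 1)
    if all(cut):
        return True, "cutrun_both"
    if any(cut) and chip_ok:
        return True, "cutrun_plus_chip"
    return False, "none"


def simulate_counts(
    expected: np.ndarray, rng: np.random.Generator, noise: str
) -> np.ndarray:
    """Poisson draws around the expectation, or the expectation itself."""
    if noise == "poisson":
        return rng.poisson(expected).astype(float)
    return np.asarray(expected, dtype=float)


# ---------------------------------------------------------------------------
# cohort generation


def _gene_layout(config: SimConfig, rng: np.random.Generator):
    """Assign chromosomes, TSSs, strands and classes to all genes."""
    genes: list[GeneAnnotation] = []
    specs = (
        [("pi%03d" % (i + 1), "pachytene_piRNA") for i in range(config.n_pirna_genes)]
        + [
            ("bio%02d" % (i + 1), "piRNA_biogenesis")
            for i in range(config.n_biogenesis_genes)
        ]
        + [
            (
                "gen%03d" % (i + 1),
                "other_coding" if i % 4 else "other_noncoding",
            )
            for i in range(config.n_other_genes)
        ]
    )
    chroms = ["chr%d" % (i + 1) for i in range(4)]
    per_chrom = {c: 0 for c in chroms}
    for idx, (gene_id, gene_class) in enumerate(specs):
        chrom = chroms[idx % len(chroms)]
        tss = 100_000 + per_chrom[chrom] * 60_000
        per_chrom[chrom] += 1
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(gene_id, chrom, tss, strand, gene_class))
    return genes


def _assign_classes(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    ids = ["pi%03d" % (i + 1) for i in range(config.n_pirna_genes)]
    labels: list[str] = []
    for cls, n in sorted(config.class_counts.items()):
        labels.extend([cls] * n)
    labels = list(np.array(labels)[rng.permutation(len(labels))])
    return dict(zip(ids, labels))


_CLASS_CONSERVATION = {
    # TCFL5-dependent loci are evolutionarily young; A-MYB-dependent old.
    CLASS_TCFL5: (["murine", "mouse_only"], [0.6, 0.4]),
    CLASS_AMYB: (["eutherian", "murine", "mouse_only"], [0.6, 0.3, 0.1]),
    CLASS_AMYB_DEFECT: (["eutherian", "murine", "mouse_only"], [0.6, 0.3, 0.1]),
}


def _assign_conservation(
    config: SimConfig, classes: dict[str, str], rng: np.random.Generator
) -> dict[str, str]:
    out = {}
    mix_names = sorted(config.conservation_mix)
    mix_p = [config.conservation_mix[k] for k in mix_names]
    for gene_id, cls in classes.items():
        names, p = _CLASS_CONSERVATION.get(cls, (mix_names, mix_p))
        out[gene_id] = str(rng.choice(names, p=p))
    return out


def _assign_fold_changes(
    classes: dict[str, str], rng: np.random.Generator
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-gene precursor and piRNA fold-changes (mutant / wild-type) with
    margins away from the twofold classification boundary."""
    fc_prec: dict[str, float] = {}
    fc_pirna: dict[str, float] = {}
    for gene_id, cls in classes.items():
        if cls == CLASS_TCFL5:
            fc_prec[gene_id] = float(rng.uniform(0.20, 0.35))
            fc_pirna[gene_id] = float(rng.uniform(0.15, 0.30))
        elif cls == CLASS_AMYB:
            fc_prec[gene_id] = float(rng.uniform(0.80, 1.20))
            fc_pirna[gene_id] = float(rng.uniform(0.80, 1.20))
        elif cls == CLASS_AMYB_DEFECT:
            fc_prec[gene_id] = float(rng.uniform(0.80, 1.20))
            fc_pirna[gene_id] = float(rng.uniform(0.20, 0.35))
        else:
            fc_prec[gene_id] = float(rng.uniform(0.60, 1.40))
            fc_pirna[gene_id] = float(rng.uniform(0.60, 1.40))
    return fc_prec, fc_pirna


def _plan_occupancy(
    genes: Sequence[GeneAnnotation],
    classes: dict[str, str],
    rng: np.random.Generator,
    window_bp: int,
):
    """Decide bound/unbound per gene and factor, draw peak distances, and
    compute the truth label with :func:`consensus_from_distances`."""

    def bound_pattern(factor: str, variant: int):
        n_chip = 3 if factor == "TCFL5" else 1
        near = lambda: int(rng.integers(-window_bp, window_bp + 1))
        far = lambda: int(rng.integers(window_bp + 1, 3001)) * (
            1 if rng.random() < 0.5 else -1
        )
        if variant == 0:  # rule (i): both CUT&RUN replicates
            cut = [near(), near()]
            chip = [near() if rng.random() < 0.5 else None for _ in range(n_chip)]
        elif variant == 1:  # rule (ii): one CUT&RUN + ChIP consensus
            cut = [near(), far()]
            chip = [near()] * n_chip if n_chip == 1 else [near(), near(), far()]
        else:  # rule (ii), second replicate absent, full ChIP support
            cut = [near(), None]
            chip = [near()] * n_chip
        return cut, chip

    def unbound_pattern(factor: str, variant: int):
        n_chip = 3 if factor == "TCFL5" else 1
        far = lambda: int(rng.integers(window_bp + 1, 3001)) * (
            1 if rng.random() < 0.5 else -1
        )
        near = lambda: int(rng.integers(-window_bp, window_bp + 1))
        if variant == 0:  # no peaks at all
            return [None, None], [None] * n_chip
        if variant == 1:  # one CUT&RUN rep only, insufficient ChIP
            chip = [None] * n_chip if n_chip == 1 else [near(), None, None]
            return [near(), None], chip
        return [far(), far()], [far()] * n_chip  # peaks, all beyond the window

    plan: dict[tuple[str, str], tuple[list, list]] = {}
    truth_rows = []
    counters = {"TCFL5": 0, "A-MYB": 0}
    for gene in genes:
        cls = classes.get(gene.gene_id)
        for factor in ("TCFL5", "A-MYB"):
            if gene.gene_class == "pachytene_piRNA":
                if cls == CLASS_TCFL5:
                    want = factor == "TCFL5" or rng.random() < 0.5
                elif cls in (CLASS_AMYB, CLASS_AMYB_DEFECT):
                    want = factor == "A-MYB" or rng.random() < 0.25
                else:  # unassigned: never A-MYB; sometimes TCFL5 with flat fc
                    want = factor == "TCFL5" and rng.random() < 0.4
            elif gene.gene_class == "piRNA_biogenesis":
                want = factor == "TCFL5" or rng.random() < 0.6
            else:
                want = rng.random() < (0.10 if factor == "TCFL5" else 0.20)
            variant = counters[factor] % 3
            counters[factor] += 1
            cut, chip = (
                bound_pattern(factor, variant)
                if want
                else unbound_pattern(factor, variant)
            )
            if gene.gene_class == "piRNA_biogenesis" and want and factor == "TCFL5":
                # the TCFL5 signal at biogenesis promoters is centred on the
                # TSS (median distance 0 in the data this emulates)
                cut = [0, 0]
                chip = [0 if rng.random() < 0.7 else None for _ in range(3)]
            bound, evidence = consensus_from_distances(factor, cut, chip, window_bp)
            plan[(gene.gene_id, factor)] = (cut, chip)
            truth_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "factor": factor,
                    "bound": bound,
                    "evidence": evidence,
                }
            )
    return plan, pd.DataFrame(truth_rows)


def generate_cohort(config: SimConfig) -> SyntheticDataset:
    """Generate the full synthetic cohort (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    L = config.precursor_length
    len_lo, len_hi = config.pirna_length_range

    genes = _gene_layout(config, rng)
    gene_by_id = {g.gene_id: g for g in genes}
    pirna_gene_ids = [g.gene_id for g in genes if g.gene_class == "pachytene_piRNA"]
    classes = _assign_classes(config, rng)
    conservation = _assign_conservation(config, classes, rng)
    fc_prec, fc_pirna = _assign_fold_changes(classes, rng)

    # --- precursor transcripts (mutable during planting) ------------------
    seqs: dict[str, list[str]] = {
        gid: list(rng.choice(_BASES, size=L)) for gid in pirna_gene_ids
    }
    reservations = _Reservations()

    # --- plan the random piRNA complement per locus ------------------------
    # (gene, start, length, is_planted); sequences are extracted after all
    # edits so every emitted piRNA is an exact substring of its precursor
    pirna_plan: list[tuple[str, int, int, bool]] = []
    for gid in pirna_gene_ids:
        starts = rng.choice(
            np.arange(1, L - len_hi + 1),
            size=config.n_pirnas_per_gene,
            replace=False,
        )
        for s in sorted(int(x) for x in starts):
            pirna_plan.append((gid, s, int(rng.integers(len_lo, len_hi + 1)), False))

    # --- plant cleavage pairs ----------------------------------------------
    by_class: dict[str, list[str]] = {}
    for gid, cls in classes.items():
        by_class.setdefault(cls, []).append(gid)

    def pick_window(tid: str, lo_t1: int, hi_t1: int) -> int:
        for _ in range(200):
            t1 = int(rng.integers(lo_t1, hi_t1 + 1))
            if not reservations.overlaps(tid, t1 - 20, t1):
                reservations.add(tid, t1 - 20, t1)
                return t1
        raise RuntimeError(f"could not reserve a planting window on {tid}")

    def pick_guide(gid: str) -> tuple[int, int]:
        for _ in range(200):
            glen = int(rng.integers(len_lo, len_hi + 1))
            gstart = int(rng.integers(1, L - glen + 2))
            if not reservations.overlaps(gid, gstart, gstart + glen - 1):
                reservations.add(gid, gstart, gstart + glen - 1)
                return gstart, glen
        raise RuntimeError(f"could not reserve a guide window on {gid}")

    truth_rows = []

    def plant(direction: str, src_pool, tgt_pool, n_pairs: int, seed_ok: bool, n: int):
        used_pairs = {(r["source_gene"], r["target_gene"]) for r in truth_rows}
        planted = 0
        while planted < n:
            src = str(rng.choice(src_pool))
            tgt = str(rng.choice(tgt_pool))
            if src == tgt or (src, tgt) in used_pairs:
                continue
            gstart, glen = pick_guide(src)
            guide_seq = "".join(seqs[src][gstart - 1 : gstart - 1 + glen])
            # keep the anchor clear of the transcript ends so the responder
            # (up to len_hi nt from t1-9) fits inside the precursor
            t1 = pick_window(tgt, 60, L - len_hi - 10)
            plant_cleavage_pair(
                guide_seq, seqs[tgt], t1, n_pairs, seed_ok, rng
            )
            resp_len = int(rng.integers(len_lo, len_hi + 1))
            pirna_plan.append((tgt, t1 - 9, resp_len, True))
            pirna_plan.append((src, gstart, glen, True))
            used_pairs.add((src, tgt))
            truth_rows.append(
                {
                    "direction": direction,
                    "source_gene": src,
                    "target_gene": tgt,
                    "guide_start": gstart,
                    "guide_length": glen,
                    "t1": t1,
                    "seed_intact": seed_ok,
                    "n_pairs_8_21": n_pairs,
                    "responder_5p": t1 - 9,
                    "expected_pass": seed_ok and n_pairs >= config.min_pairs,
                }
            )
            planted += 1

    fwd_src = by_class.get(CLASS_TCFL5, [])
    fwd_tgt = by_class.get(CLASS_AMYB_DEFECT, [])
    rev_src = by_class.get(CLASS_AMYB, []) + by_class.get(CLASS_AMYB_DEFECT, [])
    rev_tgt = fwd_src
    if config.n_planted_edges and (not fwd_src or not fwd_tgt):
        raise ValueError("cannot plant edges: a dependence class is empty")
    plant("forward", fwd_src, fwd_tgt, 14, True, config.n_planted_edges)
    plant("forward", fwd_src, fwd_tgt, 9, True, config.n_decoy_9pairs)
    plant("forward", fwd_src, fwd_tgt, 14, False, config.n_decoy_broken_seed)
    if config.n_reverse_edges:
        plant("reverse", rev_src, rev_tgt, 14, True, config.n_reverse_edges)

    truth_cleavage = pd.DataFrame(truth_rows)
    if truth_cleavage.empty:
        truth_cleavage = pd.DataFrame(
            columns=[
                "direction",
                "source_gene",
                "target_gene",
                "guide_start",
                "guide_length",
                "t1",
                "seed_intact",
                "n_pairs_8_21",
                "responder_5p",
                "expected_pass",
                "guide_sequence",
            ]
        )

    # --- scrub accidental pass-and-verify sites ----------------------------
    observed_ends = {}
    for gid, s, _, _ in pirna_plan:
        observed_ends.setdefault(gid, set()).add(s)
    planted_keys = set()
    if len(truth_cleavage):
        for r in truth_cleavage.itertuples():
            planted_keys.add((r.source_gene, r.target_gene, int(r.t1)))
    _scrub(
        seqs, pirna_plan, observed_ends, planted_keys, reservations, config, rng
    )

    # --- defensive check: planted truth satisfies the rules exactly --------
    for r in truth_cleavage.itertuples():
        gseq = "".join(
            seqs[r.source_gene][r.guide_start - 1 : r.guide_start - 1 + r.guide_length]
        )
        tseq = "".join(seqs[r.target_gene])
        seed_m, pairs = pair_profile(gseq, tseq, int(r.t1))
        if seed_m != bool(r.seed_intact) or pairs != int(r.n_pairs_8_21):
            raise RuntimeError(
                f"planted profile corrupted at {r.source_gene}->{r.target_gene}"
            )

    transcripts = [
        PrecursorTranscript(
            transcript_id=f"{gid}_precursor",
            sequence="".join(seqs[gid]),
            source_gene=gid,
            conservation=conservation[gid],
        )
        for gid in pirna_gene_ids
    ]
    if len(truth_cleavage):
        truth_cleavage["guide_sequence"] = [
            "".join(
                seqs[r.source_gene][
                    r.guide_start - 1 : r.guide_start - 1 + r.guide_length
                ]
            )
            for r in truth_cleavage.itertuples()
        ]

    # --- piRNA counts -------------------------------------------------------
    rows = []
    for gid in pirna_gene_ids:
        mine = [(s, ln, planted) for g, s, ln, planted in pirna_plan if g == gid]
        total = config.median_gene_reads * float(
            rng.lognormal(0.0, config.lognormal_sigma)
        )
        weights = rng.dirichlet(np.ones(len(mine)))
        for (s, ln, planted), w in zip(mine, weights):
            expect_wt = total * w + (50.0 if planted else 0.0)
            expect_mut = expect_wt * fc_pirna[gid]
            rows.append((gid, s, ln, expect_wt, expect_mut))
    exp = np.array([(r[3], r[4]) for r in rows])
    drawn = np.column_stack(
        [
            simulate_counts(exp[:, 0], rng, config.count_noise),
            simulate_counts(exp[:, 1], rng, config.count_noise),
        ]
    )
    pirnas = pd.DataFrame(
        {
            "sequence": [
                "".join(seqs[gid][s - 1 : s - 1 + ln]) for gid, s, ln, _, _ in rows
            ],
            "source_gene": [r[0] for r in rows],
            "start": [r[1] for r in rows],
            "length": [r[2] for r in rows],
            "count_WT": drawn[:, 0],
            "count_Tcfl5_hom": drawn[:, 1],
        }
    )
    # merge piRNA species that coincide in sequence and position
    pirnas = (
        pirnas.groupby(["source_gene", "start", "length", "sequence"], as_index=False)[
            ["count_WT", "count_Tcfl5_hom"]
        ]
        .sum()
        .sort_values(["source_gene", "start", "length"])
        .reset_index(drop=True)
    )[["sequence", "source_gene", "start", "length", "count_WT", "count_Tcfl5_hom"]]

    # --- precursor (long RNA) counts ---------------------------------------
    prec_rows = []
    for gid in pirna_gene_ids:
        wt = config.median_precursor_reads * float(
            rng.lognormal(0.0, config.precursor_sigma)
        )
        prec_rows.append((gid, L, wt, wt * fc_prec[gid]))
    pexp = np.array([(r[2], r[3]) for r in prec_rows])
    pdrawn = np.column_stack(
        [
            simulate_counts(pexp[:, 0], rng, config.count_noise),
            simulate_counts(pexp[:, 1], rng, config.count_noise),
        ]
    )
    precursor_counts = pd.DataFrame(
        {
            "gene_id": [r[0] for r in prec_rows],
            "length_nt": [r[1] for r in prec_rows],
            "count_WT": pdrawn[:, 0],
            "count_Tcfl5_hom": pdrawn[:, 1],
        }
    )

    # --- ERCC spike-ins ------------------------------------------------------
    ercc_exp = config.median_ercc_reads * rng.lognormal(
        0.0, 0.5, size=config.n_ercc
    )
    ercc_counts = pd.DataFrame(
        {
            "ercc_id": ["ERCC-%05d" % (i + 1) for i in range(config.n_ercc)],
            "count_WT": simulate_counts(ercc_exp, rng, config.count_noise),
            "count_Tcfl5_hom": simulate_counts(ercc_exp, rng, config.count_noise),
        }
    )

    # --- peaks ---------------------------------------------------------------
    plan, truth_occupancy = _plan_occupancy(genes, classes, rng, config.window_bp)
    peaks: dict[tuple[str, str, int], list[PeakCall]] = {}
    for factor in ("TCFL5", "A-MYB"):
        n_chip = 3 if factor == "TCFL5" else 1
        for rep in (1, 2):
            peaks[(factor, "CUTRUN", rep)] = []
        for rep in range(1, n_chip + 1):
            peaks[(factor, "CHIP", rep)] = []
    for gene in genes:
        for factor in ("TCFL5", "A-MYB"):
            cut, chip = plan[(gene.gene_id, factor)]
            for p in plant_peaks(gene, factor, {"CUTRUN": cut, "CHIP": chip}):
                peaks[(factor, p.assay, p.replicate)].append(p)

    truth_classes = pd.DataFrame(
        {
            "gene_id": pirna_gene_ids,
            "dependence_class": [classes[g] for g in pirna_gene_ids],
            "conservation": [conservation[g] for g in pirna_gene_ids],
            "fc_precursor": [fc_prec[g] for g in pirna_gene_ids],
            "fc_pirna": [fc_pirna[g] for g in pirna_gene_ids],
        }
    )

    totals = {
        ("smallRNA", "WT"): config.total_mapped_smallrna,
        ("smallRNA", "Tcfl5_hom"): config.total_mapped_smallrna,
        ("longRNA", "WT"): config.total_mapped_longrna,
        ("longRNA", "Tcfl5_hom"): config.total_mapped_longrna,
    }

    return SyntheticDataset(
        config=config,
        genes=genes,
        transcripts=transcripts,
        pirnas=pirnas,
        peaks=peaks,
        precursor_counts=precursor_counts,
        ercc_counts=ercc_counts,
        totals=totals,
        truth_cleavage=truth_cleavage,
        truth_occupancy=truth_occupancy,
        truth_classes=truth_classes,
    )


def _scrub(
    seqs: dict[str, list[str]],
    pirna_plan: list[tuple[str, int, int, bool]],
    observed_ends: dict[str, set[int]],
    planted_keys: set[tuple[str, str, int]],
    reservations: _Reservations,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Break chance sites that would pass and verify but were not planted.

    Scans every guide species against every non-self precursor (so the
    cohort is clean for *any* downstream class assignment) and substitutes a
    single seed-opposite base -- outside all reserved windows -- at each
    accidental hit.  Planted windows are reserved, hence untouchable.
    """
    gene_ids = sorted(seqs)
    for _ in range(10):
        guide_info = [
            (gid, s, ln)
            for gid, s, ln, _ in pirna_plan
            if ln >= MIN_GUIDE_NT
        ]
        guide_encs = np.stack(
            [
                encode("".join(seqs[gid][s - 1 : s - 1 + MIN_GUIDE_NT]))
                for gid, s, ln in guide_info
            ]
        )
        guide_gene = np.array([g[0] for g in guide_info])
        accidental: list[tuple[str, str, int, str]] = []  # tgt, src, t1, guide_seq
        for tgt in gene_ids:
            ends = observed_ends.get(tgt, set())
            if not ends:
                continue
            tenc = encode("".join(seqs[tgt]))
            seed, pairs = scan_pairing(guide_encs, tenc)
            gi, si = np.nonzero(seed & (pairs >= config.min_pairs))
            for g_idx, s in zip(gi.tolist(), si.tolist()):
                src = str(guide_gene[g_idx])
                t1 = s + MIN_GUIDE_NT
                if src == tgt or (t1 - 9) not in ends:
                    continue
                if (src, tgt, t1) in planted_keys:
                    continue
                gid, gs, gl = guide_info[g_idx]
                gseq = "".join(seqs[gid][gs - 1 : gs - 1 + gl])
                accidental.append((tgt, src, t1, gseq))
        if not accidental:
            return
        for tgt, _src, t1, gseq in accidental:
            fixed = False
            for i in list(range(2, 8)) + list(range(8, 22)):
                pos = t1 - (i - 1)
                if pos < 1 or not reservations.is_free(tgt, pos):
                    continue
                seqs[tgt][pos - 1] = gseq[i - 1]  # same base: pairs under no policy
                fixed = True
                break
            if not fixed:
                raise RuntimeError(
                    f"could not scrub accidental site on {tgt} at t1={t1}"
                )
    raise RuntimeError("scrub did not converge after 10 iterations")


# ---------------------------------------------------------------------------
# loading a written cohort back


def load_cohort(outdir: str | Path) -> dict:
    """Load a written cohort directory into the pipeline's input structures."""
    outdir = Path(outdir)
    transcripts = io_formats.read_fasta(outdir / "transcripts.fa")
    genes = io_formats.read_gene_annotations(outdir / "genes.bed")
    # transcripts are named <gene>_precursor; restore the linkage
    gene_ids = {g.gene_id for g in genes}
    truth_classes = io_formats.read_table(outdir / "truth_classes.tsv")
    conservation = dict(
        zip(truth_classes["gene_id"], truth_classes["conservation"])
    )
    for t in transcripts:
        gid = t.transcript_id.removesuffix("_precursor")
        if gid in gene_ids:
            t.source_gene = gid
            t.conservation = conservation.get(gid)
    peaks: dict[tuple[str, str, int], list[PeakCall]] = {}
    for path in sorted((outdir / "peaks").iterdir()):
        stem = path.stem  # e.g. TCFL5_CUTRUN_rep1
        name, assay, rep = stem.split("_")
        factor = "A-MYB" if name == "AMYB" else name
        rep_no = int(rep.removeprefix("rep"))
        dialect = "narrowPeak" if assay == "CHIP" else "bed6_summitless"
        peaks[(factor, assay, rep_no)] = io_formats.read_peaks(
            path, dialect, factor=factor, assay=assay, replicate=rep_no
        )
    totals_df = io_formats.read_table(outdir / "totals.tsv")
    totals = {
        (r.library, r.genotype): float(r.total_mapped)
        for r in totals_df.itertuples()
    }
    return {
        "genes": genes,
        "transcripts": transcripts,
        "pirnas": io_formats.read_table(outdir / "pirna_counts.tsv"),
        "peaks": peaks,
        "precursor_counts": io_formats.read_table(outdir / "precursor_counts.tsv"),
        "ercc_counts": io_formats.read_table(outdir / "ercc_counts.tsv"),
        "totals": totals,
        "truth_cleavage": io_formats.read_table(outdir / "truth_cleavage.tsv"),
        "truth_occupancy": io_formats.read_table(outdir / "truth_occupancy.tsv"),
        "truth_classes": truth_classes,
    }
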