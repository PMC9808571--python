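"""Call promoter occupancy from replicate CUT&RUN + ChIP-seq peak sets.

One gene is supported by both CUT&RUN replicates, one by a single CUT&RUN
replicate rescued by 2/3 ChIP replicates, and one only by ChIP (insufficient
under the consensus rule).
"""

from pirnaflow import GeneAnnotation, PeakCall, is_bound_consensus


def peak(summit):
    return [PeakCall("chr1", summit - 151, summit + 149, summit)]


NONE = []  # replicate with no peak near this promoter

genes_and_evidence = [
    ("both-cutrun", [peak(10_000), peak(10_020)], [NONE, NONE, NONE]),
    ("one-cutrun+chip", [peak(10_030), NONE], [peak(10_000), peak(9_990), NONE]),
    ("chip-only", [NONE, NONE], [peak(10_000), peak(10_000), peak(10_000)]),
]

for name, cutrun, chip in genes_and_evidence:
    gene = GeneAnnotation(name, "chr1", 10_000, "+", "pachytene_piRNA")
    rec = is_bound_consensus(gene, "TCFL5", cutrun, chip)
    print(
        f"{name:>16}: bound={rec.bound!s:<5} evidence={rec.evidence:<16} "
        f"nearest summit {rec.distance_bp} bp from TSS"
        if rec.distance_bp is not None
        else f"{name:>16}: bound={rec.bound} (no peak on this chromosome)"
    )

# A promoter counts as TCFL5-bound only with peaks within 500 bp of the TSS
# in both CUT&RUN replicates, or in one CUT&RUN replicate plus two of three
# ChIP-seq replicates; ChIP evidence alone never suffices.
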