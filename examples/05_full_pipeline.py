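"""Run the whole pipeline on a simulated cohort and print the report.

Simulates a noise-free 100-locus cohort, annotates promoters, classifies
dependence, predicts the initiator->responder network in both directions,
and runs the enrichment statistics.  Takes a short while (the generator
scrubs chance cleavage sites from ~2,500 piRNA species x 100 precursors).
"""

import json
import tempfile

from pirnaflow import RunConfig, run_all

with tempfile.TemporaryDirectory() as tmp:
    report = run_all(RunConfig(seed=1, outdir=tmp, count_noise="none"))

print("dependence classes:", report["dependence_class_tallies"])
for direction in ("forward", "reverse"):
    s = report["network"][direction]
    f = report["fisher_conservation"][direction]
    print(
        f"{direction}: {s['n_distinct_guides']} guides from "
        f"{s['n_source_genes']} source genes -> {s['n_target_genes']} targets "
        f"({s['n_verified_sites']} verified sites); "
        f"conservation Fisher p = {f['p']:.3g}"
    )
chi = report["chi_square_biogenesis_tcfl5"]
print(
    f"TCFL5 at biogenesis promoters vs background: "
    f"chi2 = {chi['statistic']:.1f}, p = {chi['p']:.2g}"
)

# The forward direction mirrors the biological claim: piRNAs from young,
# TCFL5-dependent loci initiate piRNA production on older, A-MYB-dependent
# precursors; every verified edge here was planted by the simulator.
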