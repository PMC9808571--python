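"""Normalize counts, convert to molecules per cell, and classify dependence."""

from pirnaflow import classify_dependence, fold_change, molecules_per_cell, rpkm, rpm

# rpm / RPKM on a toy library
print("rpm of 5 reads in a 10-read library:", rpm([5], 10)[0])
print("RPKM of 100 reads over 1 kb at 1e6 mapped:", rpkm(100, 1000, 1_000_000))

# ERCC spike-in absolute quantification: each library carries a known
# 623,291,645 spike molecules
m = molecules_per_cell(gene_reads=10, ercc_reads=623_291_645, n_cells=1000)
print(f"10 gene reads, spike-saturated library, 1000 cells -> {m} molecules/cell")

# dependence classification from occupancy + mutant/wild-type fold-changes
cases = [
    ("TCFL5-bound, precursor 0.3x, piRNA 0.2x", True, False, 0.3, 0.2),
    ("A-MYB-bound, precursor 0.9x, piRNA 0.4x", False, True, 0.9, 0.4),
    ("A-MYB-bound, both essentially unchanged", False, True, 1.1, 0.9),
    ("unbound by either factor", False, False, 0.2, 0.2),
]
for label, tcfl5, amyb, fp, fq in cases:
    call = classify_dependence("demo", tcfl5, amyb, fp, fq)
    print(f"{label:<45} -> {call.dependence_class}")

# fold-change guards against zero counts with a pseudocount
print("fold change wt=0, mut=0, pc=0.1:", fold_change(0, 0, 0.1))
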