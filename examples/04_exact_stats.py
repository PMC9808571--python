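"""Exact and rank statistics: Fisher, chi-square enrichment, Spearman, box stats."""

from pirnaflow import (
    ContingencyTable,
    box_stats,
    chi_square_enrichment,
    fisher_exact_two_sided,
    spearman,
)

# Conservation of initiator vs target piRNA genes: 5 initiator genes (none
# eutherian-syntenic) against 7 target genes (5 eutherian-syntenic)
p = fisher_exact_two_sided(ContingencyTable(0, 5, 5, 2))
print(f"Fisher's exact test (two-sided), initiators vs targets: P = {p:.4f}")

# TCFL5 peaks at piRNA-biogenesis promoters vs background promoters
stat, p = chi_square_enrichment(14, 14, 40, 400)
print(f"chi-square promoter enrichment: statistic = {stat:.1f}, P = {p:.2e}")

# rank correlation between promoter occupancy and CG content
rho = spearman([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5])
print(f"Spearman's rho = {rho:.3f}")

# box-plot summary with the 1.5 x IQR outlier rule
bs = box_stats(list(range(1, 10)) + [100])
print(
    f"distances: median {bs.median}, Q1-Q3 [{bs.q1}, {bs.q3}], "
    f"whiskers [{bs.whisker_low}, {bs.whisker_high}], outliers {bs.outliers}"
)
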