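"""Nucleotide-level interval metrics between a truth set and called peaks.

Jaccard, TPR and FDR all count base pairs of half-open intervals after
merging overlaps within each set — the same arithmetic used to benchmark
the caller on simulated data.
"""

from broadcall import IntervalSet, fdr, genes_overlapping, jaccard, tpr

truth = IntervalSet.from_intervals([
    ("chr1", 1_000, 21_000),
    ("chr1", 50_000, 70_000),
    ("chr2", 0, 30_000),
])
called = IntervalSet.from_intervals([
    ("chr1", 800, 19_200),    # most of the first domain
    ("chr1", 64_000, 72_000), # tail of the second, plus 2 kb false positive
    ("chr2", 0, 30_400),      # the whole third, slightly over-called
])

print(f"truth bp: {truth.total_bp():,}, called bp: {called.total_bp():,}")
print(f"Jaccard = {jaccard(truth, called):.4f}  (shared bp / union bp)")
print(f"TPR     = {tpr(truth, called):.4f}  (shared bp / truth bp)")
print(f"FDR     = {fdr(truth, called):.4f}  (called bp outside truth / called bp)")

genes = [
    ("chr1", 19_199, 25_000, "geneA"),  # exactly 1 bp overlap with the first call
    ("chr1", 30_000, 40_000, "geneB"),  # no overlap
    ("chr2", 29_000, 31_000, "geneC"),
]
print("genes overlapping calls by >= 1 bp:", genes_overlapping(genes, called))
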