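"""Hallmark combination counting.

If tumorigenesis requires one driver-gene mutation per cancer hallmark, the
number of distinct driving combinations is the product of per-hallmark gene
counts.  Uses the packaged COSMIC hallmark gene counts.
"""

from cdnscan.datasets import load_hallmark_counts
from cdnscan.hallmarks import combination_count

for column in ("breast", "colon"):
    counts = load_hallmark_counts(column)
    result = combination_count(counts)
    widest = max(counts, key=counts.get)
    print(
        f"{column}: product over {len(counts)} hallmarks = {result.product:,} "
        f"(~{result.product:.1e}); largest hallmark {widest!r} with {counts[widest]} genes "
        f"bounds any single gene's prevalence below {result.min_prevalence[widest]:.3f}"
    )
print(
    "\nOver 1e11 combinations can drive a breast tumor, so two patients are"
    "\nunlikely to share a driver set: prevalence of a gene and its potency in"
    "\nan individual tumor need not correlate."
)
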