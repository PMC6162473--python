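"""Build promoter-upstream (PROMPT) windows for a tiny hand-made annotation.

Each gene gets the 1500 bp immediately upstream of its TSS on its own
orientation; positions covered by another gene's transcript span are
subtracted, which can split a window or empty it entirely.
"""

from mgtkit import GeneModel, build_prompt_regions

genes = [
    GeneModel("lonely", "chr1", "+", 5000, 7000),
    GeneModel("crowded", "chr1", "+", 12000, 14000),
    GeneModel("blocker", "chr1", "-", 10800, 11400),   # sits inside crowded's window
    GeneModel("tail_end", "chr1", "-", 20000, 22000),  # window runs to the right
]

for region in build_prompt_regions(genes, window=1500):
    print(f"{region.gene_id:>9}  strand {region.strand}  "
          f"intervals {region.intervals}  effective {region.effective_length} bp")

# 'lonely' keeps its full 1500 bp window; 'crowded' loses the 600 bp under
# 'blocker' and is left with two flanking pieces; a minus-strand gene's
# window sits to the right of its span end (its TSS in genome coordinates).
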