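"""Fragment a molecule, merge the fragment bases, delete duplicates.

The two-fragment scheme for N-methylacetamide splits the molecule into
two overlapping 9-atom pieces (each keeping one methyl's hydrogen triple
as a permuting block).  Merging their order-3 bases drops the pair
variables between the two methyl ends and removes the polynomials the
overlap region contributes twice.
"""

import pipfrag as pf
from pipfrag.fragments import merge_and_deduplicate
from pipfrag.systems import nma_two_fragment

frags = nma_two_fragment()
report = pf.validate_fragmentation(pf.parent_allowed_blocks(frags), frags)
print(f"consistency rule: {report}")

bases = [pf.generate_basis(f, 3, 12) for f in frags]
merged = merge_and_deduplicate(bases)
c = merged.counts_report()
print(f"fragment basis sizes:   {c['fragment_sizes']}")
print(f"retained Morse vars:    {c['retained_variables']} of 66 "
      f"({c['excluded_pairs']} end-to-end pairs dropped)")
print(f"concatenated:           {c['concatenated']} polynomials")
print(f"duplicates removed:     {c['duplicates_removed']}")
print(f"unique merged basis:    {c['unique']}")
# Prints 3028+3028 = 6056 concatenated, 816 duplicates (exactly the
# C(18,3) polynomials of the shared 6-atom backbone), 5240 unique — a
# 13.5% smaller fitting basis with identical predictions.
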