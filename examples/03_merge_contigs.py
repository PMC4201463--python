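"""Merge a diploid individual's overlapping contigs into an IUPAC consensus.

Fragments a source haplotype into overlapping contigs, injects
heterozygous sites into the overlaps (the two contigs carry the two
alleles), and merges back: agreements pass through, disagreements become
the minimal IUPAC code containing both bases.
"""

import numpy as np

from lcnpipe import ContigScheme, fragment_to_contigs, merge_contigs
from lcnpipe.contigs import OrientedContig

rng = np.random.default_rng(4)
source = "".join(rng.choice(list("ACGT"), 1200))

contigs, truth = fragment_to_contigs(source, ContigScheme(400, 150, 0),
                                     heterozygosity=0.02, seed=11)
oriented = [OrientedContig(c.contig_id, "locus1", c.start, c.end, c.sequence)
            for c in contigs]
consensus = merge_contigs(oriented, individual_id="indiv1")

print(f"source length    : {len(source)} bp")
print(f"contigs          : {[(c.start, c.end) for c in contigs]}")
print(f"injected het sites ({len(truth.het_sites)}):")
for pos, (ref, alt) in sorted(truth.het_sites.items()):
    print(f"  position {pos}: {ref}/{alt} -> consensus "
          f"{consensus.sequence[pos]}")
mismatches = sum(1 for i, c in enumerate(source)
                 if i not in truth.het_sites and consensus.sequence[i] != c)
print(f"non-het positions differing from source: {mismatches} (lossless)")
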