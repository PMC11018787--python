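"""Draw the minimum spanning network over major haplotypes.

Major haplotypes (>= min_carriers accessions) become nodes; edges carry
the number of mutations (Hamming distance) separating two haplotypes,
with the closest pairs connected first.
"""

from gchapkit.gchap_core import build_gchaps, major_haps
from gchapkit.hap_network import build_msn
from gchapkit.synthetic_data import FIXTURES, simulate_matrices

per_gene, labels, _pheno, truth = simulate_matrices(FIXTURES["shifted"])
gid, (sites, gm) = next(iter(per_gene.items()))
census = build_gchaps(sites, gm)
majors = major_haps(census, min_carriers=50)
net = build_msn(majors)
print(f"{gid}: {len(net.nodes)} major haplotypes, {len(net.edges)} edges")
for e in net.edges:
    tag = "tree" if e.in_mst else "alt "
    print(f"  {e.hap_a} --{e.mutations}-- {e.hap_b}  [{tag}]")
# On the star genealogy the generator uses, every edge should touch the
# predominant haplotype (Hap1): derived haplotypes are each a few
# private mutations away from the ancestral one.
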