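"""Receptor-motif scanning and reading-frame integrity.

Scans cytoplasmic-tail sequences for canonical ITIMs (VxYxxL) and their
tyrosine-to-phenylalanine disrupted form, classifies transmembrane adaptor
pairing by charged residue, and checks which genes of a mutated haplotype
retain open reading frames.
"""

from paralocus import (
    build_haplotype,
    classify_tm_adaptor,
    generate_block,
    orf_integrity,
    scan_itims,
)

# inhibitory-style tail with two ITIMs, the membrane-proximal one disrupted
tail = "GSLMHRPQVTFAQLDHSSLAGNVIYTELPNAKP"
for hit in scan_itims(tail, "example_tail"):
    kind = "intact" if hit.motif_class == "ITIM_canonical" else "Y->F disrupted"
    print(f"ITIM at residue {hit.start}: {hit.matched} ({kind})")

# adaptor logic: membrane-proximal arginine vs transmembrane lysine
print("flank R, no TM K ->", classify_tm_adaptor("LLVVAGILLV", "QHRSS"))
print("TM K, no flank R ->", classify_tm_adaptor("LLVKAGILLV", "QHSSS"))

# reading frames: generated genes are intact; block divergence knocks some out
block = generate_block(20_000, 4, ["group1", "group2", "group3", "group4"], seed=1)
h1 = build_haplotype(block, 2, 0.02, seed=2)
print("\ngene          status       defects")
for g in h1.genes:
    v = orf_integrity(g, h1.sequence)
    defects = ", ".join(f"{kind}@{pos}" for kind, pos in v.defects) or "-"
    print(f"{g.gene_id:<12}  {v.status:<11}  {defects}")
# pseudogenes here arose from the random point mutations applied during block
# duplication, the same mechanism that inactivates real paralog copies.
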