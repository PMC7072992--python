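"""Summarize the tilapia RP gene catalog and its genomic distribution.

Loads the packaged 92-gene catalog, prints the headline statistics
(subunit split, mean gene size and exon count, extremes), the linkage-group
distribution and the paralog families produced by the gene-name grammar.
"""

from riboprot import lg_distribution, load_tilapia_catalog, paralog_families, summarize_catalog

cat = load_tilapia_catalog()
s = summarize_catalog(cat)

print(f"{s.n_genes} RP genes: {s.n_large} large-subunit, {s.n_small} small-subunit")
print(f"mean gene length {s.mean_gene_length_kb} kb, mean exon count {s.mean_exon_count}")
print(f"largest gene {s.max_length_gene} ({s.max_length_kb} kb), "
      f"smallest {s.min_length_gene} ({s.min_length_kb} kb)")
print(f"exon counts range {s.min_exon_count} ({', '.join(s.min_exon_genes)}) "
      f"to {s.max_exon_count} ({', '.join(s.max_exon_genes)})")

dist = lg_distribution(cat)
print(f"\n{len(dist)} linkage groups all carry at least one RP gene; "
      f"LG19 carries only {dist['LG19'][0]}, "
      f"LG7 and LG22 carry {len(dist['LG7'])} and {len(dist['LG22'])}")

fams = [f for f in paralog_families(cat) if f.size > 1]
print(f"\n{len(fams)} multi-member paralog families "
      "(duplicates retained from whole-genome duplications):")
for f in sorted(fams, key=lambda f: (-f.size, f.base_name)):
    print(f"  {f.base_name}: {f.size} copies ({', '.join(f.members)})")
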