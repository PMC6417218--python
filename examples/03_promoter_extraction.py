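"""Operon-aware promoter extraction on a synthetic genome.

Generates an annotated two-contig genome with operons, resolves a gene deep
inside an operon to the operon lead, and extracts the lead's upstream
intergenic region with its sequence. Every member of one operon shares the
same promoter region.
"""

from promquant import synthetic
from promquant.promoters import extract_promoter, fetch_sequence, \
    resolve_anchor

ann, operons, genome = synthetic.gen_annotation(
    60, n_contigs=2, operon_fraction=0.5, min_gap=80, seed=7)
lengths = {c: len(s) for c, s in genome.items()}
print(f"{len(ann)} genes on {len(lengths)} contigs, {len(operons)} operons")

# pick the last member of the first operon and walk back to the lead
oid = operons.table["operon_id"].iloc[0]
members = operons.members(oid)
query = members[-1]
anchor = resolve_anchor(query, operons)
print(f"operon {oid}: members {members}; query {query} -> anchor {anchor}")

region = fetch_sequence(extract_promoter(anchor, ann, lengths), genome)
print(f"promoter of {anchor}: {region.contig}:{region.start}-{region.end}"
      f"({region.strand}), {region.length} bp"
      + (" [truncated at contig edge]" if region.truncated else ""))
print(f"sequence (first 60 bp): {region.sequence[:60]}")

same = {fetch_sequence(extract_promoter(resolve_anchor(m, operons), ann,
                                        lengths), genome)
        for m in members}
print(f"distinct promoter regions across the {len(members)} members:",
      len(same), "(shared operon promoter)")
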