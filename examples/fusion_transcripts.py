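"""Analyse a chimeric read against a rearranged toy genome.

The toy generator plants a translocation whose breakpoints sit inside
introns, so the novel fusion junction is GT-AG spliceable.  A chimeric
read with a deliberately displaced raw fusion point is refined back to
the exact junction and linked to the WGS breakpoint truth.
"""

from isoforge import link_breakpoints, make_toy_reference, refine_fusion_point
from isoforge.fusion import build_fusion_transcript, call_double_hop, classify_fragments
from isoforge.classify import ReferenceIndex
from isoforge.genome_model import ExonChain
from isoforge.io_formats import AlignedSegment, ReadRecord

toy = make_toy_reference(n_genes=6, isoforms_per_gene=3, seed=11, rearrange=True)
sv = toy.breakpoints[0]
_, gene_a, gene_b = sv.sv_id.split("_")
ann = toy.annotation
chain_a = ann.transcripts[ann.genes[gene_a][0]]
chain_b = ann.transcripts[ann.genes[gene_b][0]]

# raw alignment places the fusion point 3 bp off the true splice site
off = 3
exon_a = chain_a.exons[0]
exon_b = chain_b.exons[-1]
seg5 = AlignedSegment(0, exon_a[1] - exon_a[0] + off,
                      ExonChain(chain_a.chrom, "+", [(exon_a[0], exon_a[1] + off)]), "+")
seg3 = AlignedSegment(seg5.read_end, seg5.read_end + (exon_b[1] - exon_b[0]) - off,
                      ExonChain(chain_b.chrom, "+", [(exon_b[0] + off, exon_b[1])]), "+")
read = ReadRecord("chimera1", "s1", seg5.chain, is_chimeric=True, segments=[seg5, seg3])

ft = build_fusion_transcript(read)
pt = ft.fusion_points[0]
print(f"raw fusion point     : {pt.five_pos} -> {pt.three_pos}")
refine_fusion_point(ft, toy.genome)
print(f"refined fusion point : {pt.five_pos} -> {pt.three_pos} "
      f"(spliced={pt.is_spliced}, motif={pt.motif})")
print(f"planted junction     : {exon_a[1]} -> {exon_b[0]}")

link_breakpoints(ft, toy.breakpoints)
print(f"linked SV            : {pt.link.sv_id} (summed distance {pt.link_distance:.0f} bp,"
      " spliced window 100,000 bp)")

idx = ReferenceIndex.from_annotation(ann)
seg_info, point_info = classify_fragments(ft, idx)
print(f"fragment contexts    : {[s['region'] for s in seg_info]}")
print(f"fusion-point context : {point_info[0]}")
call_double_hop([ft])
print(f"double-hop status    : {ft.double_hop_status} (two segments only)")
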