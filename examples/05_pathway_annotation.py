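"""Count pathway membership of the published candidate target genes.

Joins the packaged 215-gene candidate set against a small illustrative
gene -> pathway map and keeps pathways related to more than two genes, the
reporting rule used for pathway tables in this workflow.
"""

from lactmir import annotate_pathways, filter_min_genes, load_published_targets
from lactmir.io_tables import PathwayMap

fixture = load_published_targets()
all_genes = {g for genes in fixture.gene_lists().values() for g in genes}

# illustrative static map (a real analysis would load a full KEGG export)
pmap = PathwayMap(pathways={
    "pw:adhesion": ("Focal adhesion", {"PTK2", "CDC42", "COL1A2", "COL3A1", "COL4A2",
                                       "COL11A1", "PAK6", "PPP1CA", "PDGFB", "SRC"}),
    "pw:ecm": ("ECM-receptor interaction", {"COL1A2", "COL3A1", "COL4A2", "COL11A1",
                                            "SV2A", "SDC1"}),
    "pw:cycle": ("Cell cycle", {"E2F5", "CDKN2D", "STAG2", "YWHAH", "YWHAZ"}),
    "pw:tiny": ("Two-gene pathway", {"EIF4E", "PPARGC1A"}),
})

report = filter_min_genes(annotate_pathways(all_genes, pmap), min_genes=3)
print(f"{len(all_genes)} candidate genes against {len(pmap.pathways)} pathways; "
      f"{len(report.rows)} pathways with more than two genes:\n")
for pid, name, genes, count in report.rows:
    print(f"  {name:28s} {count:2d} genes: {', '.join(genes)}")
# The two-gene pathway is filtered out; counts are the sizes of the
# intersections between the candidate set and each pathway's member list.
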