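"""GO enrichment of a hit set and assembly of a small signal web.

Builds a toy annotation background, enriches a foreground gene set with the
hypergeometric upper tail, then assembles a reasoned gene network with a
PPI overlay and summarises it.
"""

import pandas as pd

from vtlkit.enrichment import AnnotationMap, enrich, results_to_frame
from vtlkit.network import CATEGORIES, GeneNode, build_web, web_summary

# --- enrichment ------------------------------------------------------------
genes = {f"g{i}": {"GO:ROOT"} for i in range(60)}
for i in range(12):
    genes[f"g{i}"].add("GO:0006325")   # chromatin organisation, say
for i in range(30):
    genes[f"g{i}"].add("GO:0045892")
annotations = AnnotationMap(genes, {"GO:ROOT": "P", "GO:0006325": "P", "GO:0045892": "P"})

foreground = [f"g{i}" for i in range(10)]   # 10 screen hits, skewed to term 1
results = enrich(foreground, annotations)
print(results_to_frame(results).round(4).to_string(index=False))
# e_ratio = (m/M)/(n/N); p is the one-sided hypergeometric tail, reported
# only for over-represented terms (e_ratio >= 1), sorted by p.

# --- signal web ------------------------------------------------------------
nodes = [
    GeneNode("mre11", CATEGORIES[0], frozenset({"sleep", "social"})),
    GeneNode("Dop1R1", CATEGORIES[2], frozenset({"sleep"})),
    GeneNode("Hdc", CATEGORIES[2], frozenset({"sleep"})),
    GeneNode("NELF-B", CATEGORIES[1], frozenset({"sleep", "locomotor"})),
]
reasoning = pd.DataFrame(
    {
        "gene_a": ["mre11", "mre11", "NELF-B"],
        "gene_b": ["Dop1R1", "Hdc", "Dop1R1"],
        "positive": [True, True, False],
        "direction": ["a_to_b", "a_to_b", ""],
        "sign": ["positive", "positive", ""],
        "pmid": ["36690739", "", ""],
    }
)
web = build_web(nodes, reasoning, ppi_records=[("Dop1R1", "Hdc")])
summary = web_summary(web)
print("\nedge kinds          :", summary["edge_kind_counts"])
print("regulation signs    :", summary["regulation_sign_counts"])
print("mean degree/category:",
      {k.split(" ")[0]: round(v, 2) for k, v in summary["mean_degree_by_category"].items()})
# Positive reasoned rows with a curated direction become directed
# regulations; PPIs overlay as undirected edges and do not add to the
# reasoned degree.
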