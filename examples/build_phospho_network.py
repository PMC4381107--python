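"""Merge extracted tuples into a phosphoform network and export XGMML.

Each distinct site-set of a substrate is a separate phosphoform node
(site-less tuples get the "phosphoX" placeholder form), so a protein
phosphorylated by two kinases with different (or unstated) sites shows
two phosphoforms sharing one base node — mirroring how curated
phosphoform interactions are modeled.
"""

from efip import EFIPTuple, build_network, edge_list_csv, export_xgmml

tuples = [
    EFIPTuple(substrate="CDC25B", kinase="p38 MAPK",
              sites=("Ser-309", "Ser-361"), interactant="14-3-3",
              ppi_type="binding", relation_type="causal",
              polarity="increase", doc_id="D1"),
    EFIPTuple(substrate="CDC25B", kinase="MAPKAPK2", sites=(),
              interactant="14-3-3", ppi_type="binding",
              relation_type="causal", polarity="increase", doc_id="D2"),
    EFIPTuple(substrate="CDC25B", kinase="CDK5", sites=(),
              interactant="14-3-3", ppi_type="binding",
              relation_type="causal", polarity="decrease", doc_id="D3"),
]

net = build_network(tuples)
print(f"{len(net.nodes)} nodes, {len(net.edges)} edges")
for node in net.sorted_nodes():
    print(f"  node {node.label:<22} type={node.node_type}")
print(edge_list_csv(net))

xgmml = export_xgmml(net)
print(f"XGMML: {len(xgmml)} characters; first line: "
      f"{xgmml.splitlines()[1][:60]}...")

# One CDC25B base node carries two phosphoforms (the Ser-309/Ser-361
# form and the site-unspecified phosphoX form); three kinases point at
# the forms they produce, and association edges to 14-3-3 carry "+" or
# "-" polarity — the CDK5 edge is the inhibitory one.
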