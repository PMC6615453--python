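"""Link local gene/variant nodes to a remote knowledge graph and run the
two federated analysis patterns against the bundled offline fixture.

Local URIs are mapped to remote items with owl:sameAs; one request then
joins local data with remote drug-gene interactions or variant response
evidence.  Swap the fixture endpoint for SparqlHttpEndpoint(url) to hit a
live SPARQL service.
"""

from rdflib import URIRef
from rdflib.namespace import RDF

import xenograph as xg

WD = "http://www.wikidata.org/entity/"
vocab = xg.Vocabulary()
g = xg.TripleStore()

genes = {}
for sym, qid in [("BRAF", "QG_BRAF"), ("EGFR", "QG_EGFR"),
                 ("ERBB2", "QG_ERBB2"), ("KRAS", "QG_KRAS")]:
    genes[sym] = g.local(f"gene/{sym}")
    g.add((genes[sym], RDF.type, vocab.Gene))
    xg.add_mapping(g, genes[sym], URIRef(WD + qid), "ensembl_id")

endpoint = xg.bundled_fixture_endpoint()
interactions = xg.fetch_drug_gene_interactions(g, genes.values(), endpoint)
print("drug-gene interactions (compounds hitting panel gene products):")
for row in interactions:
    print(f"  {str(row.gene).rsplit('/', 1)[-1]:6s} <- {row.compound_label}")

# variant-level evidence, including a contradictory pair
for name, qid in [("BRAF_V600E", "QV_BRAF_V600E"),
                  ("KRAS_G13D", "QV_KRAS_G13D")]:
    alt = g.local(f"alt/{name}")
    g.add((alt, RDF.type, vocab.Sequence_Alteration))
    xg.add_mapping(g, alt, URIRef(WD + qid), "cosmic_id")

evidence = xg.fetch_variant_evidence(
    g, [g.local("alt/BRAF_V600E"), g.local("alt/KRAS_G13D")], endpoint)
print("\nvariant response evidence:")
for ev in evidence:
    flag = "  [contradictory]" if ev.contradictory else ""
    print(f"  {str(ev.variant).rsplit('/', 1)[-1]:11s} {ev.predicted_response:8s} "
          f"{ev.regimen_label}{flag}")
# BRAF V600E carries a positive prediction for the Dabrafenib/Trametinib
# combination (with its literature reference); KRAS G13D illustrates how
# debated knowledge is surfaced: both signs returned, both flagged.
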