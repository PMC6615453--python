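"""Annotate a bioentity and classify a treatment response.

Observations never sit on the specimen itself: a dedicated annotation node
links the bioentity to the knowledge item over a two-predicate path and
carries meta-annotations (user, session).  Treatment outcomes are classified
from percent tumor-volume variation: <= -50 positive, >= +35 negative,
neutral in between.
"""

from rdflib.namespace import RDF

import xenograph as xg

vocab = xg.Vocabulary()
g = xg.TripleStore()
mouse = g.local("b42")
gene = g.local("gene/KRAS")
treatment = g.local("treatment/cetuximab")
g.add((mouse, RDF.type, vocab.Bioentity))
g.add((gene, RDF.type, vocab.Gene))
g.add((treatment, RDF.type, vocab.Treatment))

record = xg.annotate(g, mouse, gene, {"user": "researcher1", "session": "s114"})
print(f"annotation node: {record.annotation_uri}")
print(f"triples on the annotation node: "
      f"{len(g.match((record.annotation_uri, None, None)))}")

for delta in (-80.0, -50.0, -12.3, 34.999, 35.0, 120.0):
    print(f"volume variation {delta:+8.3f}% -> {xg.classify_response(delta)}")

obs = xg.ResponseObservation(mouse, treatment, -62.5)
resp = xg.annotate_response(g, obs, {"user": "researcher1"})
rtype = g.match((resp.reference, vocab.has_response_type, None))[0][2]
print(f"observation -62.5% references {resp.reference}")
print(f"response type: {str(rtype).rsplit('/', 1)[-1]}")
# -62.5% shrinkage is at least the 50% regression bar, so the observation
# points at the positive drug-response instance for cetuximab.
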