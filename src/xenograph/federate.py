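"""Federation of local knowledge with an external knowledge graph.

Local gene and variant nodes are linked to their remote counterparts with
``owl:sameAs`` (one remote per local — the mapping is injective).  Two
federated analysis patterns are supported, each issued as a single request
that injects all mapped URIs VALUES-style:

* drug-gene interactions: compounds that physically interact with the
  protein products of mapped panel genes;
* variant evidence: positive/negative drug-response predictions asserted
  for mapped variants, each with its literature reference; contradictory
  predictions (both signs for the same variant/regimen) are returned and
  flagged, not suppressed.

Endpoints are pluggable behind a small contract: an offline fixture
endpoint backed by rdflib's SPARQL engine (the bundled fixture is a
synthetic emulation of the remote schema) and a live HTTP endpoint client.
Both return identically shaped binding lists; endpoint failures raise,
never surface as silent empties.  The remote vocabulary (interaction and
evidence predicates) is configuration, not code, so remote schema drift is
absorbed without a release.
"""

from __future__ import annotations

import json
import urllib.parse
import urllib.request
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Protocol

from rdflib import Graph as _RdflibGraph
from rdflib import Literal, URIRef
from rdflib.namespace import OWL

from .analytics import CaseFeatureTable
from .errors import EndpointError, MappingConflictError, ReferentialIntegrityError
from .store import TripleStore

WD = "http://www.wikidata.org/entity/"
WDT = "http://www.wikidata.org/prop/direct/"
P = "http://www.wikidata.org/prop/"
PS = "http://www.wikidata.org/prop/statement/"
PROV = "http://www.w3.org/ns/prov#"


@dataclass(frozen=True)
class SameAsMapping:
    local: URIRef
    remote: URIRef
    matched_on: str = "manual"  # ensembl_id | cosmic_id | manual


@dataclass(frozen=True)
class RemoteVocabulary:
    """Predicates of the remote graph; override to track remote schema drift."""
    encodes: str = WDT + "P688"                  # gene -> protein product
    interacts: str = WDT + "P129"                # compound <-> product
    positive_statement: str = P + "P3354"        # positive therapy predictor
    positive_value: str = PS + "P3354"
    negative_statement: str = P + "P3355"        # negative therapy predictor
    negative_value: str = PS + "P3355"
    derived_from: str = PROV + "wasDerivedFrom"
    label: str = "http://www.w3.org/2000/01/rdf-schema#label"


@dataclass(frozen=True)
class DrugGeneInteraction:
    compound: URIRef
    compound_label: str
    gene: URIRef                 # local gene URI
    interaction_kind: str = "physically interacts with"


@dataclass(frozen=True)
class VariantEvidence:
    variant: URIRef              # local variant URI
    regimen: URIRef
    regimen_label: str
    predicted_response: str      # positive | negative
    reference: URIRef
    contradictory: bool = False


class RemoteEndpoint(Protocol):
    identity: str

    def execute(self, query: str) -> list[dict[str, URIRef | Literal]]: ...


class FixtureEndpoint:
    """Offline endpoint over a local rdflib graph; deterministic."""

    def __init__(self, source, identity: str = "fixture"):
        self.identity = identity
        self.graph = _RdflibGraph()
        try:
            if isinstance(source, _RdflibGraph):
                self.graph = source
            elif isinstance(source, str) and source.lstrip().startswith("@prefix"):
                self.graph.parse(data=source, format="turtle")
            else:
                self.graph.parse(source, format="turtle")
        except Exception as exc:
            raise EndpointError(f"cannot load fixture {identity!r}: {exc}") from exc

    def execute(self, query: str) -> list[dict[str, URIRef | Literal]]:
        try:
            result = self.graph.query(query)
        except Exception as exc:
            raise EndpointError(f"fixture query failed: {exc}") from exc
        rows = []
        for binding in result:
            rows.append({str(var): term for var, term in
                         zip(result.vars, binding) if term is not None})
        return sorted(rows, key=lambda r: sorted((k, str(v)) for k, v in r.items()))


def bundled_fixture_endpoint() -> FixtureEndpoint:
    """The synthetic remote-knowledge fixture shipped with the package."""
    text = (resources.files("xenograph") / "data" / "synthetic_remote.ttl") \
        .read_text(encoding="utf-8")
    g = _RdflibGraph()
    g.parse(data=text, format="turtle")
    return FixtureEndpoint(g, identity="fixture://synthetic_remote.ttl")


class SparqlHttpEndpoint:
    """Minimal SPARQL-over-HTTP client (SELECT, JSON results).

    Only used when an explicit endpoint URL is configured; nothing in the
    package contacts the network by default.
    """

    def __init__(self, url: str, timeout: float = 30.0):
        self.identity = url
        self.timeout = timeout

    def execute(self, query: str) -> list[dict[str, URIRef | Literal]]:
        data = urllib.parse.urlencode({"query": query, "format": "json"}).encode()
        req = urllib.request.Request(
            self.identity, data=data,
            headers={"Accept": "application/sparql-results+json",
                     "User-Agent": "xenograph/0.1"})
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                payload = json.load(resp)
        except Exception as exc:
            raise EndpointError(f"endpoint {self.identity} failed: {exc}") from exc
        rows = []
        for b in payload.get("results", {}).get("bindings", []):
            row: dict[str, URIRef | Literal] = {}
            for var, cell in b.items():
                row[var] = (URIRef(cell["value"]) if cell.get("type") == "uri"
                            else Literal(cell["value"]))
            rows.append(row)
        return rows


# ------------------------------------------------------------------ mappings

def add_mapping(g: TripleStore, local: URIRef, remote: URIRef,
                matched_on: str = "manual") -> SameAsMapping:
    """Assert (local, owl:sameAs, remote); idempotent, injective per local."""
    if not (g.match((local, None, None)) or g.match((None, None, local))):
        raise ReferentialIntegrityError(f"{local} does not exist in the graph")
    existing = [o for _, _, o in g.match((local, OWL.sameAs, None))]
    if existing and existing != [remote]:
        raise MappingConflictError(
            f"{local} already maps to {existing[0]}, refusing second remote {remote}")
    g.add((local, OWL.sameAs, remote))
    return SameAsMapping(local, remote, matched_on)


def get_mappings(g: TripleStore) -> dict[URIRef, URIRef]:
    return {s: o for s, _, o in g.match((None, OWL.sameAs, None))}


def _mapped(g: TripleStore, items: Iterable[URIRef],
            what: str) -> dict[URIRef, URIRef]:
    """remote -> local for the mapped subset; warn about unmapped items."""
    mappings = get_mappings(g)
    out: dict[URIRef, URIRef] = {}
    for item in sorted(set(items), key=str):
        if item in mappings:
            out[mappings[item]] = item
        else:
            warnings.warn(f"{what} {item} has no sameAs mapping; excluded",
                          stacklevel=3)
    return out


# ------------------------------------------------------------ query patterns

def fetch_drug_gene_interactions(
        g: TripleStore, panel: Iterable[URIRef], endpoint: RemoteEndpoint,
        remote_vocab: RemoteVocabulary = RemoteVocabulary(),
) -> list[DrugGeneInteraction]:
    """Compounds interacting with the protein products of mapped panel genes.

    One federated-style request; results are re-keyed to local gene URIs.
    Unmapped panel genes produce a warning and are excluded.
    """
    remote_to_local = _mapped(g, panel, "panel gene")
    if not remote_to_local:
        return []
    values = " ".join(f"<{r}>" for r in sorted(remote_to_local, key=str))
    rv = remote_vocab
    query = f"""
    SELECT ?gene ?compound ?compoundLabel WHERE {{
        VALUES ?gene {{ {values} }}
        ?gene <{rv.encodes}> ?product .
        ?compound <{rv.interacts}> ?product .
        ?compound <{rv.label}> ?compoundLabel .
    }}"""
    out = []
    for row in endpoint.execute(query):
        local_gene = remote_to_local[URIRef(str(row["gene"]))]
        out.append(DrugGeneInteraction(
            compound=URIRef(str(row["compound"])),
            compound_label=str(row["compoundLabel"]),
            gene=local_gene))
    return sorted(out, key=lambda i: (str(i.gene), str(i.compound)))


def fetch_variant_evidence(
        g: TripleStore, variants: Iterable[URIRef], endpoint: RemoteEndpoint,
        remote_vocab: RemoteVocabulary = RemoteVocabulary(),
) -> list[VariantEvidence]:
    """Drug-response predictions with literature references for mapped variants.

    Both signs are queried in one request; when the same variant/regimen
    pair carries both a positive and a negative prediction, both rows are
    returned flagged contradictory.
    """
    remote_to_local = _mapped(g, variants, "variant")
    if not remote_to_local:
        return []
    values = " ".join(f"<{r}>" for r in sorted(remote_to_local, key=str))
    rv = remote_vocab
    query = f"""
    SELECT ?variant ?regimen ?regimenLabel ?sign ?ref WHERE {{
        VALUES ?variant {{ {values} }}
        {{
            ?variant <{rv.positive_statement}> ?st .
            ?st <{rv.positive_value}> ?regimen .
            BIND("positive" AS ?sign)
        }} UNION {{
            ?variant <{rv.negative_statement}> ?st .
            ?st <{rv.negative_value}> ?regimen .
            BIND("negative" AS ?sign)
        }}
        ?st <{rv.derived_from}> ?ref .
        ?regimen <{rv.label}> ?regimenLabel .
    }}"""
    rows = endpoint.execute(query)
    signs: dict[tuple[URIRef, URIRef], set[str]] = {}
    parsed = []
    for row in rows:
        local_variant = remote_to_local[URIRef(str(row["variant"]))]
        regimen = URIRef(str(row["regimen"]))
        sign = str(row["sign"])
        parsed.append((local_variant, regimen, str(row["regimenLabel"]),
                       sign, URIRef(str(row["ref"]))))
        signs.setdefault((local_variant, regimen), set()).add(sign)
    out = [VariantEvidence(v, r, lbl, sign, ref,
                           contradictory=len(signs[(v, r)]) > 1)
           for v, r, lbl, sign, ref in parsed]
    return sorted(out, key=lambda e: (str(e.variant), str(e.regimen),
                                      e.predicted_response))


def cases_with_variant_evidence(
        table: CaseFeatureTable,
        evidence: Iterable[VariantEvidence]) -> list[tuple[URIRef, VariantEvidence]]:
    """Join evidence rows back to the local cases carrying each variant."""
    out = []
    for ev in evidence:
        for case in sorted(table.rows, key=str):
            if ev.variant in table.rows[case].variant_instances:
                out.append((case, ev))
    return out
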