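"""Ontology vocabulary, schema axioms, and instance validation.

The ontology has three regions: operational data (Case / Tissue / Bioentity
nodes linked by ``generates``), biological knowledge (chromosomes, regions,
genes, transcripts, alterations, treatments, drug responses), and the
annotation bridge connecting the two.  Two small axiom groups carry the
whole analytical design:

* ``generates rdfs:subPropertyOf hasDescendant`` together with
  ``hasDescendant a owl:TransitiveProperty`` — so materialization flattens
  every experimental tree, linking each node to all of its offspring;
* one predicate per alteration category, each ``rdfs:subPropertyOf
  has_variant`` — so gene-to-aberration links can be queried uniformly
  regardless of variant category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
from rdflib import URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .store import DEFAULT_NAMESPACE, TripleStore, _check_namespace

#: Fine-grained operational subtypes; open-ended, extensible via Vocabulary.
DEFAULT_BIOENTITY_SUBTYPES = ("DNA", "RNA", "CellLine", "Mouse", "Aliquot")

#: Alteration-category labels used throughout the analytics.
SEQUENCE_ALTERATION = "sequence_alteration"
COPY_NUMBER_VARIATION = "copy_number_variation"
FEATURE_AMPLIFICATION = "feature_amplification"


class Vocabulary:
    """URIs of the ontology's classes and predicates under one namespace."""

    def __init__(self, namespace: str = DEFAULT_NAMESPACE,
                 bioentity_subtypes: Iterable[str] = DEFAULT_BIOENTITY_SUBTYPES,
                 extra_variant_predicates: dict[str, str] | None = None):
        self.namespace = _check_namespace(namespace)
        n = lambda name: URIRef(namespace + name)  # noqa: E731

        # operational classes
        self.Case = n("Case")
        self.Tissue = n("Tissue")
        self.Bioentity = n("Bioentity")
        self.bioentity_subtypes = tuple(n(s) for s in bioentity_subtypes)

        # knowledge classes
        self.Chromosome = n("Chromosome")
        self.Region = n("Region")
        self.Gene = n("Gene")
        self.Exon = n("Exon")
        self.Transcript = n("Transcript")
        self.Peptide = n("Peptide")
        self.Alteration = n("Alteration")
        self.Sequence_Alteration = n("Sequence_Alteration")
        self.Copy_number_variation = n("Copy_number_variation")
        self.Feature_amplification = n("Feature_amplification")
        self.Treatment = n("Treatment")
        self.Drug_response = n("Drug_response")
        self.Response_type = n("Response_type")

        # annotation bridge
        self.Annotation = n("Annotation")

        # object predicates
        self.generates = n("generates")
        self.hasDescendant = n("hasDescendant")
        self.has_annotation = n("has_annotation")
        self.has_reference = n("has_reference")
        self.has_variant = n("has_variant")
        self.has_sequence_alteration = n("has_sequence_alteration")
        self.has_copy_number_variation = n("has_copy_number_variation")
        self.has_feature_amplification = n("has_feature_amplification")
        self.has_treatment = n("has_treatment")
        self.has_response_type = n("has_response_type")
        self.sameAs = OWL.sameAs

        # per-category variant predicates; config-extensible because the
        # category list is open-ended
        self.variant_predicates: dict[URIRef, URIRef] = {
            self.Sequence_Alteration: self.has_sequence_alteration,
            self.Copy_number_variation: self.has_copy_number_variation,
            self.Feature_amplification: self.has_feature_amplification,
        }
        for cls_name, pred_name in (extra_variant_predicates or {}).items():
            self.variant_predicates[n(cls_name)] = n(pred_name)

        # data predicates
        self.symbol = n("symbol")
        self.ac = n("ac")
        self.barcode = n("barcode")
        self.chrom_start = n("chrom_start")
        self.chrom_end = n("chrom_end")
        self.volume_variation = n("volume_variation")
        self.label = n("label")
        self.user = n("user")
        self.session = n("session")
        self.timestamp = n("timestamp")
        self.note = n("note")

    def classes(self) -> tuple[URIRef, ...]:
        return (self.Case, self.Tissue, self.Bioentity,
                *self.bioentity_subtypes,
                self.Chromosome, self.Region, self.Gene, self.Exon,
                self.Transcript, self.Peptide,
                self.Alteration, self.Sequence_Alteration,
                self.Copy_number_variation, self.Feature_amplification,
                self.Treatment, self.Drug_response, self.Response_type,
                self.Annotation,
                *(c for c in self.variant_predicates
                  if c not in (self.Sequence_Alteration,
                               self.Copy_number_variation,
                               self.Feature_amplification)))

    def object_predicates(self) -> tuple[URIRef, ...]:
        return (self.generates, self.hasDescendant, self.has_annotation,
                self.has_reference, self.has_variant, self.has_treatment,
                self.has_response_type,
                *sorted(set(self.variant_predicates.values())))

    def data_predicates(self) -> tuple[URIRef, ...]:
        return (self.symbol, self.ac, self.barcode, self.chrom_start,
                self.chrom_end, self.volume_variation, self.label,
                self.user, self.session, self.timestamp, self.note)

    def subclass_axioms(self) -> list[tuple[URIRef, URIRef]]:
        pairs = [(self.Sequence_Alteration, self.Alteration),
                 (self.Copy_number_variation, self.Alteration),
                 (self.Feature_amplification, self.Copy_number_variation),
                 (self.Gene, self.Region),
                 (self.Exon, self.Region)]
        pairs += [(sub, self.Bioentity) for sub in self.bioentity_subtypes]
        return pairs

    def subproperty_axioms(self) -> list[tuple[URIRef, URIRef]]:
        pairs = [(self.generates, self.hasDescendant),
                 (self.has_sequence_alteration, self.has_variant),
                 (self.has_copy_number_variation, self.has_variant),
                 (self.has_feature_amplification, self.has_copy_number_variation)]
        for cls, pred in self.variant_predicates.items():
            if (pred, self.has_variant) not in pairs and \
               pred not in (self.has_sequence_alteration,
                            self.has_copy_number_variation,
                            self.has_feature_amplification):
                pairs.append((pred, self.has_variant))
        return pairs

    def operational_classes(self) -> set[URIRef]:
        return {self.Case, self.Tissue, self.Bioentity, *self.bioentity_subtypes}


def build_schema(namespace: str = DEFAULT_NAMESPACE,
                 vocab: Vocabulary | None = None) -> TripleStore:
    """Axiom and declaration triples of the ontology as a TripleStore.

    Deterministic for a fixed namespace: two calls yield identical triple
    sets (and identical serializations).
    """
    vocab = vocab or Vocabulary(namespace)
    g = TripleStore(vocab.namespace)
    for cls in vocab.classes():
        g.add((cls, RDF.type, OWL.Class))
    for pred in vocab.object_predicates():
        g.add((pred, RDF.type, OWL.ObjectProperty))
    for pred in vocab.data_predicates():
        g.add((pred, RDF.type, OWL.DatatypeProperty))
    for sub, sup in vocab.subclass_axioms():
        g.add((sub, RDFS.subClassOf, sup))
    for sub, sup in vocab.subproperty_axioms():
        g.add((sub, RDFS.subPropertyOf, sup))
    g.add((vocab.hasDescendant, RDF.type, OWL.TransitiveProperty))
    return g


@dataclass(frozen=True)
class Violation:
    kind: str
    subject: URIRef | tuple
    detail: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.valid

    def by_kind(self, kind: str) -> list[Violation]:
        return [v for v in self.violations if v.kind == kind]


def _subclass_closure(schema: TripleStore) -> dict[URIRef, set[URIRef]]:
    up: dict[URIRef, set[URIRef]] = {}
    for s, _, o in schema.match((None, RDFS.subClassOf, None)):
        up.setdefault(s, set()).add(o)
    closure: dict[URIRef, set[URIRef]] = {}

    def supers(c: URIRef) -> set[URIRef]:
        if c not in closure:
            closure[c] = {c}
            for d in up.get(c, ()):  # acyclic by schema invariant
                closure[c] |= supers(d)
        return closure[c]

    for c in list(up):
        supers(c)
    return closure


def validate_instances(data: TripleStore, schema: TripleStore,
                       vocab: Vocabulary | None = None) -> ValidationReport:
    """Check an instance graph against the schema.

    Reported violations: instances typed with a class the schema does not
    declare (only classes in the schema's own namespace are judged — foreign
    vocabularies pass through); ``generates`` edges whose endpoints are not
    operational instances; annotation nodes without exactly one
    ``has_reference`` target or without any incoming ``has_annotation``;
    cycles among ``generates`` edges (experimental trees are acyclic).
    Schema triples mixed into the data graph are never flagged.
    """
    vocab = vocab or Vocabulary(schema.namespace)
    report = ValidationReport()
    schema_triples = schema.triple_set()
    declared = {s for s, _, _ in schema.match((None, RDF.type, OWL.Class))}
    closure = _subclass_closure(schema)
    operational = set()
    for c in declared:
        if closure.get(c, {c}) & vocab.operational_classes():
            operational.add(c)
    operational |= vocab.operational_classes()

    # unknown classes
    for s, p, o in data.match((None, RDF.type, None)):
        if (s, p, o) in schema_triples:
            continue
        if isinstance(o, URIRef) and str(o).startswith(schema.namespace) \
                and o not in declared:
            report.violations.append(Violation(
                "unknown_class", s, f"instance typed with undeclared class {o}"))

    def is_operational(node) -> bool:
        return any(isinstance(o, URIRef) and o in operational
                   for _, _, o in data.match((node, RDF.type, None)))

    # generates endpoints + acyclicity
    gen_edges = [(s, o) for s, _, o in data.match((None, vocab.generates, None))
                 if (s, vocab.generates, o) not in schema_triples]
    for s, o in gen_edges:
        for end in (s, o):
            if not is_operational(end):
                report.violations.append(Violation(
                    "generates_endpoint", end,
                    "generates endpoint is not a Case/Tissue/Bioentity instance"))
    dg = nx.DiGraph(gen_edges)
    for cycle in nx.simple_cycles(dg):
        report.violations.append(Violation(
            "generates_cycle", tuple(cycle),
            f"generates cycle of length {len(cycle)}"))

    # annotation shape: exactly one reference, at least one incoming link
    for s, _, _ in data.match((None, RDF.type, vocab.Annotation)):
        refs = data.match((s, vocab.has_reference, None))
        if len(refs) != 1:
            report.violations.append(Violation(
                "annotation_reference", s,
                f"annotation node has {len(refs)} has_reference targets, expected 1"))
        if not data.match((None, vocab.has_annotation, s)):
            report.violations.append(Violation(
                "annotation_orphan", s,
                "annotation node has no incoming has_annotation link"))
    return report
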