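"""Annotation bridge nodes and treatment-response classification.

An observation never sits directly on a specimen: it is tracked by a
dedicated annotation node, giving a two-predicate path

    bioentity --has_annotation--> annotation --has_reference--> knowledge item

so the same specimen can carry many observations and each observation can
carry meta-annotations (user, analytical session, timestamp, free note).

Treatment outcomes are classified from the percent tumor-volume variation
during therapy with the clinical-like thresholds: positive for variations of
at least -50%, negative for variations of at least +35%, neutral strictly in
between.  Both boundaries are inclusive toward the outer classes.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from decimal import Decimal

from rdflib import Literal, URIRef
from rdflib.namespace import RDF, XSD

from .errors import ReferentialIntegrityError, ResponseDomainError
from .store import TripleStore
from .vocab import Vocabulary

POSITIVE = "positive"
NEUTRAL = "neutral"
NEGATIVE = "negative"
RESPONSE_CLASSES = (POSITIVE, NEUTRAL, NEGATIVE)

#: Volume-variation thresholds (percent): shrinkage of at least 50% is a
#: positive response; growth of at least 35% is a negative response.
POSITIVE_MAX = -50.0
NEGATIVE_MIN = 35.0


def classify_response(volume_variation: float) -> str:
    """Response class of a percent tumor-volume variation.

    The three classes partition the real line: positive iff Δ <= -50,
    negative iff Δ >= +35, neutral otherwise.  Δ below -100 (a tumor cannot
    lose more than its whole volume) or non-finite is a domain error.
    """
    v = float(volume_variation)
    if not math.isfinite(v):
        raise ResponseDomainError(f"volume variation must be finite, got {v!r}")
    if v < -100.0:
        raise ResponseDomainError(
            f"volume variation cannot be below -100%, got {v}")
    if v <= POSITIVE_MAX:
        return POSITIVE
    if v >= NEGATIVE_MIN:
        return NEGATIVE
    return NEUTRAL


@dataclass(frozen=True)
class AnnotationRecord:
    """One bridge node: (target, has_annotation, uri), (uri, has_reference, reference)."""
    annotation_uri: URIRef
    target: URIRef
    reference: URIRef
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ResponseObservation:
    bioentity: URIRef
    treatment: URIRef
    volume_variation: float


def _node_exists(g: TripleStore, node: URIRef) -> bool:
    return bool(g.match((node, None, None)) or g.match((None, None, node)))


def _mint_annotation_uri(g: TripleStore, vocab: Vocabulary,
                         target: URIRef, reference: URIRef,
                         meta: dict) -> URIRef:
    """Deterministic content-addressed URI: re-running the same annotation
    script reproduces the same graph.  Repeated identical annotations get a
    numeric disambiguator so they stay distinct nodes."""
    key = "|".join([str(target), str(reference),
                    str(meta.get("timestamp", "")), str(meta.get("session", ""))])
    digest = hashlib.sha1(key.encode("utf-8")).hexdigest()[:16]
    uri = URIRef(f"{vocab.namespace}annotation/{digest}")
    k = 1
    while (uri, RDF.type, vocab.Annotation) in g:
        k += 1
        uri = URIRef(f"{vocab.namespace}annotation/{digest}-{k}")
    return uri


def annotate(g: TripleStore, target: URIRef, reference: URIRef,
             meta: dict | None = None,
             vocab: Vocabulary | None = None) -> AnnotationRecord:
    """Create an annotation node linking ``target`` to ``reference``.

    Adds exactly 3 + len(meta) triples: the type triple, the two path
    triples, and one literal triple per meta entry.  The store is mutated
    in place; existing triples are never touched.

    Raises :class:`ReferentialIntegrityError` if the target is not typed as
    an operational instance (Case/Tissue/Bioentity or subclass) or the
    reference does not exist in the graph.
    """
    vocab = vocab or Vocabulary(g.namespace)
    meta = dict(meta or {})
    target_types = {o for _, _, o in g.match((target, RDF.type, None))}
    if not target_types & vocab.operational_classes():
        raise ReferentialIntegrityError(
            f"annotation target {target} is not a Case/Tissue/Bioentity instance")
    if not _node_exists(g, reference):
        raise ReferentialIntegrityError(
            f"annotation reference {reference} does not exist in the graph")
    uri = _mint_annotation_uri(g, vocab, target, reference, meta)
    g.add((uri, RDF.type, vocab.Annotation))
    g.add((target, vocab.has_annotation, uri))
    g.add((uri, vocab.has_reference, reference))
    known = {"user": vocab.user, "session": vocab.session,
             "timestamp": vocab.timestamp, "note": vocab.note}
    for key, value in meta.items():
        pred = known.get(key, URIRef(vocab.namespace + key))
        g.add((uri, pred, Literal(str(value))))
    return AnnotationRecord(uri, target, reference, meta)


def response_instance(g: TripleStore, treatment: URIRef, label: str,
                      vocab: Vocabulary | None = None) -> URIRef:
    """Find or create the Drug_response instance for (treatment, class).

    The instance is linked to its treatment and to the response-type
    individual for its class; reused across observations with the same
    outcome so cohort queries can group on it.
    """
    vocab = vocab or Vocabulary(g.namespace)
    if label not in RESPONSE_CLASSES:
        raise ValueError(f"unknown response class {label!r}")
    rtype = URIRef(f"{vocab.namespace}response/{label}")
    g.add((rtype, RDF.type, vocab.Response_type))
    tname = str(treatment).rsplit("/", 1)[-1]
    dr = URIRef(f"{vocab.namespace}drug_response/{tname}-{label}")
    g.add((dr, RDF.type, vocab.Drug_response))
    g.add((dr, vocab.has_treatment, treatment))
    g.add((dr, vocab.has_response_type, rtype))
    return dr


def annotate_response(g: TripleStore, obs: ResponseObservation,
                      meta: dict | None = None,
                      vocab: Vocabulary | None = None) -> AnnotationRecord:
    """Classify an observation and annotate the bioentity with it.

    The volume variation is stored as a literal on the annotation node (not
    on the bioentity), so longitudinal repeats of the same treatment remain
    distinct observations.
    """
    vocab = vocab or Vocabulary(g.namespace)
    label = classify_response(obs.volume_variation)
    if (obs.treatment, RDF.type, vocab.Treatment) not in g:
        raise ReferentialIntegrityError(
            f"treatment {obs.treatment} does not exist in the graph")
    dr = response_instance(g, obs.treatment, label, vocab)
    record = annotate(g, obs.bioentity, dr, meta, vocab)
    g.add((record.annotation_uri, vocab.volume_variation,
           Literal(Decimal(str(float(obs.volume_variation))), datatype=XSD.decimal)))
    return record
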