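"""Synthetic experimental-tree cohorts with planted, recoverable effects.

Emulates what a translational pharmacogenomics biobank looks like to the
analytics: per patient case, a ``generates``-tree of typed bioentities of
irregular depth and branching; gene-alteration annotations (point-mutation
style sequence alterations and feature amplifications) on a four-gene panel
(BRAF, EGFR, ERBB2, KRAS); and one treatment-response observation per case
whose class depends on the case's variant status.

The planted response model is the study condition the analytics must
recover: a case with at least one panel variant is a non-responder
(negative class) with probability 0.70, a variant-free case with
probability 0.30; non-negative outcomes split evenly between positive and
neutral.  Volume variations are drawn uniformly inside each class band
(negative: [+35, +100]; positive: [-100, -50]; neutral: (-50, +35)), so the
classifier reproduces the planted class exactly.

Default alteration probabilities follow the qualitative structure of real
anti-EGFR cohorts: KRAS is the most frequently mutated panel gene, and
amplifications occur only in EGFR and ERBB2, EGFR most often.

Same config + seed => byte-identical Turtle output.
"""

from __future__ import annotations

import dataclasses
import random
from dataclasses import dataclass, field
from typing import Mapping

from rdflib import Literal, URIRef
from rdflib.namespace import RDF

from .annotate import ResponseObservation, annotate, annotate_response
from .errors import ConfigurationError
from .store import DEFAULT_NAMESPACE, TripleStore
from .vocab import (FEATURE_AMPLIFICATION, SEQUENCE_ALTERATION, Vocabulary)

#: Real Ensembl gene accessions for the default panel.
ENSEMBL_AC = {
    "BRAF": "ENSG00000157764",
    "EGFR": "ENSG00000146648",
    "ERBB2": "ENSG00000141736",
    "KRAS": "ENSG00000133703",
}

#: Small per-gene catalogs of recurrent point mutations; sequence
#: alterations get distinct instance URIs so non-responder breakdowns can
#: go down to the variant-instance level.
MUTATION_CATALOG = {
    "KRAS": ("G12D", "G12V", "G13D", "A146T"),
    "BRAF": ("V600E", "D594G"),
    "EGFR": ("S492R", "G465R"),
    "ERBB2": ("V842I", "L755S"),
}


@dataclass(frozen=True)
class ResponseModel:
    """Planted variant -> response effect sizes."""
    p_negative_given_variant: float = 0.70
    p_negative_given_no_variant: float = 0.30
    positive_share_of_nonnegative: float = 0.50
    p_observed: float = 1.0  # fraction of cases with a response observation


def _default_p_alteration() -> dict[str, dict[str, float]]:
    return {
        "BRAF": {SEQUENCE_ALTERATION: 0.10, FEATURE_AMPLIFICATION: 0.0},
        "EGFR": {SEQUENCE_ALTERATION: 0.05, FEATURE_AMPLIFICATION: 0.10},
        "ERBB2": {SEQUENCE_ALTERATION: 0.05, FEATURE_AMPLIFICATION: 0.07},
        "KRAS": {SEQUENCE_ALTERATION: 0.30, FEATURE_AMPLIFICATION: 0.0},
    }


def _default_branching() -> dict[int, float]:
    # child-count distribution per bioentity node (bounded support)
    return {0: 0.35, 1: 0.40, 2: 0.25}


@dataclass
class CohortConfig:
    n_cases: int = 400
    branching: Mapping[int, float] = field(default_factory=_default_branching)
    max_depth: int = 4
    panel: tuple[str, ...] = ("BRAF", "EGFR", "ERBB2", "KRAS")
    p_alteration: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_p_alteration)
    response: ResponseModel = field(default_factory=ResponseModel)
    treatments: tuple[str, ...] = ("cetuximab",)
    annotation_depth_policy: str = "random_node"
    namespace: str = DEFAULT_NAMESPACE
    p_variant_observed: float = 1.0  # fraction of cases with variant notes
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ConfigurationError("n_cases must be >= 0")
        if self.max_depth < 1:
            raise ConfigurationError("max_depth must be >= 1")
        if not self.branching or min(self.branching) < 0:
            raise ConfigurationError("branching support must be >= 0")
        if abs(sum(self.branching.values()) - 1.0) > 1e-9:
            raise ConfigurationError("branching probabilities must sum to 1")
        if self.annotation_depth_policy not in ("root", "random_node", "leaf"):
            raise ConfigurationError(
                f"unknown annotation_depth_policy {self.annotation_depth_policy!r}")
        probs = [self.response.p_negative_given_variant,
                 self.response.p_negative_given_no_variant,
                 self.response.positive_share_of_nonnegative,
                 self.response.p_observed, self.p_variant_observed]
        probs += [p for gene in self.p_alteration.values() for p in gene.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")


@dataclass
class CaseTruth:
    """Audit record for one generated case: exactly what was planted."""
    case: URIRef
    nodes: list[URIRef]
    altered: set[tuple[str, str]]            # (gene symbol, alteration type)
    variant_instances: set[str]              # e.g. "KRAS G12D", "EGFR amplification"
    volume_variation: float | None
    response_class: str | None
    treatment: str | None
    placements: dict[URIRef, URIRef]         # annotation node -> carrying node


@dataclass
class GroundTruth:
    cases: dict[URIRef, CaseTruth] = field(default_factory=dict)

    @property
    def n_variant_annotated(self) -> int:
        return sum(1 for c in self.cases.values() if c.altered)

    @property
    def n_response_annotated(self) -> int:
        return sum(1 for c in self.cases.values() if c.response_class is not None)

    @property
    def n_both(self) -> int:
        return sum(1 for c in self.cases.values()
                   if c.altered and c.response_class is not None)


def _draw(rng: random.Random, dist: Mapping[int, float]) -> int:
    u = rng.random()
    acc = 0.0
    for k in sorted(dist):
        acc += dist[k]
        if u < acc:
            return k
    return max(dist)


def _draw_variation(rng: random.Random, label: str) -> float:
    if label == "negative":
        return rng.uniform(35.0, 100.0)
    if label == "positive":
        return rng.uniform(-100.0, -50.0)
    while True:
        v = rng.uniform(-50.0, 35.0)
        if -50.0 < v < 35.0:
            return v


def _emit_knowledge(g: TripleStore, vocab: Vocabulary,
                    config: CohortConfig) -> dict[str, URIRef]:
    genes: dict[str, URIRef] = {}
    for sym in config.panel:
        uri = g.local(f"gene/{sym}")
        genes[sym] = uri
        g.add((uri, RDF.type, vocab.Gene))
        g.add((uri, vocab.symbol, Literal(sym)))
        if sym in ENSEMBL_AC:
            g.add((uri, vocab.ac, Literal(ENSEMBL_AC[sym])))
    for name in config.treatments:
        t = g.local(f"treatment/{name}")
        g.add((t, RDF.type, vocab.Treatment))
        g.add((t, vocab.label, Literal(name)))
    return genes


def _alteration_instance(g: TripleStore, vocab: Vocabulary, gene: URIRef,
                         sym: str, atype: str,
                         rng: random.Random) -> tuple[URIRef, str]:
    """Create (or reuse) an alteration instance; sequence alterations are
    distinct per mutation, amplifications collapse to one instance per gene."""
    if atype == SEQUENCE_ALTERATION:
        mut = rng.choice(MUTATION_CATALOG.get(sym, ("X1", "X2")))
        uri = g.local(f"alt/{sym}_{mut}")
        label = f"{sym} {mut}"
        cls = vocab.Sequence_Alteration
        pred = vocab.has_sequence_alteration
    else:
        uri = g.local(f"alt/{sym}_amp")
        label = f"{sym} amplification"
        cls = vocab.Feature_amplification
        pred = vocab.has_feature_amplification
    g.add((uri, RDF.type, cls))
    g.add((uri, vocab.label, Literal(label)))
    g.add((gene, pred, uri))
    return uri, label


def generate_cohort(config: CohortConfig) -> tuple[TripleStore, GroundTruth]:
    """Generate a cohort graph plus the matching ground truth.

    The emitted graph passes schema validation with zero violations; the
    ground truth is an auditable 1:1 record of every planted choice.
    """
    config.validate()
    rng = random.Random(config.seed)
    vocab = Vocabulary(config.namespace)
    g = TripleStore(config.namespace)
    truth = GroundTruth()
    genes = _emit_knowledge(g, vocab, config)
    stamp = "2019-01-01T00:00:00"
    meta = {"user": "simulator", "session": f"seed-{config.seed}",
            "timestamp": stamp}

    for i in range(config.n_cases):
        case = g.local(f"case/{i:05d}")
        g.add((case, RDF.type, vocab.Case))
        nodes = [case]
        # one or two tissues per case
        n_tissues = 1 + int(rng.random() < 0.3)
        frontier: list[URIRef] = []
        for ti in range(n_tissues):
            tissue = g.local(f"case/{i:05d}/t{ti}")
            g.add((tissue, RDF.type, vocab.Tissue))
            g.add((case, vocab.generates, tissue))
            nodes.append(tissue)
            frontier.append(tissue)
        # bioentity tree below the tissues
        bcount = 0
        depth = 1
        while frontier and depth < config.max_depth:
            nxt: list[URIRef] = []
            for parent in frontier:
                k = _draw(rng, config.branching)
                if depth == 1 and parent == nodes[1] and k == 0:
                    k = 1  # at least one bioentity per tree
                for _ in range(k):
                    b = g.local(f"case/{i:05d}/b{bcount}")
                    bcount += 1
                    g.add((b, RDF.type, vocab.Bioentity))
                    g.add((parent, vocab.generates, b))
                    nodes.append(b)
                    nxt.append(b)
            frontier = nxt
            depth += 1

        def pick_node() -> URIRef:
            # one draw regardless of policy, so cohorts generated from the
            # same seed differ only in placement depth, never in content
            idx = rng.randrange(len(nodes))
            policy = config.annotation_depth_policy
            if policy == "root":
                return case
            if policy == "random_node":
                return nodes[idx]
            # leaf: a node with no outgoing generates edge
            leaves = [x for x in nodes if not g.match((x, vocab.generates, None))]
            return (leaves or nodes)[idx % len(leaves or nodes)]

        placements: dict[URIRef, URIRef] = {}
        altered: set[tuple[str, str]] = set()
        instances: set[str] = set()
        if rng.random() < config.p_variant_observed:
            for sym in config.panel:
                for atype, p in config.p_alteration.get(sym, {}).items():
                    if rng.random() < p:
                        inst, label = _alteration_instance(
                            g, vocab, genes[sym], sym, atype, rng)
                        node = pick_node()
                        rec = annotate(g, node, inst, meta, vocab)
                        placements[rec.annotation_uri] = node
                        altered.add((sym, atype))
                        instances.add(label)

        variation: float | None = None
        label_cls: str | None = None
        treat_name: str | None = None
        if rng.random() < config.response.p_observed:
            has_variant = bool(altered)
            p_neg = (config.response.p_negative_given_variant if has_variant
                     else config.response.p_negative_given_no_variant)
            if rng.random() < p_neg:
                label_cls = "negative"
            elif rng.random() < config.response.positive_share_of_nonnegative:
                label_cls = "positive"
            else:
                label_cls = "neutral"
            variation = _draw_variation(rng, label_cls)
            treat_name = config.treatments[0]
            treatment = g.local(f"treatment/{treat_name}")
            node = pick_node()
            obs = ResponseObservation(node, treatment, variation)
            rec = annotate_response(g, obs, meta, vocab)
            placements[rec.annotation_uri] = node

        truth.cases[case] = CaseTruth(case, nodes, altered, instances,
                                      variation, label_cls, treat_name,
                                      placements)
    return g, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Tab-separated audit dump of the planted cohort."""
    import csv
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["case", "n_nodes", "altered", "instances",
                    "volume_variation", "response_class", "treatment"])
        for case in sorted(truth.cases, key=str):
            c = truth.cases[case]
            w.writerow([str(case), len(c.nodes),
                        ";".join(sorted(f"{g}:{t}" for g, t in c.altered)),
                        ";".join(sorted(c.variant_instances)),
                        "" if c.volume_variation is None
                        else f"{c.volume_variation:.3f}",
                        c.response_class or "", c.treatment or ""])


def table1_fixture(namespace: str = DEFAULT_NAMESPACE) -> TripleStore:
    """The worked-example experimental tree: seven ``generates`` edges.

    Root generates Tissue1 and Tissue2; Tissue1 generates Bioentity1;
    Tissue2 generates Bioentity2 and Bioentity3; Bioentity1 generates
    Bioentity4; Bioentity3 generates Bioentity5.  Nodes carry their
    operational types.
    """
    vocab = Vocabulary(namespace)
    g = TripleStore(namespace)
    root = g.local("Root")
    t1, t2 = g.local("Tissue1"), g.local("Tissue2")
    b = {i: g.local(f"Bioentity{i}") for i in range(1, 6)}
    g.add((root, RDF.type, vocab.Case))
    for t in (t1, t2):
        g.add((t, RDF.type, vocab.Tissue))
    for x in b.values():
        g.add((x, RDF.type, vocab.Bioentity))
    for s, o in [(root, t1), (root, t2), (t1, b[1]), (t2, b[2]), (t2, b[3]),
                 (b[1], b[4]), (b[3], b[5])]:
        g.add((s, vocab.generates, o))
    return g
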