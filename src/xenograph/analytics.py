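"""Cohort roll-up and summaries over materialized experimental trees.

The roll-up walks each case root plus everything the reasoner linked to it
via ``hasDescendant`` — the flattened secondary structure — so an
annotation sitting on a depth-5 aliquot counts for its case exactly like
one on the root.  Downstream summaries reproduce the standard cohort
views: annotated-tree counts, per-gene variant distributions, response
fractions stratified by altered-gene combination, and the non-responder
breakdown (gene, then alteration type, then variant instance — instances
only exist for point mutations; amplifications collapse to the type
level).

Subset semantics: "mutations only" means at least one sequence alteration
in the panel and no amplification, and vice versa for "amplifications
only"; the two subsets are disjoint by construction.  Co-occurrence strata
use exact gene-set identity: a case altered in {KRAS, BRAF} belongs to the
{KRAS, BRAF} stratum and is *not* counted in the {KRAS} stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal as TypingLiteral

import pandas as pd
from rdflib import Literal, URIRef
from rdflib.namespace import RDF

from .annotate import classify_response
from .reason import MaterializationState
from .store import TripleStore
from .vocab import (COPY_NUMBER_VARIATION, FEATURE_AMPLIFICATION,
                    SEQUENCE_ALTERATION, Vocabulary)

SubsetMode = TypingLiteral["all", "mutations_only", "amplifications_only",
                           "any_variant", "no_variant"]


@dataclass(frozen=True)
class VariantHit:
    gene: URIRef
    alteration_type: str
    instance: URIRef


@dataclass(frozen=True)
class ResponseSummary:
    mean_variation: float
    label: str
    n_observations: int


@dataclass
class CaseRow:
    altered_genes_by_type: dict[URIRef, set[str]] = field(default_factory=dict)
    variant_instances: set[URIRef] = field(default_factory=set)
    variants: set[VariantHit] = field(default_factory=set)
    responses: dict[URIRef, ResponseSummary] = field(default_factory=dict)

    @property
    def has_variant(self) -> bool:
        return bool(self.altered_genes_by_type)

    def altered_genes(self, types: Iterable[str] | None = None) -> frozenset[URIRef]:
        if types is None:
            return frozenset(self.altered_genes_by_type)
        tset = set(types)
        return frozenset(g for g, ts in self.altered_genes_by_type.items()
                         if ts & tset)


@dataclass
class CaseFeatureTable:
    rows: dict[URIRef, CaseRow] = field(default_factory=dict)
    panel: frozenset[URIRef] = frozenset()

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for case in sorted(self.rows, key=str):
            row = self.rows[case]
            for treatment, resp in sorted(row.responses.items(), key=str):
                recs.append({
                    "case": str(case),
                    "genes": ";".join(sorted(str(g).rsplit("/", 1)[-1]
                                             for g in row.altered_genes())),
                    "treatment": str(treatment).rsplit("/", 1)[-1],
                    "mean_variation": resp.mean_variation,
                    "response": resp.label,
                    "n_observations": resp.n_observations,
                })
            if not row.responses:
                recs.append({"case": str(case),
                             "genes": ";".join(sorted(
                                 str(g).rsplit("/", 1)[-1]
                                 for g in row.altered_genes())),
                             "treatment": None, "mean_variation": None,
                             "response": None, "n_observations": 0})
        return pd.DataFrame(recs)


def _alteration_type(state_graph: TripleStore, vocab: Vocabulary,
                     instance: URIRef) -> str | None:
    """Most specific alteration category of an instance, as a label."""
    types = {o for _, _, o in state_graph.match((instance, RDF.type, None))}
    if vocab.Feature_amplification in types:
        return FEATURE_AMPLIFICATION
    if vocab.Sequence_Alteration in types:
        return SEQUENCE_ALTERATION
    if vocab.Copy_number_variation in types:
        return COPY_NUMBER_VARIATION
    if vocab.Alteration in types:
        return "alteration"
    return None


def roll_up(state: MaterializationState, panel: Iterable[URIRef],
            vocab: Vocabulary | None = None,
            aggregate: str = "mean") -> CaseFeatureTable:
    """Per-case feature table from a materialized cohort graph.

    For each case root, annotations on the root and on every
    ``hasDescendant`` offspring are collected.  Alteration references are
    resolved to genes through the ``has_variant`` super-property (so any
    alteration category works), restricted to ``panel``.  Response
    observations are aggregated per case x treatment (``mean`` by default;
    ``worst`` takes the largest volume variation, ``best`` the smallest)
    and the aggregate is classified.
    """
    if aggregate not in ("mean", "worst", "best"):
        raise ValueError(f"unknown aggregation {aggregate!r}")
    g = state.graph
    vocab = vocab or Vocabulary(g.namespace)
    panel = frozenset(panel)
    table = CaseFeatureTable(panel=panel)
    for case, _, _ in g.match((None, RDF.type, vocab.Case)):
        row = CaseRow()
        observations: dict[URIRef, list[float]] = {}
        nodes = [case] + [o for _, _, o in
                          g.match((case, vocab.hasDescendant, None))]
        for node in nodes:
            for _, _, ann in g.match((node, vocab.has_annotation, None)):
                refs = g.match((ann, vocab.has_reference, None))
                if len(refs) != 1:
                    continue
                ref = refs[0][2]
                atype = _alteration_type(g, vocab, ref)
                if atype is not None:
                    hits = [s for s, _, _ in
                            g.match((None, vocab.has_variant, ref))
                            if s in panel]
                    for gene in hits:
                        row.altered_genes_by_type.setdefault(gene, set()).add(atype)
                        row.variant_instances.add(ref)
                        row.variants.add(VariantHit(gene, atype, ref))
                    continue
                if (ref, RDF.type, vocab.Drug_response) in g:
                    treatments = g.match((ref, vocab.has_treatment, None))
                    values = g.match((ann, vocab.volume_variation, None))
                    if treatments and values:
                        treatment = treatments[0][2]
                        delta = float(values[0][2])
                        observations.setdefault(treatment, []).append(delta)
        for treatment, deltas in observations.items():
            if aggregate == "mean":
                value = sum(deltas) / len(deltas)
            elif aggregate == "worst":
                value = max(deltas)
            else:
                value = min(deltas)
            row.responses[treatment] = ResponseSummary(
                value, classify_response(value), len(deltas))
        table.rows[case] = row
    return table


def count_cohort(table: CaseFeatureTable) -> dict[str, int]:
    """Cohort headline counts: cases with >=1 panel variant, with >=1
    response, and with both."""
    n_var = sum(1 for r in table.rows.values() if r.has_variant)
    n_resp = sum(1 for r in table.rows.values() if r.responses)
    n_both = sum(1 for r in table.rows.values()
                 if r.has_variant and r.responses)
    return {"n_variant_annotated": n_var, "n_response_annotated": n_resp,
            "n_both": n_both}


@dataclass(frozen=True)
class SubsetSpec:
    mode: SubsetMode = "all"
    panel: frozenset[URIRef] = frozenset()

    def __post_init__(self):
        if self.mode != "all" and not self.panel:
            raise ValueError("panel must be non-empty for gene-restricted modes")

    def contains(self, row: CaseRow) -> bool:
        muts = bool(row.altered_genes([SEQUENCE_ALTERATION]) & self.panel)
        amps = bool(row.altered_genes([FEATURE_AMPLIFICATION]) & self.panel)
        anyv = bool(row.altered_genes() & self.panel)
        if self.mode == "all":
            return True
        if self.mode == "mutations_only":
            return muts and not amps
        if self.mode == "amplifications_only":
            return amps and not muts
        if self.mode == "any_variant":
            return anyv
        if self.mode == "no_variant":
            return not anyv
        raise ValueError(f"unknown subset mode {self.mode!r}")


@dataclass
class ResponseFractionMatrix:
    """Per-stratum response-class fractions plus stratum case counts.

    Strata are frozensets of panel genes: every single panel gene plus
    every observed multi-gene combination; the empty frozenset collects
    variant-free cases.  Within a non-empty stratum the three fractions
    sum to 1.
    """
    fractions: dict[frozenset, dict[str, float]] = field(default_factory=dict)
    counts: dict[frozenset, int] = field(default_factory=dict)
    class_counts: dict[frozenset, dict[str, int]] = field(default_factory=dict)

    def overall(self) -> dict[str, float]:
        """Count-weighted class fractions across all strata."""
        totals = {"positive": 0, "neutral": 0, "negative": 0}
        n = 0
        for stratum, counts in self.class_counts.items():
            for label, k in counts.items():
                totals[label] += k
                n += k
        if n == 0:
            return {k: 0.0 for k in totals}
        return {k: v / n for k, v in totals.items()}

    @property
    def n_cases(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for stratum in sorted(self.fractions, key=lambda s: (len(s), sorted(map(str, s)))):
            name = "+".join(sorted(str(g).rsplit("/", 1)[-1] for g in stratum)) \
                or "(none)"
            recs.append({"stratum": name, "n": self.counts[stratum],
                         **self.fractions[stratum]})
        return pd.DataFrame(recs)


def stratified_response_fractions(table: CaseFeatureTable, spec: SubsetSpec,
                                  treatment: URIRef) -> ResponseFractionMatrix:
    """Response fractions per altered-gene stratum within a subset.

    Only cases inside the subset that carry a response for ``treatment``
    contribute.  Strata are exact gene-set combinations (see module notes);
    all single panel genes are reported even when empty.
    """
    matrix = ResponseFractionMatrix()
    strata: dict[frozenset, dict[str, int]] = {
        frozenset([g]): {"positive": 0, "neutral": 0, "negative": 0}
        for g in (spec.panel or table.panel)}
    for case, row in table.rows.items():
        if not spec.contains(row):
            continue
        resp = row.responses.get(treatment)
        if resp is None:
            continue
        key = frozenset(row.altered_genes() & (spec.panel or table.panel))
        strata.setdefault(key, {"positive": 0, "neutral": 0, "negative": 0})
        strata[key][resp.label] += 1
    for key, counts in strata.items():
        n = sum(counts.values())
        matrix.counts[key] = n
        matrix.class_counts[key] = dict(counts)
        matrix.fractions[key] = (
            {k: v / n for k, v in counts.items()} if n
            else {k: 0.0 for k in counts})
    return matrix


def variant_distribution(table: CaseFeatureTable,
                         spec: SubsetSpec) -> pd.DataFrame:
    """Cases carrying each (gene, alteration type) pair within a subset.

    Raw counts; any log scaling is presentation-layer.
    """
    counts: dict[tuple[str, str], int] = {}
    for row in table.rows.values():
        if not spec.contains(row):
            continue
        for gene, types in row.altered_genes_by_type.items():
            for atype in types:
                key = (str(gene).rsplit("/", 1)[-1], atype)
                counts[key] = counts.get(key, 0) + 1
    recs = [{"gene": g, "alteration_type": t, "n_cases": n}
            for (g, t), n in sorted(counts.items())]
    return pd.DataFrame(recs, columns=["gene", "alteration_type", "n_cases"])


def nonresponder_breakdown(table: CaseFeatureTable,
                           treatment: URIRef | None = None) -> pd.DataFrame:
    """Variant occurrences in negative-response cases, grouped by gene,
    then alteration type, then variant instance.

    The instance level is only available for sequence alterations;
    amplification occurrences collapse to the type level (instance is
    reported as missing).  If ``treatment`` is None, a case counts as a
    non-responder when any of its treatments classified negative.
    """
    counts: dict[tuple[str, str, str | None], int] = {}
    for row in table.rows.values():
        if treatment is None:
            negative = any(r.label == "negative" for r in row.responses.values())
        else:
            resp = row.responses.get(treatment)
            negative = resp is not None and resp.label == "negative"
        if not negative:
            continue
        for hit in row.variants:
            gene = str(hit.gene).rsplit("/", 1)[-1]
            inst = (str(hit.instance).rsplit("/", 1)[-1]
                    if hit.alteration_type == SEQUENCE_ALTERATION else None)
            key = (gene, hit.alteration_type, inst)
            counts[key] = counts.get(key, 0) + 1
    recs = [{"gene": g, "alteration_type": t, "instance": i, "n_cases": n}
            for (g, t, i), n in sorted(counts.items(),
                                       key=lambda kv: (kv[0][0], kv[0][1],
                                                       kv[0][2] or ""))]
    return pd.DataFrame(recs,
                        columns=["gene", "alteration_type", "instance",
                                 "n_cases"])


def genes_by_symbol(store: TripleStore, symbols: Iterable[str],
                    vocab: Vocabulary | None = None) -> dict[str, URIRef]:
    """Resolve gene symbols to URIs via their symbol literals."""
    vocab = vocab or Vocabulary(store.namespace)
    out: dict[str, URIRef] = {}
    for sym in symbols:
        hits = store.match((None, vocab.symbol, Literal(sym)))
        if hits:
            out[sym] = hits[0][0]
    return out
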