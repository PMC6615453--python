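"""In-memory triple store with Turtle I/O and conjunctive triple-pattern queries.

The store keeps RDF triples (rdflib terms) in plain Python sets with
subject/predicate/object indexes, and tracks per-triple provenance:
``asserted`` statements come from input documents or API calls, ``inferred``
statements are added by the reasoner.  (s, p, o) identity ignores provenance
and the store never holds duplicates; a triple that is both asserted and
derivable is stored as asserted.

Turtle parsing is delegated to rdflib.  Serialization is a deterministic
emitter (sorted subjects/predicates/objects, terms formatted with rdflib's
``n3``) so that a fixed input always yields byte-identical output — a
contract the synthetic-cohort generator relies on.
"""

from __future__ import annotations

import re
from collections import defaultdict
from typing import Iterable, Iterator, Mapping, Sequence

from rdflib import Graph as _RdflibGraph
from rdflib import Literal, URIRef, Variable
from rdflib.namespace import OWL, RDF, RDFS, XSD, NamespaceManager

from .errors import ConfigurationError, ParseError, QueryError

Term = URIRef | Literal
Triple = tuple[URIRef, URIRef, Term]
#: One position of a triple pattern: a constant, a named variable, or None (wildcard).
PatternTerm = Term | Variable | None
TriplePattern = tuple[PatternTerm, PatternTerm, PatternTerm]

ASSERTED = "asserted"
INFERRED = "inferred"

DEFAULT_NAMESPACE = "http://example.org/lab/"

WD = "http://www.wikidata.org/entity/"

_BASE_PREFIXES: dict[str, str] = {
    "rdf": str(RDF),
    "rdfs": str(RDFS),
    "owl": str(OWL),
    "xsd": str(XSD),
    "wd": WD,
}

_URI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*://\S+$|^urn:\S+$")


def _check_namespace(namespace: str) -> str:
    if not isinstance(namespace, str) or not _URI_RE.match(namespace):
        raise ConfigurationError(f"not a valid namespace URI: {namespace!r}")
    return namespace


class TripleStore:
    """A set of triples with provenance, prefixes, and pattern matching."""

    def __init__(self, namespace: str = DEFAULT_NAMESPACE,
                 prefixes: Mapping[str, str] | None = None):
        self.namespace = _check_namespace(namespace)
        self._prefixes: dict[str, str] = {"": namespace, **_BASE_PREFIXES}
        if prefixes:
            self._prefixes.update(prefixes)
        self._asserted: set[Triple] = set()
        self._inferred: set[Triple] = set()
        self._by_s: dict[Term, set[Triple]] = defaultdict(set)
        self._by_p: dict[Term, set[Triple]] = defaultdict(set)
        self._by_o: dict[Term, set[Triple]] = defaultdict(set)

    # ------------------------------------------------------------------ basics

    def __len__(self) -> int:
        return len(self._asserted) + len(self._inferred)

    def __iter__(self) -> Iterator[Triple]:
        yield from self._asserted
        yield from self._inferred

    def __contains__(self, triple: Triple) -> bool:
        return triple in self._asserted or triple in self._inferred

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TripleStore):
            return NotImplemented
        return self.triple_set() == other.triple_set()

    def triple_set(self) -> frozenset[Triple]:
        return frozenset(self._asserted | self._inferred)

    @property
    def asserted(self) -> frozenset[Triple]:
        return frozenset(self._asserted)

    @property
    def inferred(self) -> frozenset[Triple]:
        return frozenset(self._inferred)

    def provenance(self, triple: Triple) -> str | None:
        if triple in self._asserted:
            return ASSERTED
        if triple in self._inferred:
            return INFERRED
        return None

    def bind(self, prefix: str, namespace: str) -> None:
        self._prefixes[prefix] = namespace

    @property
    def prefixes(self) -> dict[str, str]:
        return dict(self._prefixes)

    def local(self, name: str) -> URIRef:
        """URI in the store's default (local) namespace."""
        return URIRef(self.namespace + name)

    # --------------------------------------------------------------- mutation

    def add(self, triple: Triple, *, inferred: bool = False) -> bool:
        """Insert a triple; returns True if the triple set grew or the
        triple was promoted from inferred to asserted."""
        s, p, o = triple
        if isinstance(s, Literal) or isinstance(p, Literal):
            raise ValueError("literals are only allowed in object position")
        if triple in self._asserted:
            return False
        if triple in self._inferred:
            if inferred:
                return False
            # promotion: explicit assertion of a previously derived fact
            self._inferred.discard(triple)
            self._asserted.add(triple)
            return True
        (self._inferred if inferred else self._asserted).add(triple)
        self._by_s[s].add(triple)
        self._by_p[p].add(triple)
        self._by_o[o].add(triple)
        return True

    def discard(self, triple: Triple) -> bool:
        """Remove a triple regardless of provenance; True if it was present."""
        if triple in self._asserted:
            self._asserted.discard(triple)
        elif triple in self._inferred:
            self._inferred.discard(triple)
        else:
            return False
        s, p, o = triple
        self._by_s[s].discard(triple)
        self._by_p[p].discard(triple)
        self._by_o[o].discard(triple)
        return True

    def demote(self, triple: Triple) -> None:
        """Turn an asserted triple into an inferred one (reasoner internal)."""
        if triple in self._asserted:
            self._asserted.discard(triple)
            self._inferred.add(triple)

    def update(self, triples: Iterable[Triple], *, inferred: bool = False) -> None:
        for t in triples:
            self.add(t, inferred=inferred)

    def copy(self) -> "TripleStore":
        dup = TripleStore(self.namespace, self._prefixes)
        for t in self._asserted:
            dup.add(t)
        for t in self._inferred:
            dup.add(t, inferred=True)
        return dup

    # --------------------------------------------------------------- matching

    def match(self, pattern: TriplePattern) -> list[Triple]:
        """All triples unifying with the pattern (Variable/None = wildcard).

        A variable repeated within the pattern must bind consistently,
        e.g. ``(?x, p, ?x)`` only matches triples with subject == object.
        """
        s, p, o = pattern
        candidate_sets = []
        if isinstance(s, (URIRef, Literal)):
            candidate_sets.append(self._by_s.get(s, set()))
        if isinstance(p, (URIRef, Literal)):
            candidate_sets.append(self._by_p.get(p, set()))
        if isinstance(o, (URIRef, Literal)):
            candidate_sets.append(self._by_o.get(o, set()))
        if candidate_sets:
            pool: Iterable[Triple] = min(candidate_sets, key=len)
        else:
            pool = self
        out = []
        for t in pool:
            if self._unifies(pattern, t):
                out.append(t)
        return out

    @staticmethod
    def _unifies(pattern: TriplePattern, triple: Triple) -> bool:
        binding: dict[Variable, Term] = {}
        for pt, tt in zip(pattern, triple):
            if pt is None:
                continue
            if isinstance(pt, Variable):
                if pt in binding and binding[pt] != tt:
                    return False
                binding[pt] = tt
            elif pt != tt:
                return False
        return True

    def query(self, patterns: Sequence[TriplePattern],
              project: Sequence[str | Variable]) -> set[tuple[Term, ...]]:
        """Conjunctive pattern query: natural join of the pattern matches,
        projected to ``project`` and deduplicated (SELECT DISTINCT semantics)."""
        proj_vars = [Variable(v) if isinstance(v, str) else v for v in project]
        known = {t for pat in patterns for t in pat if isinstance(t, Variable)}
        for v in proj_vars:
            if v not in known:
                raise QueryError(f"projected variable ?{v} not bound by any pattern")
        bindings: list[dict[Variable, Term]] = [{}]
        for pat in patterns:
            nxt: list[dict[Variable, Term]] = []
            for b in bindings:
                ground = tuple(b.get(t, t) if isinstance(t, Variable) else t
                               for t in pat)
                for triple in self.match(ground):  # type: ignore[arg-type]
                    nb = dict(b)
                    ok = True
                    for pt, tt in zip(pat, triple):
                        if isinstance(pt, Variable):
                            if pt in nb and nb[pt] != tt:
                                ok = False
                                break
                            nb[pt] = tt
                    if ok:
                        nxt.append(nb)
            bindings = nxt
        return {tuple(b[v] for v in proj_vars) for b in bindings}

    # -------------------------------------------------------------- Turtle IO

    def load_turtle(self, text: str) -> int:
        """Parse a Turtle document and add its statements as asserted triples.

        Returns the number of statements added; absorbs the document's
        prefix declarations into the store's prefix table.
        """
        g = _RdflibGraph()
        try:
            g.parse(data=text, format="turtle")
        except Exception as exc:  # rdflib BadSyntax carries .lines
            line = getattr(exc, "lines", None)
            raise ParseError(f"Turtle syntax error: {exc}", line=line) from exc
        for prefix, ns in g.namespaces():
            if prefix and prefix not in self._prefixes:
                self._prefixes[prefix] = str(ns)
        n = 0
        for s, p, o in g:
            n += int(self.add((s, p, o)))  # type: ignore[arg-type]
        return n

    @classmethod
    def from_turtle(cls, text: str, namespace: str = DEFAULT_NAMESPACE) -> "TripleStore":
        store = cls(namespace)
        store.load_turtle(text)
        return store

    @classmethod
    def read(cls, path, namespace: str = DEFAULT_NAMESPACE) -> "TripleStore":
        with open(path, encoding="utf-8") as fh:
            return cls.from_turtle(fh.read(), namespace)

    def _namespace_manager(self) -> NamespaceManager:
        g = _RdflibGraph(bind_namespaces="none")
        for prefix, ns in self._prefixes.items():
            g.bind(prefix, ns, replace=True)
        return NamespaceManager(g, bind_namespaces="none")

    def serialize(self, provenance: str = "both") -> str:
        """Deterministic Turtle serialization.

        ``provenance`` selects which statements to emit: ``asserted``,
        ``inferred`` or ``both``.  Output is stable across runs and
        processes: prefixes, subjects, predicates and objects are sorted.
        """
        if provenance == ASSERTED:
            triples: Iterable[Triple] = self._asserted
        elif provenance == INFERRED:
            triples = self._inferred
        elif provenance == "both":
            triples = self._asserted | self._inferred
        else:
            raise ValueError(f"unknown provenance selector: {provenance!r}")
        nm = self._namespace_manager()
        lines = [f"@prefix {prefix}: <{ns}> ."
                 for prefix, ns in sorted(self._prefixes.items())]
        lines.append("")
        by_subject: dict[str, list[tuple[str, str]]] = defaultdict(list)
        for s, p, o in triples:
            by_subject[s.n3(nm)].append((p.n3(nm), o.n3(nm)))
        for subj in sorted(by_subject):
            pos = sorted(by_subject[subj])
            parts = [f"{subj} {p} {o}" for p, o in pos]
            lines.append(" ;\n    ".join([parts[0]] +
                                         [f"{p} {o}" for p, o in pos[1:]]) + " .")
        return "\n".join(lines) + "\n"

    def write(self, path, provenance: str = "both") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.serialize(provenance))

    # ------------------------------------------------------------ CLI parsing

    def expand_curie(self, token: str) -> URIRef:
        if token.startswith("<") and token.endswith(">"):
            return URIRef(token[1:-1])
        if ":" in token:
            prefix, _, local = token.partition(":")
            if prefix in self._prefixes:
                return URIRef(self._prefixes[prefix] + local)
        if _URI_RE.match(token):
            return URIRef(token)
        raise QueryError(f"cannot resolve {token!r}: unknown prefix")

    def parse_pattern(self, text: str) -> TriplePattern:
        """Parse a whitespace-separated pattern like ``?s :has_annotation ?a``."""
        tokens = text.split()
        if len(tokens) != 3:
            raise QueryError(f"pattern must have 3 terms: {text!r}")
        out: list[PatternTerm] = []
        for i, tok in enumerate(tokens):
            if tok.startswith("?"):
                out.append(Variable(tok[1:]))
            elif tok.startswith('"') and tok.endswith('"') and len(tok) >= 2:
                out.append(Literal(tok[1:-1]))
            elif i == 2 and re.fullmatch(r"[+-]?\d+(\.\d+)?", tok):
                out.append(Literal(tok, datatype=XSD.decimal))
            else:
                out.append(self.expand_curie(tok))
        return tuple(out)  # type: ignore[return-value]
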