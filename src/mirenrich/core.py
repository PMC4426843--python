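"""Core domain types and overlap primitives.

The objects here are shared by every enrichment method in the package:

* :class:`TargetPredictionSet` — a sparse miRNA × gene incidence structure
  carrying predicted binding-site counts.  Its miRNA universe is the set of
  names eligible for null resampling.
* :class:`AnnotationSet` — term → gene-set map plus the gene universe used
  as the population of the hypergeometric test.
* :class:`MiRNAList` / :class:`AliasMap` — input-list resolution through
  miRBase-style aliases.
* :class:`HypergeomParams` — the validated (k, n, K, N) tuple of the
  one-sided over-representation test.

All name matching is case-insensitive after whitespace trimming, because
published miRNA lists mix capitalisation conventions.  Internal orderings
are lexicographic so seeded runs are bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "TargetPredictionSet",
    "AnnotationSet",
    "MiRNAList",
    "AliasMap",
    "HypergeomParams",
    "union_targets",
    "term_overlap",
    "resolve_mirnas",
]


def _norm(name: str) -> str:
    return name.strip().casefold()


class TargetPredictionSet:
    """Sparse miRNA → gene map with predicted binding-site counts.

    Absence of a (miRNA, gene) key means "not predicted to target"; every
    stored count is >= 1.  ``mirna_ids`` is exactly the miRNA universe used
    for null resampling.
    """

    def __init__(self, sites: Mapping[tuple[str, str], int]) -> None:
        by_mirna: dict[str, dict[str, int]] = {}
        genes: set[str] = set()
        for (m, g), c in sites.items():
            c = int(c)
            if c < 1:
                raise ValueError(f"site count for ({m}, {g}) must be >= 1, got {c}")
            by_mirna.setdefault(m, {})[g] = c
            genes.add(g)
        self._by_mirna = {m: by_mirna[m] for m in sorted(by_mirna)}
        self.mirna_ids: tuple[str, ...] = tuple(sorted(by_mirna))
        self.gene_ids: tuple[str, ...] = tuple(sorted(genes))
        self._mirna_lookup = {_norm(m): m for m in self.mirna_ids}

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, int]]) -> "TargetPredictionSet":
        """Build from (mirna, gene, site_count) rows, summing duplicates."""
        agg: dict[tuple[str, str], int] = {}
        for m, g, c in records:
            c = int(c)
            if c < 1:
                raise ValueError(f"site count for ({m}, {g}) must be >= 1, got {c}")
            key = (m.strip(), g.strip())
            agg[key] = agg.get(key, 0) + c
        return cls(agg)

    @property
    def sites(self) -> dict[tuple[str, str], int]:
        return {(m, g): c for m, row in self._by_mirna.items() for g, c in row.items()}

    def site_count(self, mirna: str, gene: str) -> int:
        return self._by_mirna.get(mirna, {}).get(gene, 0)

    def targets_of(self, mirna: str) -> frozenset[str]:
        return frozenset(self._by_mirna.get(mirna, {}))

    def sites_of(self, mirna: str) -> Mapping[str, int]:
        return dict(self._by_mirna.get(mirna, {}))

    def lookup(self, name: str) -> str | None:
        """Case-insensitive resolution of a miRNA name to its stored id."""
        return self._mirna_lookup.get(_norm(name))

    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TargetPredictionSet) and self._by_mirna == other._by_mirna

    def __repr__(self) -> str:
        n_pairs = sum(len(r) for r in self._by_mirna.values())
        return (
            f"TargetPredictionSet({len(self.mirna_ids)} miRNAs, "
            f"{len(self.gene_ids)} genes, {n_pairs} pairs)"
        )


class AnnotationSet:
    """Term → gene-set map plus the gene universe (hypergeometric population).

    By default the universe is the set of genes carrying at least one
    annotation, the population a DAVID-style analysis uses; an explicit
    universe may be supplied but must contain every annotated gene.
    """

    def __init__(
        self,
        terms: Mapping[str, Iterable[str]],
        universe: Iterable[str] | None = None,
        term_names: Mapping[str, str] | None = None,
    ) -> None:
        self.terms: dict[str, frozenset[str]] = {
            t: frozenset(terms[t]) for t in sorted(terms)
        }
        annotated = frozenset().union(*self.terms.values()) if self.terms else frozenset()
        if universe is None:
            self.universe: frozenset[str] = annotated
        else:
            self.universe = frozenset(universe)
            missing = annotated - self.universe
            if missing:
                raise ValueError(
                    f"{len(missing)} annotated gene(s) missing from explicit universe, "
                    f"e.g. {sorted(missing)[:3]}"
                )
        self.term_names: dict[str, str] = dict(term_names or {})

    @property
    def term_ids(self) -> tuple[str, ...]:
        return tuple(self.terms)

    def term_size(self, term_id: str) -> int:
        """Term size restricted to the universe (the K of the test)."""
        return len(self.terms[term_id] & self.universe)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AnnotationSet)
            and self.terms == other.terms
            and self.universe == other.universe
        )

    def __repr__(self) -> str:
        return f"AnnotationSet({len(self.terms)} terms, universe of {len(self.universe)} genes)"


@dataclass(frozen=True)
class MiRNAList:
    """A resolved input miRNA list; ``dropped`` records names removed during
    resolution (deleted entries, names absent from the prediction set)."""

    names: tuple[str, ...]
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("miRNA list contains duplicate names")

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class AliasMap:
    """Many-to-one alias → canonical miRNA-name map.

    ``deleted`` holds names whose entries no longer have a current canonical
    form.  The map is idempotent: one application reaches a canonical name.
    """

    mapping: Mapping[str, str] = field(default_factory=dict)
    deleted: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        norm = {_norm(a): c for a, c in self.mapping.items()}
        object.__setattr__(self, "_norm_map", norm)
        object.__setattr__(self, "_norm_deleted", frozenset(_norm(d) for d in self.deleted))
        for canonical in norm.values():
            mapped = norm.get(_norm(canonical))
            if mapped is not None and _norm(mapped) != _norm(canonical):
                raise ValueError(
                    f"alias map is not idempotent: {canonical!r} maps on to {mapped!r}"
                )

    def resolve(self, name: str) -> str | None:
        """Canonical name for ``name``; None when the entry was deleted."""
        key = _norm(name)
        if key in self._norm_deleted:  # type: ignore[attr-defined]
            return None
        return self._norm_map.get(key, name.strip())  # type: ignore[attr-defined]


@dataclass(frozen=True)
class HypergeomParams:
    """Parameters of the one-sided over-representation test.

    k: observed annotated targets; n: total targeted genes in the universe;
    K: term size in the universe; N: universe size.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"require 0 <= k <= min(n, K); got {self}")
        if not (0 <= self.n <= self.N and 0 <= self.K <= self.N):
            raise ValueError(f"require n <= N and K <= N; got {self}")
        if self.N <= 0:
            raise ValueError("universe size N must be positive")


def resolve_mirnas(
    raw_names: Iterable[str],
    aliases: AliasMap | None,
    preds: TargetPredictionSet,
) -> MiRNAList:
    """Map raw names through aliases, then keep those present in the
    prediction set's miRNA universe.

    Non-resolvable names (deleted miRBase entries, names without predictions)
    are recorded in ``dropped``, never silently discarded.  Duplicates after
    resolution are collapsed, keeping first occurrence order.
    """
    aliases = aliases or AliasMap()
    names: list[str] = []
    seen: set[str] = set()
    dropped: list[str] = []
    for raw in raw_names:
        canonical = aliases.resolve(raw)
        if canonical is None:
            dropped.append(raw)
            continue
        stored = preds.lookup(canonical)
        if stored is None:
            dropped.append(raw)
            continue
        if stored not in seen:
            seen.add(stored)
            names.append(stored)
    if not names:
        raise ValueError(
            "no input miRNA resolved to the prediction set; nothing to test "
            f"(dropped: {dropped})"
        )
    return MiRNAList(names=tuple(names), dropped=tuple(dropped))


def union_targets(preds: TargetPredictionSet, mirnas: MiRNAList) -> frozenset[str]:
    """Union of predicted target genes over the input miRNAs."""
    out: set[str] = set()
    for m in mirnas.names:
        out |= preds.targets_of(m)
    return frozenset(out)


def term_overlap(
    target_genes: frozenset[str] | set[str],
    term_id: str,
    ann: AnnotationSet,
    mode: str = "count",
) -> float:
    """Overlap of a target gene set with one term.

    ``count`` mode returns |targets ∩ term|; ``proportion`` divides by the
    number of target genes (0 when the target set is empty).  The caller is
    expected to have restricted ``target_genes`` to ``ann.universe``.
    """
    if term_id not in ann.terms:
        raise KeyError(f"unknown term id: {term_id!r}")
    count = len(frozenset(target_genes) & ann.terms[term_id])
    if mode == "count":
        return float(count)
    if mode == "proportion":
        return count / len(target_genes) if target_genes else 0.0
    raise ValueError(f"mode must be 'count' or 'proportion', got {mode!r}")
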