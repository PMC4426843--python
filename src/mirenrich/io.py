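"""Readers and writers for the plain-text formats consumed by the package.

Formats
-------
prediction TSV
    Columns ``mirna<TAB>gene[<TAB>site_count]``.  A header row is optional
    (detected when the third column is non-numeric or the first row equals
    common header names); ``#`` comment lines are ignored.
annotation
    Standard GMT (``term<TAB>description<TAB>gene...``) or a two-column
    ``gene<TAB>term`` TSV (BioMart-export style).
alias map
    Either miRBase ``aliases.txt`` shape (``accession<TAB>name1;name2;...``,
    all previous names mapping to the last, current, name) or a plain
    ``old<TAB>new`` TSV where an empty / ``-`` second column marks a name
    whose entry has been deleted.
miRNA list
    One name per line.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

from .core import AliasMap, AnnotationSet, TargetPredictionSet

__all__ = [
    "load_predictions",
    "write_predictions",
    "load_annotations",
    "write_annotations_gmt",
    "load_mirna_list",
    "write_mirna_list",
    "load_aliases",
]

_PRED_HEADERS = {"mirna", "mir", "mirna_id", "microrna"}


def _data_lines(path: str | Path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def load_predictions(path: str | Path, dialect: str = "pairs_with_counts") -> TargetPredictionSet:
    """Load a miRNA → gene target-prediction table.

    ``pairs`` treats every row as one predicted site (duplicates sum);
    ``pairs_with_counts`` reads an explicit third site-count column.
    """
    if dialect not in ("pairs", "pairs_with_counts"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[tuple[str, str, int]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 tab-separated columns")
        mirna, gene = fields[0].strip(), fields[1].strip()
        if lineno == 1 and mirna.casefold() in _PRED_HEADERS:
            continue
        if not mirna or not gene:
            raise ValueError(f"{path}:{lineno}: empty miRNA or gene name")
        if dialect == "pairs":
            count = 1
        else:
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: dialect pairs_with_counts needs a third column")
            try:
                count = int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: site_count {fields[2]!r} is not an integer") from exc
            if count <= 0:
                raise ValueError(f"{path}:{lineno}: site_count must be >= 1, got {count}")
        records.append((mirna, gene, count))
    return TargetPredictionSet.from_records(records)


def write_predictions(preds: TargetPredictionSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("mirna\tgene\tsite_count\n")
        for m in preds.mirna_ids:
            for g, c in sorted(preds.sites_of(m).items()):
                fh.write(f"{m}\t{g}\t{c}\n")


def load_annotations(
    path: str | Path,
    dialect: str = "gmt",
    universe_policy: str = "annotated_only",
    universe: Iterable[str] | None = None,
) -> AnnotationSet:
    """Load term → gene-set annotations from GMT or gene/term pairs.

    ``universe_policy='annotated_only'`` (default) sets the population to
    genes with at least one annotation; ``'explicit'`` requires ``universe``.
    Empty terms are dropped with a warning; a duplicated term id with a
    different gene set is an error.
    """
    if universe_policy not in ("annotated_only", "explicit"):
        raise ValueError(f"unknown universe_policy {universe_policy!r}")
    if universe_policy == "explicit" and universe is None:
        raise ValueError("universe_policy='explicit' requires a universe")
    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    if dialect == "gmt":
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs term and description columns")
            term, desc = fields[0].strip(), fields[1].strip()
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                warnings.warn(f"{path}:{lineno}: dropping empty term {term!r}")
                continue
            if term in terms and terms[term] != genes:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r} with different gene sets")
            terms[term] = genes
            if desc:
                names[term] = desc
    elif dialect == "pairs":
        pair_sets: dict[str, set[str]] = {}
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene<TAB>term")
            gene, term = fields[0].strip(), fields[1].strip()
            if not gene or not term:
                raise ValueError(f"{path}:{lineno}: empty gene or term")
            pair_sets.setdefault(term, set()).add(gene)
        terms = {t: frozenset(gs) for t, gs in pair_sets.items()}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return AnnotationSet(
        terms,
        universe=None if universe_policy == "annotated_only" else universe,
        term_names=names,
    )


def write_annotations_gmt(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term in ann.term_ids:
            desc = ann.term_names.get(term, "")
            genes = "\t".join(sorted(ann.terms[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def load_mirna_list(path: str | Path) -> list[str]:
    """Read raw (unresolved) miRNA names, one per line."""
    return [line.strip() for _, line in _data_lines(path)]


def write_mirna_list(names: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in names:
            fh.write(f"{name}\n")


def load_aliases(path: str | Path, dialect: str = "mirbase") -> AliasMap:
    """Load an alias map.

    ``mirbase``: ``accession<TAB>name1;name2;...`` — every listed name maps
    to the last (current) name.  ``pairs``: ``old<TAB>new`` rows; an empty or
    ``-`` new name marks a deleted entry.
    """
    mapping: dict[str, str] = {}
    deleted: set[str] = set()
    if dialect == "mirbase":
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected accession<TAB>names")
            names = [n.strip() for n in fields[1].split(";") if n.strip()]
            if not names:
                continue
            current = names[-1]
            for old in names[:-1]:
                mapping[old] = current
    elif dialect == "pairs":
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            old = fields[0].strip()
            new = fields[1].strip() if len(fields) > 1 else ""
            if not old:
                raise ValueError(f"{path}:{lineno}: empty name")
            if not new or new == "-":
                deleted.add(old)
            else:
                mapping[old] = new
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return AliasMap(mapping=mapping, deleted=frozenset(deleted))
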