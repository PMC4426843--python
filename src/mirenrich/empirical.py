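"""Empirical resampling test for miRNA target-set functional enrichment.

Instead of modelling the union target set as a uniform draw of genes (the
hypergeometric assumption), the test is taken back to the level of miRNAs:
random miRNA sets of the same size as the input list are drawn without
replacement from the full miRNA universe, the per-term overlap statistic is
recomputed for each draw, and the empirical p-value is the proportion of
draws whose statistic is equal to or greater than the observed one.

Three statistics are supported:

* ``union_count`` — number of union target genes annotated with the term;
* ``union_proportion`` — that count divided by the union size (default for
  hypothesis testing: it normalises for union size varying across draws);
* ``multihit`` — each gene scored by its total predicted binding-site count
  over the input miRNAs (multiple sites per miRNA included); the term
  statistic is the summed score of its member genes divided by the total
  score.  This rewards convergent targeting of a process by many miRNAs.

Null sampling is streamed: only per-term exceedance counts and running
moments are kept, so one million iterations need no storage of null vectors.
Draws are generated counter-style — batch ``b`` of a fixed batch size
derives from a Philox key ``(seed, b)`` — making the stream independent of
execution order and prefix-stable in the iteration count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .core import AnnotationSet, MiRNAList, TargetPredictionSet, term_overlap, union_targets
from .stats import EnrichmentTable, bh_adjust

__all__ = [
    "STATISTIC_KINDS",
    "GeneScoreMap",
    "NullSummary",
    "multihit_gene_scores",
    "multihit_term_overlap",
    "observed_statistic",
    "sample_null",
    "empirical_enrichment",
    "exact_enumeration_enrichment",
]

STATISTIC_KINDS = ("union_count", "union_proportion", "multihit")

#: iterations per Philox counter batch; part of the reproducibility contract
#: (draws for batch b depend only on (seed, b) and this constant).
_BATCH = 1024

#: relative tolerance making float ties inclusive in the ">= observed" rule
#: for proportion-valued statistics; counts are compared exactly.
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class GeneScoreMap:
    """Gene → total predicted binding-site count over the input miRNAs."""

    scores: Mapping[str, int]
    total_score: int

    def __post_init__(self) -> None:
        if self.total_score != sum(self.scores.values()):
            raise ValueError("total_score does not equal the sum of gene scores")
        if any(s < 0 for s in self.scores.values()):
            raise ValueError("gene scores must be non-negative")


def multihit_gene_scores(
    preds: TargetPredictionSet,
    mirnas: MiRNAList,
    universe: frozenset[str] | set[str] | None = None,
) -> GeneScoreMap:
    """Score each gene by its summed site count across the input miRNAs.

    Multiple sites for the same miRNA count individually.  When ``universe``
    is given, genes outside it are excluded (the default universe policy).
    """
    scores: dict[str, int] = {}
    for m in mirnas.names:
        for g, c in preds.sites_of(m).items():
            if universe is not None and g not in universe:
                continue
            scores[g] = scores.get(g, 0) + c
    return GeneScoreMap(scores=scores, total_score=sum(scores.values()))


def multihit_term_overlap(scores: GeneScoreMap, term_id: str, ann: AnnotationSet) -> float:
    """Summed score of the term's member genes divided by the total score."""
    if term_id not in ann.terms:
        raise KeyError(f"unknown term id: {term_id!r}")
    if scores.total_score == 0:
        raise ValueError("total score is zero; no scored target gene")
    term_genes = ann.terms[term_id]
    return sum(s for g, s in scores.scores.items() if g in term_genes) / scores.total_score


def observed_statistic(
    preds: TargetPredictionSet,
    ann: AnnotationSet,
    mirnas: MiRNAList,
    statistic_kind: str = "union_proportion",
) -> dict[str, float]:
    """Per-term observed statistic for the input list (set-based reference
    path, independent of the vectorised null engine)."""
    if statistic_kind not in STATISTIC_KINDS:
        raise ValueError(f"unknown statistic_kind {statistic_kind!r}")
    if statistic_kind == "multihit":
        scores = multihit_gene_scores(preds, mirnas, universe=ann.universe)
        if scores.total_score == 0:
            raise ValueError("no predicted target site falls in the annotation universe")
        return {t: multihit_term_overlap(scores, t, ann) for t in ann.term_ids}
    targets = union_targets(preds, mirnas) & ann.universe
    if not targets:
        raise ValueError("no predicted target gene falls in the annotation universe")
    mode = "count" if statistic_kind == "union_count" else "proportion"
    return {t: term_overlap(targets, t, ann, mode=mode) for t in ann.term_ids}


# ---------------------------------------------------------------------------
# vectorised null engine
# ---------------------------------------------------------------------------


def _pack_bool_rows(mat: np.ndarray) -> np.ndarray:
    """Pack boolean rows into uint64 words (zero-padded) for bitset algebra."""
    packed = np.packbits(mat, axis=1)
    pad = (-packed.shape[1]) % 8
    if pad:
        packed = np.pad(packed, ((0, 0), (0, pad)))
    return np.ascontiguousarray(packed).view(np.uint64)


class NullEngine:
    """Precomputed arrays turning a null draw into per-term statistics.

    Union statistics use bit-packed gene incidence (OR-reduce over the drawn
    miRNA rows, then popcount against packed term masks); the multi-hit
    statistic is linear in miRNAs, so per-term site totals are precomputed
    per miRNA and a draw reduces to a sum of rows.  Genes outside the
    annotation universe and terms with no universe gene are excluded.
    """

    def __init__(
        self,
        preds: TargetPredictionSet,
        ann: AnnotationSet,
        statistic_kind: str = "union_proportion",
    ) -> None:
        if statistic_kind not in STATISTIC_KINDS:
            raise ValueError(f"unknown statistic_kind {statistic_kind!r}")
        if not ann.universe:
            raise ValueError("annotation universe is empty")
        self.statistic_kind = statistic_kind
        self.mirna_ids = preds.mirna_ids
        self._mirna_index = {m: i for i, m in enumerate(self.mirna_ids)}
        genes = sorted(ann.universe)
        gene_index = {g: j for j, g in enumerate(genes)}
        self.term_ids = tuple(t for t in ann.term_ids if ann.terms[t] & ann.universe)
        self.term_sizes = np.array(
            [len(ann.terms[t] & ann.universe) for t in self.term_ids], dtype=np.int64
        )
        self.n_mirnas = len(self.mirna_ids)
        self.n_genes = len(genes)

        term_mask = np.zeros((len(self.term_ids), self.n_genes), dtype=bool)
        for ti, t in enumerate(self.term_ids):
            for g in ann.terms[t]:
                j = gene_index.get(g)
                if j is not None:
                    term_mask[ti, j] = True

        if statistic_kind == "multihit":
            sites = np.zeros((self.n_mirnas, self.n_genes), dtype=np.float64)
            for mi, m in enumerate(self.mirna_ids):
                for g, c in preds.sites_of(m).items():
                    j = gene_index.get(g)
                    if j is not None:
                        sites[mi, j] = c
            # per-miRNA term score and total score: the multi-hit statistic
            # is additive over the drawn miRNAs
            self._term_scores = sites @ term_mask.T
            self._row_totals = sites.sum(axis=1)
        else:
            incid = np.zeros((self.n_mirnas, self.n_genes), dtype=bool)
            for mi, m in enumerate(self.mirna_ids):
                for g in preds.targets_of(m):
                    j = gene_index.get(g)
                    if j is not None:
                        incid[mi, j] = True
            self._packed = _pack_bool_rows(incid)
            self._packed_terms = _pack_bool_rows(term_mask)

    def indices_of(self, mirnas: MiRNAList) -> np.ndarray:
        try:
            return np.array([self._mirna_index[m] for m in mirnas.names], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"miRNA {exc.args[0]!r} not in the prediction set") from exc

    def union_counts(self, subsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-term union-overlap counts and union sizes for each subset row."""
        n_sub = subsets.shape[0]
        n_terms = len(self.term_ids)
        words = self._packed.shape[1]
        counts = np.empty((n_sub, n_terms), dtype=np.int64)
        sizes = np.empty(n_sub, dtype=np.int64)
        # chunk so the (chunk, terms, words) popcount intermediate stays small
        chunk = max(1, int(4_000_000 / max(1, n_terms * words)))
        for lo in range(0, n_sub, chunk):
            hi = min(lo + chunk, n_sub)
            union = np.bitwise_or.reduce(self._packed[subsets[lo:hi]], axis=1)
            sizes[lo:hi] = np.bitwise_count(union).sum(axis=1)
            counts[lo:hi] = np.bitwise_count(
                union[:, None, :] & self._packed_terms[None, :, :]
            ).sum(axis=2)
        return counts, sizes

    def stats_for_subsets(self, subsets: np.ndarray) -> np.ndarray:
        """(n_subsets, n_terms) statistic values for index-array draws."""
        subsets = np.asarray(subsets, dtype=np.int64)
        if self.statistic_kind == "multihit":
            term_scores = self._term_scores[subsets].sum(axis=1)
            totals = self._row_totals[subsets].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                stats = np.where(totals[:, None] > 0, term_scores / totals[:, None], 0.0)
            return stats
        counts, sizes = self.union_counts(subsets)
        if self.statistic_kind == "union_count":
            return counts.astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sizes[:, None] > 0, counts / sizes[:, None], 0.0)

    def observed(self, mirnas: MiRNAList) -> np.ndarray:
        return self.stats_for_subsets(self.indices_of(mirnas)[None, :])[0]


def _draw_batch(
    seed: int, batch_index: int, batch_size: int, n_mirnas: int, list_size: int
) -> np.ndarray:
    """Uniform without-replacement subsets for one counter batch."""
    key = np.array([seed, batch_index], dtype=np.uint64)
    rng = np.random.Generator(np.random.Philox(key=key))
    u = rng.random((batch_size, n_mirnas))
    return np.argpartition(u, list_size - 1, axis=1)[:, :list_size]


def iter_null_batches(
    n_mirnas: int, list_size: int, n_iterations: int, seed: int
) -> Iterator[np.ndarray]:
    """Yield subset index arrays covering ``n_iterations`` draws.

    The draws for a given (seed, iteration index) never depend on the total
    iteration count: a longer run extends a shorter one.
    """
    if list_size < 1 or list_size > n_mirnas:
        raise ValueError(f"list_size must be in [1, {n_mirnas}], got {list_size}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    done = 0
    batch_index = 0
    while done < n_iterations:
        subsets = _draw_batch(seed, batch_index, _BATCH, n_mirnas, list_size)
        take = min(_BATCH, n_iterations - done)
        yield subsets[:take]
        done += take
        batch_index += 1


@dataclass
class NullSummary:
    """Streamed per-term summary of the resampling null distribution."""

    term_ids: tuple[str, ...]
    exceedance: np.ndarray  # draws with statistic >= observed, per term
    mean: np.ndarray
    m2: np.ndarray  # sum of squared deviations (Welford)
    n_iterations: int
    list_size: int
    seed: int
    statistic_kind: str

    @property
    def null_mean(self) -> np.ndarray:
        return self.mean

    @property
    def null_sd(self) -> np.ndarray:
        if self.n_iterations < 2:
            return np.zeros_like(self.mean)
        return np.sqrt(np.maximum(self.m2, 0.0) / (self.n_iterations - 1))

    def p_values(self, rule: str = "plain") -> np.ndarray:
        """plain: exceedance / iterations (minimum resolution 1/iterations,
        can be exactly 0); add_one: (exceedance + 1) / (iterations + 1)."""
        if rule == "plain":
            return self.exceedance / self.n_iterations
        if rule == "add_one":
            return (self.exceedance + 1) / (self.n_iterations + 1)
        raise ValueError(f"unknown p rule {rule!r}")


def _exceedance_thresholds(observed: np.ndarray, statistic_kind: str) -> np.ndarray:
    if statistic_kind == "union_count":
        return observed
    return observed * (1.0 - _TIE_RTOL)


def sample_null(
    preds: TargetPredictionSet,
    ann: AnnotationSet,
    list_size: int,
    observed: Mapping[str, float],
    n_iterations: int,
    seed: int,
    statistic_kind: str = "union_proportion",
    engine: NullEngine | None = None,
) -> NullSummary:
    """Stream the resampling null: random same-size miRNA sets drawn without
    replacement from the full miRNA universe, statistic recomputed per draw.

    Exceedance uses the inclusive "equal or greater" rule (with a 1e-12
    relative tolerance for proportion-valued statistics).  Only counts and
    running moments are retained.  Null draws may coincide with the input
    set: sampling is from all annotated miRNAs, with no exclusion.
    """
    eng = engine if engine is not None else NullEngine(preds, ann, statistic_kind)
    if eng.statistic_kind != statistic_kind:
        raise ValueError("engine statistic_kind does not match request")
    obs = np.array([observed[t] for t in eng.term_ids], dtype=np.float64)
    thr = _exceedance_thresholds(obs, statistic_kind)

    n_terms = len(eng.term_ids)
    exceed = np.zeros(n_terms, dtype=np.int64)
    mean = np.zeros(n_terms)
    m2 = np.zeros(n_terms)
    count = 0
    for subsets in iter_null_batches(eng.n_mirnas, list_size, n_iterations, seed):
        stats = eng.stats_for_subsets(subsets)
        exceed += (stats >= thr).sum(axis=0)
        b = stats.shape[0]
        b_mean = stats.mean(axis=0)
        b_m2 = ((stats - b_mean) ** 2).sum(axis=0)
        if count == 0:
            mean, m2, count = b_mean, b_m2, b
        else:
            delta = b_mean - mean
            total = count + b
            mean = mean + delta * (b / total)
            m2 = m2 + b_m2 + delta**2 * (count * b / total)
            count = total
    return NullSummary(
        term_ids=eng.term_ids,
        exceedance=exceed,
        mean=mean,
        m2=m2,
        n_iterations=n_iterations,
        list_size=list_size,
        seed=seed,
        statistic_kind=statistic_kind,
    )


def _result_table(
    eng: NullEngine,
    ann: AnnotationSet,
    observed: Mapping[str, float],
    overlap: Mapping[str, float],
    p: np.ndarray,
    null_mean: np.ndarray,
    null_sd: np.ndarray,
    method: str,
    n_iterations,
    meta: dict,
) -> EnrichmentTable:
    frame = pd.DataFrame(
        {
            "term_id": list(eng.term_ids),
            "term_name": [ann.term_names.get(t, "") for t in eng.term_ids],
            "term_size": eng.term_sizes,
            "overlap": [overlap[t] for t in eng.term_ids],
            "statistic": [observed[t] for t in eng.term_ids],
            "p_value": np.clip(p, 0.0, 1.0),
            "q_value": bh_adjust(np.clip(p, 0.0, 1.0)),
            "null_mean": null_mean,
            "null_sd": null_sd,
            "method": method,
            "n_iterations": n_iterations,
        }
    )
    return EnrichmentTable(frame=frame, meta=meta)


def _overlap_column(
    preds: TargetPredictionSet,
    ann: AnnotationSet,
    mirnas: MiRNAList,
    statistic_kind: str,
) -> dict[str, float]:
    """Raw overlap reported alongside the statistic: union-overlap count for
    union statistics, summed term site-score for the multi-hit statistic."""
    if statistic_kind == "multihit":
        scores = multihit_gene_scores(preds, mirnas, universe=ann.universe)
        return {
            t: float(sum(s for g, s in scores.scores.items() if g in ann.terms[t]))
            for t in ann.term_ids
        }
    targets = union_targets(preds, mirnas) & ann.universe
    return {t: term_overlap(targets, t, ann, mode="count") for t in ann.term_ids}


def empirical_enrichment(
    preds: TargetPredictionSet,
    ann: AnnotationSet,
    mirnas: MiRNAList,
    n_iterations: int = 1_000_000,
    seed: int = 0,
    statistic_kind: str = "union_proportion",
    p_rule: str = "plain",
) -> EnrichmentTable:
    """Empirical enrichment test: p-value per term is the proportion of
    random same-size miRNA sets with statistic equal to or greater than the
    observed one; q-values by Benjamini–Hochberg over all tested terms."""
    if p_rule not in ("plain", "add_one"):
        raise ValueError(f"unknown p rule {p_rule!r}")
    eng = NullEngine(preds, ann, statistic_kind)
    observed = observed_statistic(preds, ann, mirnas, statistic_kind)
    summary = sample_null(
        preds,
        ann,
        list_size=len(mirnas),
        observed=observed,
        n_iterations=n_iterations,
        seed=seed,
        statistic_kind=statistic_kind,
        engine=eng,
    )
    meta = {
        "method": f"empirical[{statistic_kind}]",
        "statistic_kind": statistic_kind,
        "n_iterations": n_iterations,
        "seed": seed,
        "p_rule": p_rule,
        "list_size": len(mirnas),
        "N": len(ann.universe),
    }
    return _result_table(
        eng,
        ann,
        observed,
        _overlap_column(preds, ann, mirnas, statistic_kind),
        summary.p_values(p_rule),
        summary.null_mean,
        summary.null_sd,
        meta["method"],
        n_iterations,
        meta,
    )


def exact_enumeration_enrichment(
    preds: TargetPredictionSet,
    ann: AnnotationSet,
    mirnas: MiRNAList,
    statistic_kind: str = "union_proportion",
    cap: int = 100_000,
) -> EnrichmentTable:
    """Exact version of the resampling null: enumerate every same-size miRNA
    subset.  Usable as an oracle when C(n_mirnas, list_size) is small."""
    eng = NullEngine(preds, ann, statistic_kind)
    list_size = len(mirnas)
    total = comb(eng.n_mirnas, list_size)
    if total > cap:
        raise ValueError(
            f"C({eng.n_mirnas}, {list_size}) = {total} exceeds cap {cap}; use sample_null"
        )
    observed = observed_statistic(preds, ann, mirnas, statistic_kind)
    obs = np.array([observed[t] for t in eng.term_ids])
    thr = _exceedance_thresholds(obs, statistic_kind)

    exceed = np.zeros(len(eng.term_ids), dtype=np.int64)
    sum_ = np.zeros(len(eng.term_ids))
    sum_sq = np.zeros(len(eng.term_ids))
    buffer: list[tuple[int, ...]] = []

    def flush() -> None:
        nonlocal exceed, sum_, sum_sq
        if not buffer:
            return
        stats = eng.stats_for_subsets(np.array(buffer, dtype=np.int64))
        exceed += (stats >= thr).sum(axis=0)
        sum_ += stats.sum(axis=0)
        sum_sq += (stats**2).sum(axis=0)
        buffer.clear()

    for subset in combinations(range(eng.n_mirnas), list_size):
        buffer.append(subset)
        if len(buffer) >= 4096:
            flush()
    flush()

    p = exceed / total
    null_mean = sum_ / total
    null_var = np.maximum(sum_sq / total - null_mean**2, 0.0)
    meta = {
        "method": f"exact_enumeration[{statistic_kind}]",
        "statistic_kind": statistic_kind,
        "n_subsets": total,
        "list_size": list_size,
    }
    return _result_table(
        eng,
        ann,
        observed,
        _overlap_column(preds, ann, mirnas, statistic_kind),
        p,
        null_mean,
        np.sqrt(null_var),
        meta["method"],
        float("nan"),
        meta,
    )
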