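"""The standard over-representation test and shared result containers.

The standard method forms the union of predicted target genes for the input
miRNA list and tests each term with the one-sided hypergeometric tail
P(X >= k) for X ~ Hypergeometric(N, K, n) — equivalently a one-sided
Fisher's exact test on the 2x2 table — over the annotated-gene universe.
Benjamini–Hochberg adjustment is shared by every method in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import AnnotationSet, HypergeomParams, MiRNAList, TargetPredictionSet, union_targets

__all__ = ["EnrichmentTable", "hypergeom_sf", "bh_adjust", "standard_enrichment"]

#: fixed column order of the serialized table
TABLE_COLUMNS = [
    "term_id",
    "term_name",
    "term_size",
    "overlap",
    "statistic",
    "p_value",
    "q_value",
    "null_mean",
    "null_sd",
    "method",
    "n_iterations",
]


@dataclass
class EnrichmentTable:
    """Per-term enrichment results plus run metadata.

    One row per tested term.  ``overlap`` is the union-overlap count (or the
    term site-score for the multi-hit statistic), ``statistic`` the value the
    p-value was computed from, ``null_mean``/``null_sd`` the first two
    moments of the null distribution of that statistic.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"EnrichmentTable missing columns: {missing}")
        self.frame = self.frame[TABLE_COLUMNS].reset_index(drop=True)
        p, q = self.frame["p_value"], self.frame["q_value"]
        if ((p < 0) | (p > 1)).any() or ((q < 0) | (q > 1)).any():
            raise ValueError("p and q values must lie in [0, 1]")

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.frame[self.frame["q_value"] < fdr].reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.12g", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnrichmentTable":
        frame = pd.read_csv(path, sep="\t")
        frame["term_name"] = frame["term_name"].fillna("")
        return cls(frame=frame)


def hypergeom_sf(params: HypergeomParams) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    The inclusive upper tail is the one-sided enrichment p-value and equals
    the one-sided Fisher's exact test on the corresponding 2x2 table.
    """
    # params validation enforces 0 <= k <= min(n, K) <= N
    return float(hypergeom.sf(params.k - 1, params.N, params.K, params.n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j >= i} (p_(j) * m / j), clipped to 1; thresholding the
    result at alpha reproduces the BH step-up rejection set at FDR alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def standard_enrichment(
    preds: TargetPredictionSet,
    ann: AnnotationSet,
    mirnas: MiRNAList,
    min_term_size: int = 0,
) -> EnrichmentTable:
    """Hypergeometric over-representation test on the union target set.

    n is the union of predicted targets intersected with the annotation
    universe; for each term, k is the overlap count and K the term size in
    the universe.  Terms with K = 0 (or below ``min_term_size``) are dropped
    rather than reported at p = 1, so untestable hypotheses do not inflate
    the BH denominator.
    """
    if not ann.universe:
        raise ValueError("annotation universe is empty")
    targets = union_targets(preds, mirnas) & ann.universe
    n = len(targets)
    if n == 0:
        raise ValueError("no predicted target gene falls in the annotation universe")
    N = len(ann.universe)

    rows = []
    for term_id in ann.term_ids:
        term_genes = ann.terms[term_id] & ann.universe
        K = len(term_genes)
        if K == 0:
            warnings.warn(f"dropping term {term_id!r}: no member gene in universe")
            continue
        if K < min_term_size:
            continue
        k = len(targets & term_genes)
        rows.append((term_id, K, k))
    if not rows:
        raise ValueError("no testable term")

    term_ids = [r[0] for r in rows]
    K_arr = np.array([r[1] for r in rows])
    k_arr = np.array([r[2] for r in rows])
    p = hypergeom.sf(k_arr - 1, N, K_arr, n)
    q = bh_adjust(p)
    frame = pd.DataFrame(
        {
            "term_id": term_ids,
            "term_name": [ann.term_names.get(t, "") for t in term_ids],
            "term_size": K_arr,
            "overlap": k_arr,
            "statistic": k_arr.astype(float),
            "p_value": np.clip(p, 0.0, 1.0),
            "q_value": q,
            "null_mean": n * K_arr / N,
            "null_sd": np.sqrt(n * (K_arr / N) * (1 - K_arr / N) * (N - n) / max(N - 1, 1)),
            "method": "hypergeometric",
            "n_iterations": np.nan,
        }
    )
    meta = {"method": "hypergeometric", "n": n, "N": N, "list_size": len(mirnas)}
    return EnrichmentTable(frame=frame, meta=meta)
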