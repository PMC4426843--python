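"""Synthetic miRNA-target universes with covariate-driven targeting bias.

The generator emulates the structure that breaks the hypergeometric null in
real prediction data: genes carry a 3' UTR-length-like covariate, and the
per-(miRNA, gene) predicted-site count is Poisson with mean

    base_rate * mirna_factor(m) * covariate(g) ** bias_strength

so that with ``bias_strength > 0`` long-covariate genes are targeted more
often by *every* miRNA, exactly the kind of shared, list-independent bias
that inflates the standard test.  Terms are gene subsets sampled with
replacement from the gene pool (so genes carry several annotations, GO
fashion); planted biased terms draw their genes with weight
``covariate ** beta``, making them systematically over- (beta > 0) or
under-targeted (beta < 0).  An optional spike boosts a handful of miRNAs'
targeting of one term to provide a true positive.

The covariate is dimensionless relative UTR length (log-normal, median 1).
All randomness flows from a single seed; a given config is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .core import AnnotationSet, MiRNAList, TargetPredictionSet
from .io import write_annotations_gmt, write_predictions

__all__ = [
    "SyntheticConfig",
    "generate_dataset",
    "spike_in_list",
    "write_dataset",
    "load_config",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a biased miRNA-target universe.

    Defaults describe a desk-scale universe (200 miRNAs x 3000 genes x 100
    terms) with moderate covariate-driven bias and ten planted biased terms
    (five over-, five under-targeted); ``unbiased()`` switches all bias off.
    """

    n_genes: int = 3000
    n_mirnas: int = 200
    n_terms: int = 100
    term_size_min: int = 10
    term_size_max: int = 150
    #: planted biased terms are drawn at least this large, so the planted
    #: diagnostics measure bias strength rather than term-size noise
    planted_term_size_min: int = 50
    covariate_log_mean: float = 0.0
    covariate_log_sd: float = 0.8
    base_rate: float = 0.05
    mirna_rate_log_sd: float = 0.5
    bias_strength: float = 1.0
    #: (term index, covariate-weight exponent) for planted biased terms
    term_bias_spec: tuple[tuple[int, float], ...] = (
        (0, 2.0), (1, 2.0), (2, 2.0), (3, 2.0), (4, 2.0),
        (5, -2.0), (6, -2.0), (7, -2.0), (8, -2.0), (9, -2.0),
    )
    #: optional (term index, n miRNAs, rate multiplier) true-positive spike
    spike_spec: tuple[int, int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_terms", "term_size_min", "term_size_max"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.term_size_min > self.term_size_max:
            raise ValueError("term_size_min must not exceed term_size_max")
        if self.planted_term_size_min > self.term_size_max:
            raise ValueError("planted_term_size_min must not exceed term_size_max")
        if self.term_size_max > self.n_genes:
            raise ValueError("term_size_max exceeds the number of genes")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if self.covariate_log_sd < 0 or self.mirna_rate_log_sd < 0:
            raise ValueError("scale parameters must be non-negative")
        for idx, _ in self.term_bias_spec:
            if not (0 <= idx < self.n_terms):
                raise ValueError(f"term_bias_spec index {idx} out of range")
        if self.spike_spec is not None:
            t, n, boost = self.spike_spec
            if not (0 <= t < self.n_terms):
                raise ValueError("spike term index out of range")
            if not (1 <= n <= self.n_mirnas):
                raise ValueError("spike size out of range")
            if boost <= 0:
                raise ValueError("spike boost must be positive")

    @classmethod
    def unbiased(cls, **kwargs) -> "SyntheticConfig":
        """Uniform-targeting control: no covariate effect, no planted terms."""
        return cls(bias_strength=0.0, term_bias_spec=(), **kwargs)

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)

    def biased_term_ids(self) -> dict[str, float]:
        return {_term_id(i, self.n_terms): beta for i, beta in self.term_bias_spec}


def _term_id(i: int, n_terms: int) -> str:
    width = max(3, len(str(n_terms - 1)))
    return f"T{i:0{width}d}"


def generate_dataset(
    config: SyntheticConfig, return_details: bool = False
) -> tuple[TargetPredictionSet, AnnotationSet, dict[str, float]] | tuple:
    """Draw one synthetic universe: predictions, annotations, covariate.

    With ``return_details=True`` a fourth dict is returned carrying the
    per-miRNA rate factors, the spiked miRNA names and the analytic expected
    target count per miRNA (sum over genes of P(site count >= 1)), for use
    in distribution checks.
    """
    rng = np.random.default_rng(config.seed)
    G, M, T = config.n_genes, config.n_mirnas, config.n_terms

    gene_ids = [f"g{j:05d}" for j in range(G)]
    mirna_ids = [f"mir-{i:04d}" for i in range(M)]

    cov = rng.lognormal(mean=config.covariate_log_mean, sigma=config.covariate_log_sd, size=G)
    # per-miRNA propensity, log-normal with unit mean
    s = config.mirna_rate_log_sd
    factors = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=M)

    log_lo, log_hi = np.log(config.term_size_min), np.log(config.term_size_max + 1)
    sizes = np.minimum(
        np.floor(np.exp(rng.uniform(log_lo, log_hi, size=T))).astype(int),
        config.term_size_max,
    )
    betas = dict(config.term_bias_spec)
    planted = set(betas)
    if config.spike_spec is not None:
        planted.add(config.spike_spec[0])
    for t in planted:
        sizes[t] = max(sizes[t], config.planted_term_size_min)
    terms: dict[str, frozenset[str]] = {}
    term_names: dict[str, str] = {}
    for t in range(T):
        beta = betas.get(t, 0.0)
        if beta == 0.0:
            members = rng.choice(G, size=sizes[t], replace=False)
        else:
            w = cov**beta
            members = rng.choice(G, size=sizes[t], replace=False, p=w / w.sum())
        tid = _term_id(t, T)
        terms[tid] = frozenset(gene_ids[j] for j in members)
        label = "planted" if beta else "background"
        term_names[tid] = f"synthetic process {t} ({label})"

    lam = config.base_rate * factors[:, None] * cov[None, :] ** config.bias_strength
    spiked: list[str] = []
    if config.spike_spec is not None:
        t_idx, n_spike, boost = config.spike_spec
        spike_rows = rng.choice(M, size=n_spike, replace=False)
        term_cols = np.array(
            sorted(gene_ids.index(g) for g in terms[_term_id(t_idx, T)]), dtype=int
        )
        lam[np.ix_(spike_rows, term_cols)] *= boost
        spiked = sorted(mirna_ids[i] for i in spike_rows)

    sites = rng.poisson(lam)
    rows, cols = np.nonzero(sites)
    preds = TargetPredictionSet(
        {(mirna_ids[i], gene_ids[j]): int(sites[i, j]) for i, j in zip(rows, cols)}
    )
    ann = AnnotationSet(terms, universe=None, term_names=term_names)
    covariate = dict(zip(gene_ids, cov.tolist()))
    if not return_details:
        return preds, ann, covariate
    details = {
        "mirna_factors": dict(zip(mirna_ids, factors.tolist())),
        "spiked_mirnas": spiked,
        "expected_targets": dict(zip(mirna_ids, (1.0 - np.exp(-lam)).sum(axis=1).tolist())),
    }
    return preds, ann, covariate, details


def spike_in_list(
    preds: TargetPredictionSet,
    ann: AnnotationSet,
    term_id: str,
    n_mirnas: int,
) -> MiRNAList:
    """The n miRNAs with the most predicted targets inside one term.

    This mimics hand-selecting an input set known to converge on a process;
    ties are broken lexicographically.  miRNAs with zero targets in the term
    fill the list (lexicographically) when fewer than n target it at all.
    """
    if term_id not in ann.terms:
        raise KeyError(f"unknown term id: {term_id!r}")
    if not (1 <= n_mirnas <= len(preds.mirna_ids)):
        raise ValueError(f"n_mirnas must be in [1, {len(preds.mirna_ids)}]")
    term_genes = ann.terms[term_id]
    ranked = sorted(
        preds.mirna_ids, key=lambda m: (-len(preds.targets_of(m) & term_genes), m)
    )
    return MiRNAList(names=tuple(ranked[:n_mirnas]))


def write_dataset(
    preds: TargetPredictionSet,
    ann: AnnotationSet,
    covariate: Mapping[str, float],
    out_dir: str | Path,
    config: SyntheticConfig | None = None,
) -> dict[str, Path]:
    """Emit the standard on-disk forms: prediction TSV, GMT, covariate TSV
    and (optionally) the generating config as YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "predictions": out / "predictions.tsv",
        "annotations": out / "annotations.gmt",
        "covariate": out / "covariate.tsv",
    }
    write_predictions(preds, paths["predictions"])
    write_annotations_gmt(ann, paths["annotations"])
    with open(paths["covariate"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tcovariate\n")
        for g in sorted(covariate):
            fh.write(f"{g}\t{covariate[g]:.10g}\n")
    if config is not None:
        paths["config"] = out / "config.yaml"
        data = asdict(config)
        data["term_bias_spec"] = [list(t) for t in config.term_bias_spec]
        data["spike_spec"] = list(config.spike_spec) if config.spike_spec else None
        with open(paths["config"], "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
    return paths


def load_config(path: str | Path) -> SyntheticConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    data["term_bias_spec"] = tuple(tuple(t) for t in data.get("term_bias_spec") or ())
    spike = data.get("spike_spec")
    data["spike_spec"] = tuple(spike) if spike else None
    return SyntheticConfig(**data)
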