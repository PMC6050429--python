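"""Downstream RNA-seq expression statistics.

Implements the quality/normalisation/testing arithmetic used on the
treated-vs-untreated expression data: Phred quality scores, read-level
filters, RPKM normalisation, Benjamini–Hochberg FDR adjustment,
differential-expression calling at q < 0.01, and one-sided hypergeometric
gene-set enrichment.  Upstream differential-expression p-values are taken
as input — read alignment and the DE tools themselves are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reaction_network import DomainError, StructuralError

__all__ = [
    "ReadRecord",
    "CountTable",
    "DegCall",
    "EnrichmentResult",
    "FilterSummary",
    "phred_q",
    "filter_reads",
    "rpkm",
    "bh_adjust",
    "call_degs",
    "hypergeom_enrichment",
    "read_gmt",
]


@dataclass
class ReadRecord:
    """One sequencing read, reduced to what the filters need."""

    id: str
    qualities: Sequence[int]  # per-base Phred scores
    fraction_N: float = 0.0
    has_adapter: bool = False

    def __post_init__(self):
        if not 0.0 <= self.fraction_N <= 1.0:
            raise DomainError(f"read {self.id!r}: fraction_N {self.fraction_N} not in [0, 1]")


@dataclass
class CountTable:
    """Gene × sample counts with gene lengths (kb) and mapped totals (millions)."""

    gene_ids: list
    length_kb: np.ndarray  # per gene
    counts: np.ndarray  # genes × samples
    mapped_millions: np.ndarray  # per sample
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.length_kb = np.asarray(self.length_kb, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.mapped_millions = np.asarray(self.mapped_millions, dtype=float)
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.counts.shape[1])]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise StructuralError("duplicate gene ids in count table")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise StructuralError("counts shape does not match gene/sample ids")
        if (self.counts < 0).any():
            raise DomainError("negative counts")
        if (self.length_kb <= 0).any():
            raise DomainError("gene lengths must be positive")
        if (self.mapped_millions <= 0).any():
            raise DomainError("mapped-read totals must be positive")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)
        df.insert(0, "length_kb", self.length_kb)
        return df


@dataclass
class DegCall:
    gene_id: str
    log2_fold_change: float
    p_value: float
    q_value: float
    direction: str  # "up" | "down" | "none"


@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # list genes in term
    K: int  # term size
    n: int  # list size
    N: int  # background size
    p_value: float
    q_value: float = float("nan")


@dataclass
class FilterSummary:
    kept: list
    n_input: int
    discarded_adapter: int
    discarded_n_fraction: int
    discarded_low_quality: int


# ---------------------------------------------------------------------------
# Quality and filtering
# ---------------------------------------------------------------------------

def phred_q(error_rate: float, log_base: float = 10.0) -> float:
    """Phred quality score Q = −10·log_base(E) for base-call error rate E.

    Base 10 is the Phred standard (E=0.01 → Q20); base 2 is available for
    compatibility with sources that print the formula that way.
    """
    if not 0.0 < error_rate <= 1.0:
        raise DomainError(f"error rate {error_rate} outside (0, 1]")
    return -10.0 * math.log(error_rate, log_base)


def filter_reads(
    reads: Iterable[ReadRecord],
    max_N_frac: float = 0.20,
    low_q_threshold: float = 20.0,
    max_low_q_frac: float = 0.50,
) -> FilterSummary:
    """Apply the three standard read filters and count discards per rule.

    A read is discarded if it (1) carries adapter sequence, (2) has more
    than ``max_N_frac`` N bases, or (3) has more than ``max_low_q_frac`` of
    its bases below Phred ``low_q_threshold``.  Rules are checked in that
    order; each read is charged to the first rule it violates.
    """
    if not 0.0 <= max_N_frac <= 1.0 or not 0.0 <= max_low_q_frac <= 1.0:
        raise DomainError("fraction thresholds must lie in [0, 1]")
    kept = []
    n_in = n_ad = n_nf = n_lq = 0
    for read in reads:
        n_in += 1
        if read.has_adapter:
            n_ad += 1
            continue
        if read.fraction_N > max_N_frac:
            n_nf += 1
            continue
        quals = np.asarray(read.qualities, dtype=float)
        if quals.size and (quals < low_q_threshold).mean() > max_low_q_frac:
            n_lq += 1
            continue
        kept.append(read)
    return FilterSummary(
        kept=kept,
        n_input=n_in,
        discarded_adapter=n_ad,
        discarded_n_fraction=n_nf,
        discarded_low_quality=n_lq,
    )


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def rpkm(table: CountTable) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM[g, s] = counts[g, s] / (mapped_millions[s] · length_kb[g]).
    """
    mat = table.counts / (table.mapped_millions[None, :] * table.length_kb[:, None])
    return pd.DataFrame(mat, index=table.gene_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Multiple testing and DEG calling
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j ≥ i} ( m·p_(j) / j ), capped at 1, returned in the
    original input order.  Handles ties and unsorted input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise DomainError("pvalues must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_degs(
    stats_table: Mapping[str, tuple] | pd.DataFrame,
    q_threshold: float = 0.01,
) -> list:
    """Call differentially expressed genes at a BH q-value threshold.

    ``stats_table`` maps gene id → (log2 fold change, p-value), or is a
    DataFrame with columns ``log2_fold_change`` and ``p_value`` indexed by
    gene.  p-values are BH-adjusted across all genes; a gene is "up" if
    q < threshold and its fold change is positive in log2 (ratio > 1),
    "down" if q < threshold and negative, else "none".
    """
    if isinstance(stats_table, pd.DataFrame):
        genes = list(stats_table.index)
        lfc = stats_table["log2_fold_change"].to_numpy(dtype=float)
        pvals = stats_table["p_value"].to_numpy(dtype=float)
    else:
        genes = list(stats_table)
        lfc = np.array([stats_table[g][0] for g in genes], dtype=float)
        pvals = np.array([stats_table[g][1] for g in genes], dtype=float)
    if len(set(genes)) != len(genes):
        raise StructuralError("duplicate gene ids")
    qvals = bh_adjust(pvals) if len(genes) else np.array([])
    calls = []
    for g, fc, p, q in zip(genes, lfc, pvals, qvals):
        if q < q_threshold and fc > 0:
            direction = "up"
        elif q < q_threshold and fc < 0:
            direction = "down"
        else:
            direction = "none"
        calls.append(DegCall(g, float(fc), float(p), float(q), direction))
    return calls


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrichment(
    gene_list: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> list:
    """Upper-tail hypergeometric enrichment of each term in a gene list.

    For a term with K members in a background of N genes and a list of n
    genes of which k are members, p = P(X ≥ k) for X ~ Hypergeom(N, K, n).
    q-values are BH-adjusted across terms.  Results are sorted by p.
    """
    bg = set(background)
    lst = set(gene_list)
    missing = lst - bg
    if missing:
        raise StructuralError(
            f"{len(missing)} list genes absent from background, e.g. {sorted(missing)[:3]}"
        )
    N, n = len(bg), len(lst)
    results = []
    for term, members in gene_sets.items():
        mem = set(members)
        extra = mem - bg
        if extra:
            raise StructuralError(
                f"term {term!r}: {len(extra)} members absent from background"
            )
        K = len(mem)
        k = len(mem & lst)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        results.append(EnrichmentResult(term_id=term, k=k, K=K, n=n, N=N, p_value=p))
    qvals = bh_adjust([r.p_value for r in results]) if results else []
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def read_gmt(path) -> dict:
    """Parse a GMT gene-set file: term <tab> description <tab> genes..."""
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets
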