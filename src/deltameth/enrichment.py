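"""Hypergeometric over-representation testing with Benjamini–Hochberg FDR.

Given a selected gene set (e.g. the hypermethylated DMGs), a universe (the
genes measurable on the array after filtering), and a collection of terms,
each term is tested for over-representation with the upper-tail
hypergeometric probability

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the universe size, K the term size within the universe, n the
selected-set size, and k the observed overlap. The tail sum is accumulated
in log space so small p-values remain accurate. Adjusted p-values use the
Benjamini–Hochberg step-up over ALL tested terms, including those whose
overlap is zero (dropping them from the family would inflate significance);
zero-overlap terms are simply omitted from the output rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp


def _log_comb(a: np.ndarray | int, b: np.ndarray | int) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n), computed in log space.

    N: universe size, K: marked items, n: draws, k: observed marked draws.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k <= max(0, n + K - N):
        return 1.0  # support starts at max(0, n+K-N): the event is certain
    j = np.arange(k, min(K, n) + 1)
    log_terms = _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    adjusted_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1, over the
    ascending order statistics p_(1) <= ... <= p_(m).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's contingency counts and (adjusted) p-value."""

    term_id: str
    description: str
    universe_size: int
    term_size: int
    selected_size: int
    overlap: int
    p_value: float
    fdr_adjusted_p: float


def enrich(
    selected_genes: Sequence[str],
    terms: Mapping[str, tuple[str, Sequence[str]]],
    universe: Sequence[str],
    fdr_threshold: float = 0.05,
) -> tuple[list[EnrichmentRow], list[EnrichmentRow]]:
    """Test every term for over-representation of ``selected_genes``.

    Terms are intersected with the universe before testing; terms empty in
    the universe are skipped entirely, terms with zero overlap count toward
    the BH family but produce no output row. Returns ``(all_rows,
    significant_rows)``, both sorted by p-value then term id; the second is
    the adjusted-p < ``fdr_threshold`` view.
    """
    universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise ValueError("empty gene universe")
    selected = {g.upper() for g in selected_genes}
    if not selected <= universe_set:
        missing = sorted(selected - universe_set)[:3]
        raise ValueError(f"selected genes outside universe, e.g. {missing}")
    N, n = len(universe_set), len(selected)

    tested: list[tuple[str, str, int, int]] = []  # term, desc, K, k
    for term_id, (description, genes) in terms.items():
        term_genes = {g.upper() for g in genes} & universe_set
        if not term_genes:
            continue
        tested.append(
            (term_id, description, len(term_genes), len(term_genes & selected))
        )
    if not tested:
        return [], []
    p_values = [hypergeom_upper_tail(N, K, n, k) for _, _, K, k in tested]
    adjusted = bh_adjust(p_values)

    rows = [
        EnrichmentRow(
            term_id=term_id,
            description=description,
            universe_size=N,
            term_size=K,
            selected_size=n,
            overlap=k,
            p_value=p,
            fdr_adjusted_p=float(q),
        )
        for (term_id, description, K, k), p, q in zip(tested, p_values, adjusted)
        if k >= 1
    ]
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    significant = [r for r in rows if r.fdr_adjusted_p < fdr_threshold]
    return rows, significant


def enrichment_to_frame(rows: Sequence[EnrichmentRow]):
    """Flatten enrichment rows to the output TSV schema."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "description": r.description,
                "universe_size": r.universe_size,
                "term_size": r.term_size,
                "selected_size": r.selected_size,
                "overlap": r.overlap,
                "p_value": r.p_value,
                "fdr_adjusted_p": r.fdr_adjusted_p,
            }
            for r in rows
        ],
        columns=[
            "term_id", "description", "universe_size", "term_size",
            "selected_size", "overlap", "p_value", "fdr_adjusted_p",
        ],
    )
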