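"""Downstream statistics: binomial over-representation, BH-FDR, and exact
2x2 tests for experimental outcome counts.

The over-representation test is the classic binomial gene-set test over a
user-supplied gene-to-term annotation table: with K of N background genes
annotated to a term and k of s study genes observed, the one-sided p-value
is the upper binomial tail P(X >= k), X ~ Binomial(s, K/N); q-values are
Benjamini-Hochberg across the tested terms.

Boschloo's exact test treats Fisher's one-sided p-value as the test
statistic and maximizes, over a common nuisance proportion, the exact
probability of a statistic at least as extreme.  The convention here
mirrors the widely used SciPy implementation applied to a rows-as-groups
table ``[[a, m-a], [b, n-b]]``: the pair of unconditional binomials is
taken over the table's *columns* (the outcome margin), and the two-tailed
p-value is twice the smaller one-sided value, capped at 1.  A test pins
this equivalence against ``scipy.stats.boschloo_exact``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationTable",
    "binomial_enrichment",
    "bh_fdr",
    "boschloo_objective",
    "boschloo_one_sided",
    "boschloo_two_tailed",
    "mann_whitney_u_two_tailed",
]


# --------------------------------------------------------------------------
# enrichment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationTable:
    """gene -> term annotations over an explicit background gene set."""

    gene_to_terms: Mapping[str, frozenset[str]]
    background: frozenset[str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   background: Iterable[str]) -> "AnnotationTable":
        background = frozenset(background)
        g2t: dict[str, set[str]] = {}
        for gene, term in pairs:
            if gene not in background:
                raise ValueError(
                    f"annotated gene {gene!r} missing from background")
            g2t.setdefault(gene, set()).add(term)
        return cls({g: frozenset(t) for g, t in g2t.items()}, background)

    @classmethod
    def read_tsv(cls, path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"gene_id", "term_id"}.issubset(df.columns):
            raise ValueError("annotation TSV needs gene_id and term_id")
        pairs = list(df[["gene_id", "term_id"]].itertuples(index=False,
                                                           name=None))
        background = {g for g, _ in pairs}
        return cls.from_pairs(pairs, background)

    def term_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, terms in self.gene_to_terms.items():
            for t in terms:
                out.setdefault(t, set()).add(gene)
        return out


def binomial_enrichment(study_genes: Iterable[str],
                        table: AnnotationTable) -> pd.DataFrame:
    """One-sided binomial over-representation of each annotated term.

    Returns a DataFrame with columns term_id, n_background, observed,
    expected, fold, p, q sorted by p ascending (ties by term_id).
    """
    study = set(study_genes)
    if not study:
        raise ValueError("study set is empty")
    extra = study - table.background
    if extra:
        raise ValueError(
            f"study genes missing from background: {sorted(extra)[:5]}")
    n_total = len(table.background)
    s = len(study)
    rows = []
    for term, genes in sorted(table.term_genes().items()):
        big_k = len(genes)
        k = len(genes & study)
        expected = s * big_k / n_total
        fold = k / expected if expected > 0 else float("nan")
        p = float(sps.binom.sf(k - 1, s, big_k / n_total))
        rows.append((term, big_k, k, expected, fold, p))
    df = pd.DataFrame(rows, columns=["term_id", "n_background", "observed",
                                     "expected", "fold", "p"])
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df.sort_values(["p", "term_id"], kind="stable",
                          ignore_index=True)


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order preserved vs input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# exact 2x2 tests
# --------------------------------------------------------------------------

def _boschloo_statistic_mask(a: int, m: int, b: int, n: int,
                             alternative: str
                             ) -> tuple[float, np.ndarray, int, int]:
    """Fisher statistic and the set of at-least-as-extreme outcomes.

    ``alternative='greater'`` tests success-rate(group 1) > rate(group 2)
    for the table [[a, m-a], [b, n-b]].  The unconditional binomials run
    over the outcome margin: X1 ~ Binom(c1, pi) successes in column 1
    (c1 = a + b) and X2 ~ Binom(c2, pi) in column 2.
    """
    c1, c2 = a + b, (m - a) + (n - b)
    tot = c1 + c2
    x1 = np.arange(c1 + 1)[None, :]
    x2 = np.arange(c2 + 1)[:, None]
    s = x1 + x2
    if alternative == "less":
        pv = sps.hypergeom.cdf(x1, tot, s, c1).T
    elif alternative == "greater":
        pv = sps.hypergeom.cdf(x2, tot, s, c2).T
    else:
        raise ValueError(f"bad alternative {alternative!r}")
    stat = float(pv[a, m - a])
    # small relative guard against floating error in the statistic ordering
    mask = pv <= stat * (1 + 1e-13)
    return stat, mask, c1, c2


def boschloo_objective(a: int, m: int, b: int, n: int, alternative: str,
                       pis: np.ndarray) -> np.ndarray:
    """P(Fisher p <= observed) under the nuisance proportion, per pi.

    The quantity Boschloo's test maximizes; exposed so independent
    enumeration oracles can probe it point by point.
    """
    _, mask, c1, c2 = _boschloo_statistic_mask(a, m, b, n, alternative)
    pis = np.asarray(pis, dtype=float)
    pmf1 = sps.binom.pmf(np.arange(c1 + 1)[None, :], c1, pis[:, None])
    pmf2 = sps.binom.pmf(np.arange(c2 + 1)[None, :], c2, pis[:, None])
    inner = mask @ pmf2.T            # (c1+1, n_pi)
    return np.einsum("gi,ig->g", pmf1, inner)


def _boschloo_one_sided_grid(a: int, m: int, b: int, n: int,
                             alternative: str,
                             grid_points: int) -> tuple[float, float]:
    """One-sided Boschloo p (grid max + local refinement) and statistic."""
    stat, _, _, _ = _boschloo_statistic_mask(a, m, b, n, alternative)
    pis = np.linspace(0.0, 1.0, grid_points + 2)[1:-1]
    vals = boschloo_objective(a, m, b, n, alternative, pis)
    best = int(np.argmax(vals))
    lo = pis[max(best - 1, 0)]
    hi = pis[min(best + 1, pis.size - 1)]
    refined = boschloo_objective(a, m, b, n, alternative,
                                 np.linspace(lo, hi, 201))
    p = float(min(1.0, max(vals.max(), refined.max())))
    return p, stat


def boschloo_one_sided(a: int, m: int, b: int, n: int,
                       alternative: str = "greater",
                       grid_points: int = 999) -> float:
    """One-sided Boschloo exact p for counts a/m vs b/n."""
    _validate_counts(a, m, b, n)
    p, _ = _boschloo_one_sided_grid(a, m, b, n, alternative, grid_points)
    return p


def boschloo_two_tailed(a: int, m: int, b: int, n: int,
                        grid_points: int = 999) -> float:
    """Two-tailed Boschloo exact p: twice the smaller one-sided, capped at 1.

    ``a`` successes of ``m`` trials in group 1 vs ``b`` of ``n`` in group 2.
    """
    _validate_counts(a, m, b, n)
    pg, _ = _boschloo_one_sided_grid(a, m, b, n, "greater", grid_points)
    pl, _ = _boschloo_one_sided_grid(a, m, b, n, "less", grid_points)
    return float(min(1.0, 2.0 * min(pg, pl)))


def _validate_counts(a: int, m: int, b: int, n: int) -> None:
    if m < 1 or n < 1:
        raise ValueError("group sizes m and n must be >= 1")
    if not (0 <= a <= m and 0 <= b <= n):
        raise ValueError("need 0 <= a <= m and 0 <= b <= n")


def fisher_one_sided(a: int, m: int, b: int, n: int,
                     alternative: str = "greater") -> float:
    """Fisher's exact one-sided p for the table [[a, m-a], [b, n-b]]."""
    _validate_counts(a, m, b, n)
    return float(sps.fisher_exact([[a, m - a], [b, n - b]],
                                  alternative=alternative)[1])


def mann_whitney_u_two_tailed(x: Sequence[float],
                              y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Exact enumeration of the permutation null when there are no ties and
    the pooled size is at most 20; otherwise the normal approximation with
    tie and continuity corrections.
    Returns ``(U, p)`` with U computed for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and pooled.size <= 20) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)
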