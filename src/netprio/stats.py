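"""Exact overlap and over-representation statistics.

The central question — "is the overlap between a compound's predicted
targets and a disease gene set larger than chance?" — is answered with a
one-sided (upper-tail) hypergeometric test: draw K genes from a universe
of N containing M annotated successes and ask for P(X >= x).  The tail is
evaluated in log space through log-gamma binomial coefficients so that it
stays accurate for universes of ~2e4 genes and p-values far below the
double-precision underflow threshold.

Generic gene-set over-representation analysis (ORA) applies the same tail
test to each set of a GMT collection, followed by Benjamini-Hochberg
step-up control of the false discovery rate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .graph_io import GeneList, normalize_symbol

__all__ = [
    "OverlapTestResult",
    "hypergeom_tail",
    "hypergeom_tail_p",
    "overlap_test",
    "ora_enrich",
    "bh_adjust",
    "read_gmt",
    "write_gmt",
]


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(N: int, K: int, M: int, x: int) -> float:
    """Natural log of P(X >= x) for X ~ Hypergeometric(N, M, K).

    Computed as a log-sum-exp over the log-gamma form of the pmf,
    sum_{j=x}^{min(K,M)} C(M, j) C(N-M, K-j) / C(N, K), which is stable
    for N ~ 2e4 and tails far smaller than the smallest positive double.
    Returns 0.0 (log of 1) when x <= 0 and -inf when x > min(K, M).
    """
    if N < 0 or not (0 <= K <= N) or not (0 <= M <= N):
        raise ValueError(f"require 0 <= K, M <= N; got N={N}, K={K}, M={M}")
    upper = min(K, M)
    if x <= 0:
        return 0.0
    if x > upper:
        return -math.inf
    j = np.arange(x, upper + 1, dtype=float)
    log_pmf = _log_binom(M, j) + _log_binom(N - M, K - j) - _log_binom(N, np.array(K, dtype=float))
    peak = log_pmf.max()
    return float(min(0.0, peak + math.log(np.exp(log_pmf - peak).sum())))


def hypergeom_tail_p(N: int, K: int, M: int, x: int) -> float:
    """Linear-scale convenience wrapper around :func:`hypergeom_tail`."""
    return math.exp(hypergeom_tail(N, K, M, x))


@dataclass(frozen=True)
class OverlapTestResult:
    """Outcome of a one-sided hypergeometric overlap test.

    The tail probability is stored on the natural-log scale so that
    extreme significance does not underflow.
    """

    universe_N: int
    draws_K: int
    successes_M: int
    observed_x: int
    log_p: float

    @property
    def expected(self) -> float:
        return self.draws_K * self.successes_M / self.universe_N

    @property
    def p_tail(self) -> float:
        return math.exp(self.log_p)

    @property
    def log10_p(self) -> float:
        return self.log_p / math.log(10.0)

    def to_dict(self) -> dict:
        return {
            "universe_N": self.universe_N,
            "draws_K": self.draws_K,
            "successes_M": self.successes_M,
            "observed_x": self.observed_x,
            "expected": self.expected,
            "log10_p": self.log10_p,
            "p_tail": self.p_tail,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def overlap_test(a: GeneList, b: GeneList, universe_N: int) -> OverlapTestResult:
    """Test whether two gene lists overlap more than chance in a universe
    of ``universe_N`` symbols.  The universe size is a required, explicit
    input: it determines the null and silently defaulting it is the main
    way this test gets misused."""
    x = len(a.as_set & b.as_set)
    union = len(a.as_set | b.as_set)
    if universe_N < union:
        raise ValueError(
            f"universe_N={universe_N} smaller than the union of the lists ({union})"
        )
    return OverlapTestResult(
        universe_N=universe_N,
        draws_K=len(a),
        successes_M=len(b),
        observed_x=x,
        log_p=hypergeom_tail(universe_N, len(a), len(b), x),
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg and ORA
# ---------------------------------------------------------------------------

def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1, original order."""
    p = np.asarray(list(pvals), dtype=float)
    m = len(p)
    if m == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def ora_enrich(
    query: GeneList,
    collection: Mapping[str, Iterable[str]],
    universe: GeneList,
) -> pd.DataFrame:
    """Over-representation analysis of ``query`` against a GMT collection.

    Each set is restricted to the universe; one upper-tail hypergeometric
    test per set, BH-FDR across all tested sets, rows sorted by ascending
    p-value (ties by set name).  Query genes outside the universe are
    dropped with a warning.
    """
    uni = universe.as_set
    q = query.as_set
    stray = q - uni
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
        q = q & uni
    if not collection:
        warnings.warn("empty gene-set collection: nothing to test", stacklevel=2)
        return pd.DataFrame(
            columns=["set_name", "set_size", "overlap_count", "p_value", "bh_fdr"]
        )
    N, K = len(uni), len(q)
    rows = []
    for name, members in collection.items():
        mem = {normalize_symbol(s) for s in members} & uni
        x = len(q & mem)
        p = hypergeom_tail_p(N, K, len(mem), x)
        rows.append((name, len(mem), x, p))
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap_count", "p_value"])
    df["bh_fdr"] = bh_adjust(df["p_value"])
    return df.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT format
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a GMT file (set name, description, members; tab-separated)."""
    sets: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT rows need name, description "
                    f"and at least one member"
                )
            name = fields[0].strip()
            members = tuple(
                dict.fromkeys(normalize_symbol(s) for s in fields[2:] if s.strip())
            )
            sets[name] = members
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
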