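"""Gene-set overrepresentation by the hypergeometric upper tail.

Given a query list (e.g. the upregulated mRNAs), a universe (all genes
passing the relevant layer's filter), and a collection of gene sets, each
term is scored by P(X >= k) for a hypergeometric draw of n = |query| from
a universe of N genes containing K term members, with k the observed
overlap.  P-values are Benjamini-Hochberg adjusted across all tested
terms and the shortlist keeps at most six terms below FDR 0.05, ranked by
FDR (ties broken by larger overlap, then term id).

This is a plain, reproducible overrepresentation test; it deliberately
does not try to reproduce any particular web service's modified statistic
or curated background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "hypergeom_pvalue",
    "hypergeom_enrich",
    "top_terms",
    "FDR_CUTOFF",
    "MAX_TERMS",
]

FDR_CUTOFF = 0.05
MAX_TERMS = 6


@dataclass
class GeneSet:
    term_id: str
    term_name: str
    members: set[str] = field(default_factory=set)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT: term_id <tab> term_name <tab> member genes..."""
    sets: list[GeneSet] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path} line {lineno}: GMT needs term_id, term_name and >=1 member"
                )
            sets.append(GeneSet(parts[0], parts[1], set(parts[2:])))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in sets:
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.members)]) + "\n")


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) with population N, K successes, n draws."""
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query: set[str],
    sets: Iterable[GeneSet] | Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Score every gene set against the query within the universe.

    Membership is intersected with the universe before testing; terms with
    no member in the universe are skipped.  An empty query returns an
    empty frame with a warning.  Output columns: term_id, term_name, k, K,
    n, N, p_value, fdr, rank (rank assigned ascending by fdr with the
    shortlist tie rule).
    """
    if isinstance(sets, Mapping):
        sets = [GeneSet(t, t, set(m)) for t, m in sets.items()]
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    columns = ["term_id", "term_name", "k", "K", "n", "N", "p_value", "fdr", "rank"]
    if not query:
        logger.warning("empty query: no enrichment computed")
        return pd.DataFrame(columns=columns)
    N, n = len(universe), len(query)
    rows = []
    for s in sets:
        members = s.members & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        rows.append(
            {
                "term_id": s.term_id,
                "term_name": s.term_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeom_pvalue(k, N, K, n),
            }
        )
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df = df.sort_values(
        ["fdr", "k", "term_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["rank"] = df.index + 1
    return df


def top_terms(
    results: pd.DataFrame,
    fdr_cutoff: float = FDR_CUTOFF,
    max_terms: int = MAX_TERMS,
) -> pd.DataFrame:
    """At most ``max_terms`` terms with FDR strictly below the cutoff.

    Sorted ascending by FDR; ties broken by larger overlap then term id.
    May legitimately be empty (no significant enrichment).
    """
    if results.empty:
        return results
    passing = results[results["fdr"] < fdr_cutoff]
    ordered = passing.sort_values(
        ["fdr", "k", "term_id"], ascending=[True, False, True]
    )
    return ordered.head(max_terms).reset_index(drop=True)
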