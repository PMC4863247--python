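"""Literature-based validity scoring and pathway over-representation.

Feature sets (e.g. the per-fraction DE sets, their compilation, and the
cross-omics verified set) are scored against independently retrieved
literature gene lists by simple overlap percentages, and mapped to
pathways with a right-tailed Fisher (hypergeometric) test against an
explicit background universe.  The universe is a required, logged
parameter: proprietary pathway tools ship their own undisclosed
backgrounds, so over-representation here is always relative to a
user-chosen universe (by default the union of all quantified features).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceList:
    """A named literature gene list; symbols are upper-cased internally."""

    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"reference list {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "ReferenceList":
        genes = {
            line.strip() for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        }
        return cls(name or Path(path).stem, frozenset(genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class OverlapResult:
    query_name: str
    reference_name: str
    query_size: int
    overlap_count: int

    @property
    def overlap_pct(self) -> float:
        return 100.0 * self.overlap_count / self.query_size

    @property
    def overlap_pct_reported(self) -> float:
        """Percentage rounded half-up to one decimal, the reporting convention."""
        exact = Decimal(self.overlap_count) * 100 / Decimal(self.query_size)
        return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def overlap_stats(query, ref: ReferenceList, query_name: str = "query") -> OverlapResult:
    """Count and percentage of a query gene set found in a reference list."""
    qset = {g.upper() for g in query}
    if not qset:
        raise ValueError("empty query set")
    return OverlapResult(
        query_name=query_name,
        reference_name=ref.name,
        query_size=len(qset),
        overlap_count=len(qset & ref.genes),
    )


def overlap_table(queries: dict, refs: list) -> pd.DataFrame:
    """Overlap statistics for every query set against every reference list."""
    rows = []
    for qname, qset in queries.items():
        for ref in refs:
            r = overlap_stats(qset, ref, qname)
            rows.append({
                "query": qname,
                "reference": ref.name,
                "query_size": r.query_size,
                "overlap_count": r.overlap_count,
                "overlap_pct": r.overlap_pct_reported,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GMT gene sets and over-representation

def read_gmt(path) -> dict:
    """GMT: one gene set per line — name, description, member symbols."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line needs name, description, >=1 member: {line[:50]!r}")
        sets[parts[0]] = frozenset(g.upper() for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description] + sorted(sets[name])) + "\n")


def fisher_ora(query, pathways: dict, universe, alpha: float = 0.05) -> pd.DataFrame:
    """Right-tailed Fisher over-representation of each pathway in the query.

    Every pathway is intersected with the universe before testing; p is the
    upper hypergeometric tail P(X >= hits).  Results are sorted by ascending
    p, ties broken by larger hit count then pathway name; a BH column is
    included for transparency although significance uses the raw p.
    """
    uni = {g.upper() for g in universe}
    if not uni:
        raise ValueError("empty universe")
    qset = {g.upper() for g in query} & uni
    if len(qset) < len({g.upper() for g in query}):
        logger.info("query genes outside the universe were dropped")
    M, n = len(uni), len(qset)
    rows = []
    for name, members in pathways.items():
        inset = {g.upper() for g in members} & uni
        K = len(inset)
        hits = qset & inset
        k = len(hits)
        p = float(hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append({
            "pathway": name,
            "hits": k,
            "pathway_size": K,
            "query_size": n,
            "universe_size": M,
            "p": min(1.0, p),
            "members_hit": ",".join(sorted(hits)),
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["neg_hits"] = -df["hits"]
    df = df.sort_values(["p", "neg_hits", "pathway"]).drop(columns="neg_hits")
    df = df.reset_index(drop=True)
    df["p_adj"] = bh_adjust(df["p"])
    df["significant"] = df["p"] < alpha
    df["rank"] = df.index + 1
    return df


def rank_comparison(primary: pd.DataFrame, others: dict, top_k: int = 15) -> pd.DataFrame:
    """Cross-tabulate the primary list's top pathways against other rankings.

    For each of the top ``top_k`` significant pathways of ``primary``, report
    its rank and significance in every other ranked list; pathways absent
    from a list are marked ``not predicted``, present-but-not-significant
    ones get an ``(n.s.)`` suffix.
    """
    top = primary[primary["significant"]].head(top_k)
    rows = []
    for _, row in top.iterrows():
        rec = {"pathway": row["pathway"], "rank_primary": int(row["rank"])}
        for name, other in others.items():
            hit = other[other["pathway"] == row["pathway"]]
            if hit.empty:
                rec[f"rank_{name}"] = "not predicted"
            else:
                r = int(hit.iloc[0]["rank"])
                rec[f"rank_{name}"] = str(r) if hit.iloc[0]["significant"] else f"{r} (n.s.)"
        rows.append(rec)
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
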