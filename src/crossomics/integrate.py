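"""Cross-strategy and cross-omics integration.

Direction calls from the three fractionation strategies (CE, ER/Golgi, CM)
and from the transcriptome are combined per gene symbol into a strategy
matrix; features whose non-trivial directions agree across at least
``min_support`` strategies form the "verified" set, with the
proteomics-only agreement (>= 2 of 3 fractions) reported as the
"cross-validated" subset.  Transcript support uses fold-change magnitude
and direction only — with two replicates per cell line the transcriptome
cannot sustain a per-gene test, so no mRNA p-value enters the rule.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .diffexpr import DIRECTION_DOWN, DIRECTION_NONE, DIRECTION_UP
from .quant import GROUP_ALT, GROUP_REF, ONLY_T24, ONLY_T24M

logger = logging.getLogger(__name__)

NOT_MEASURED = "not_measured"
PROTEOMIC_STRATEGIES = ("CE", "ERGolgi", "CM")
STRATEGIES = PROTEOMIC_STRATEGIES + ("mRNA",)

TIER_ALL4 = "all4"
TIER_TWO_OR_THREE = "two_or_three"
TIER_UNVERIFIED = "unverified"


# ---------------------------------------------------------------------------
# Transcript side

def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per sample (library-size normalization)."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero total counts")
    return counts.div(totals, axis=1) * 1e6


def transcript_fold_change(
    counts: pd.DataFrame,
    groups: pd.Series,
    fc_threshold: float = 1.5,
    normalized: bool = False,
) -> pd.DataFrame:
    """Per-gene mRNA fold change (T24M vs T24) and direction.

    ``counts`` is gene x sample; ``groups`` maps sample -> cell line.  Raw
    counts are CPM-normalized unless ``normalized`` is set (externally
    normalized abundances pass through).  Direction is up for fc >=
    threshold, down for fc <= 1/threshold, none otherwise; genes expressed
    in only one line carry an exclusivity sentinel, genes with zero signal
    in both are ``not_measured``.
    """
    abund = counts if normalized else cpm(counts)
    cols_ref = [s for s in abund.columns if groups[s] == GROUP_REF]
    cols_alt = [s for s in abund.columns if groups[s] == GROUP_ALT]
    m_ref = abund[cols_ref].mean(axis=1)
    m_alt = abund[cols_alt].mean(axis=1)
    fc, direction = [], []
    for a, r in zip(m_alt, m_ref):
        if a <= 0 and r <= 0:
            fc.append(np.nan)
            direction.append(NOT_MEASURED)
        elif r <= 0:
            fc.append(ONLY_T24M)
            direction.append(DIRECTION_UP)
        elif a <= 0:
            fc.append(ONLY_T24)
            direction.append(DIRECTION_DOWN)
        else:
            ratio = a / r
            fc.append(ratio)
            if ratio >= fc_threshold:
                direction.append(DIRECTION_UP)
            elif ratio <= 1.0 / fc_threshold:
                direction.append(DIRECTION_DOWN)
            else:
                direction.append(DIRECTION_NONE)
    return pd.DataFrame({"fc_mrna": fc, "direction": direction}, index=abund.index)


def read_transcript_table(path) -> tuple[pd.DataFrame, pd.Series]:
    """TSV with ``symbol`` then per-sample count columns ``<group>_<rep>``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "symbol":
        raise ValueError(f"{path}: first column must be 'symbol'")
    df = df.set_index("symbol")
    groups = pd.Series({c: c.rsplit("_", 1)[0] for c in df.columns})
    return df, groups


# ---------------------------------------------------------------------------
# Strategy matrix

def read_id_map(path) -> dict:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _merge_directions(dirs: list[str]) -> tuple[str, bool]:
    """Collapse several same-symbol calls; conflicting non-trivial calls flag."""
    nontrivial = {d for d in dirs if d in (DIRECTION_UP, DIRECTION_DOWN)}
    if len(nontrivial) > 1:
        return DIRECTION_NONE, True
    if len(nontrivial) == 1:
        return nontrivial.pop(), False
    if DIRECTION_NONE in dirs:
        return DIRECTION_NONE, False
    return NOT_MEASURED, False


def build_strategy_matrix(
    de_tables: dict,
    mrna: pd.DataFrame | None = None,
    idmap: dict | None = None,
) -> pd.DataFrame:
    """Per-symbol direction calls across the four strategies.

    ``de_tables`` maps fraction label -> called DE table (accession, fc, p,
    direction, passes_nominal).  A proteomics slot carries the DE direction
    only for proteins passing the nominal call; retained-but-not-called
    proteins contribute ``none`` and absent proteins ``not_measured``.
    ``mrna`` is the output of :func:`transcript_fold_change` indexed by
    symbol.  Accessions missing from ``idmap`` keep a synthesized symbol
    (the accession itself, logged).  Same-symbol collisions within one
    strategy merge when their directions do not conflict; conflicts are
    flagged and contribute no direction.
    """
    idmap = idmap or {}
    per_symbol: dict[str, dict[str, list[str]]] = {}
    unmapped = 0
    for label, de in de_tables.items():
        if label not in PROTEOMIC_STRATEGIES:
            raise ValueError(f"unknown proteomics strategy {label!r}")
        for _, row in de.iterrows():
            acc = str(row["accession"])
            symbol = idmap.get(acc)
            if symbol is None:
                unmapped += 1
                symbol = acc
            symbol = symbol.upper()
            d = row["direction"] if row["passes_nominal"] else DIRECTION_NONE
            per_symbol.setdefault(symbol, {}).setdefault(label, []).append(d)
    if unmapped:
        logger.info("%d accessions missing from the id map; used accession as symbol", unmapped)
    symbols = sorted(per_symbol)
    records = []
    for sym in symbols:
        rec = {"symbol": sym, "collision_flag": False}
        for label in PROTEOMIC_STRATEGIES:
            dirs = per_symbol[sym].get(label)
            if not dirs:
                rec[f"dir_{label}"] = NOT_MEASURED
            else:
                d, conflict = _merge_directions(dirs)
                rec[f"dir_{label}"] = d
                rec["collision_flag"] |= conflict
        if mrna is not None and sym in mrna.index:
            rec["dir_mRNA"] = mrna.loc[sym, "direction"]
        else:
            rec["dir_mRNA"] = NOT_MEASURED
        records.append(rec)
    m = pd.DataFrame.from_records(records).set_index("symbol")
    return annotate_support(m)


def annotate_support(m: pd.DataFrame) -> pd.DataFrame:
    """Add support_count / consistent / tier columns to a strategy matrix."""
    m = m.copy()
    dir_cols = [f"dir_{s}" for s in STRATEGIES]
    support, consistent, tiers = [], [], []
    for _, row in m.iterrows():
        dirs = [row[c] for c in dir_cols if c in m.columns]
        nontrivial = [d for d in dirs if d in (DIRECTION_UP, DIRECTION_DOWN)]
        ok = len(set(nontrivial)) <= 1
        n = len(nontrivial)
        support.append(n)
        consistent.append(ok)
        if ok and n >= 4:
            tiers.append(TIER_ALL4)
        elif ok and n >= 2:
            tiers.append(TIER_TWO_OR_THREE)
        else:
            tiers.append(TIER_UNVERIFIED)
    m["support_count"] = support
    m["consistent"] = consistent
    m["tier"] = tiers
    return m


def verified_set(m: pd.DataFrame, min_support: int = 2) -> pd.DataFrame:
    """Features whose non-trivial directions agree across >= min_support strategies.

    Any pair of opposing directions disqualifies a feature regardless of how
    many strategies support it.
    """
    return m[(m["support_count"] >= min_support) & m["consistent"]].copy()


def cross_validated_set(m: pd.DataFrame, min_support: int = 2) -> pd.DataFrame:
    """Proteomics-only agreement: >= min_support consistent fraction calls."""
    cols = [f"dir_{s}" for s in PROTEOMIC_STRATEGIES]
    keep = []
    for sym, row in m.iterrows():
        nontrivial = [row[c] for c in cols if row[c] in (DIRECTION_UP, DIRECTION_DOWN)]
        if len(nontrivial) >= min_support and len(set(nontrivial)) == 1:
            keep.append(sym)
    return m.loc[keep].copy()


def integration_summary(m: pd.DataFrame, min_support: int = 2) -> dict:
    v = verified_set(m, min_support)
    return {
        "n_features": int(len(m)),
        "verified": int(len(v)),
        "all4": int((v["tier"] == TIER_ALL4).sum()),
        "two_or_three": int((v["tier"] == TIER_TWO_OR_THREE).sum()),
        "cross_validated_proteomics": int(len(cross_validated_set(m, min_support))),
        "conflicting": int((~m["consistent"]).sum()),
    }


# ---------------------------------------------------------------------------
# Sub-threshold trends

def _trend(fc, dead_zone: float) -> str:
    """Direction of a raw fold change outside an indifference band around 1."""
    if fc == ONLY_T24M:
        return DIRECTION_UP
    if fc == ONLY_T24:
        return DIRECTION_DOWN
    fc = float(fc)
    if fc >= dead_zone:
        return DIRECTION_UP
    if fc <= 1.0 / dead_zone:
        return DIRECTION_DOWN
    return DIRECTION_NONE


def suggestive_support(
    m: pd.DataFrame,
    full_tables: dict,
    idmap: dict | None = None,
    dead_zone: float = 1.25,
) -> pd.DataFrame:
    """Strategies showing a same-direction trend that misses the DE thresholds.

    For every feature with at least one nominal DE call, inspect the other
    fractions' full (uncalled) fc/p tables: a strategy is *suggestive* when
    its raw fold change trends the same way (outside an indifference band,
    default 1.25-fold) but the feature did not pass the fold-change and/or
    p-value thresholds there.
    """
    idmap = idmap or {}
    trends: dict[str, dict[str, str]] = {}
    for label, tab in full_tables.items():
        for _, row in tab.iterrows():
            sym = idmap.get(str(row["accession"]), str(row["accession"])).upper()
            trends.setdefault(sym, {})[label] = _trend(row["fc"], dead_zone)
    records = []
    for sym, row in m.iterrows():
        called = [
            s for s in PROTEOMIC_STRATEGIES
            if row[f"dir_{s}"] in (DIRECTION_UP, DIRECTION_DOWN)
        ]
        if not called:
            continue
        ref_dir = row[f"dir_{called[0]}"]
        sugg = [
            s for s in PROTEOMIC_STRATEGIES
            if s not in called
            and row[f"dir_{s}"] == DIRECTION_NONE
            and trends.get(sym, {}).get(s) == ref_dir
        ]
        if sugg:
            records.append({"symbol": sym, "direction": ref_dir,
                            "suggestive_strategies": ",".join(sugg)})
    return pd.DataFrame.from_records(
        records, columns=["symbol", "direction", "suggestive_strategies"]
    )


def write_strategy_matrix(m: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        m.to_csv(fh, sep="\t")
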