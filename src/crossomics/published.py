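"""Curated published comparison tables shipped with the package.

The bundled TSV lists the proteins a published T24M-vs-T24 bladder cancer
cell line comparison reported as differentially expressed by all three
fractionation strategies (CE, ER/Golgi, CM) with their printed two-decimal
fold changes and Mann-Whitney p-values; exclusive detections are encoded
with the ``only_T24`` / ``only_T24M`` sentinels.  Re-scoring this table
through the cross-strategy agreement machinery is the package's worked
example: the agreement rule must classify all and only these proteins as
three-strategy consistent.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import diffexpr, integrate

THREE_STRATEGY_TABLE = "three_strategy_consistent.tsv"


def load_three_strategy_table() -> pd.DataFrame:
    """The published three-strategy DE table (one row per protein)."""
    with resources.files("crossomics.data").joinpath(THREE_STRATEGY_TABLE).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return df


def published_de_tables(df: pd.DataFrame | None = None) -> dict:
    """Split the published table into per-fraction fc/p tables."""
    df = load_three_strategy_table() if df is None else df
    out = {}
    for label in integrate.PROTEOMIC_STRATEGIES:
        out[label] = pd.DataFrame({
            "accession": df["accession"],
            "fc": [_parse_fc(v) for v in df[f"fc_{label}"]],
            "p": df[f"p_{label}"].astype(float),
        })
    return out


def _parse_fc(value):
    s = str(value).strip()
    if s in (diffexpr.ONLY_T24, diffexpr.ONLY_T24M):
        return s
    return float(s)


def count_three_strategy_consistent(
    df: pd.DataFrame | None = None,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    p_rule: str = "less_equal",
) -> int:
    """Proteins called DE with one consistent direction in all three fractions.

    Printed p-values are compared with ``p <= alpha`` by default to absorb
    their two-decimal rounding; fold-change magnitude must reach the
    threshold (or be an exclusive detection) in every fraction.
    """
    cfg = diffexpr.DEConfig(fc_threshold=fc_threshold, alpha=alpha, p_rule=p_rule)
    tables = {
        label: diffexpr.call_de(tab, cfg, fraction_label=label)
        for label, tab in published_de_tables(df).items()
    }
    matrix = integrate.build_strategy_matrix(tables)
    consistent = integrate.cross_validated_set(matrix, min_support=3)
    return int(len(consistent))
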