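"""Differential expression per fraction: fold changes, exact Mann-Whitney
p-values, Benjamini-Hochberg adjustment, and up/down calls.

Fold changes are ratios of group means of imputed ppm values (T24M over
T24); proteins detected exclusively in one cell line carry a sentinel
instead of a number.  The Mann-Whitney p-value is exact for the small group
sizes used here: the two-sided p is twice the one-sided tail of the
rank-sum statistic over the full enumeration of group-label arrangements of
the pooled values, matching the doubling convention of classical
statistical packages; ties are handled by enumerating the statistic over
the actual tied values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import (
    EXCLUSIVITY_NONE,
    GROUP_ALT,
    GROUP_REF,
    ONLY_T24,
    ONLY_T24M,
    DetectionMask,
    NormalizedDataset,
)

logger = logging.getLogger(__name__)

EXACT_MAX_N = 16  # full enumeration up to C(16,8)=12870 arrangements

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NONE = "none"

P_RULES = ("strict_less", "less_equal")


@dataclass
class DEConfig:
    """Thresholds for calling a protein differentially expressed.

    fc_threshold: minimum fold-change magnitude (calls use >= threshold,
        <= 1/threshold for down).
    alpha: significance level for the Mann-Whitney p-value.
    p_rule: 'strict_less' (p < alpha) or 'less_equal' (p <= alpha); the
        latter absorbs two-decimal rounding when re-scoring printed tables.
    use_fdr: gate calls on the BH-adjusted p-value instead of the nominal one.
    """

    fc_threshold: float = 1.5
    alpha: float = 0.05
    p_rule: str = "strict_less"
    use_fdr: bool = False

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.p_rule not in P_RULES:
            raise ValueError(f"p_rule must be one of {P_RULES}")

    def p_passes(self, p) -> bool:
        return p < self.alpha if self.p_rule == "strict_less" else p <= self.alpha


@dataclass
class DEResult:
    accession: str
    fraction_label: str
    fc: object           # float or sentinel 'only_T24M' / 'only_T24'
    p: float
    p_adj: float
    direction: str
    passes_nominal: bool
    passes_fdr: bool


def fold_change(ppm_alt, ppm_ref, exclusivity: str = EXCLUSIVITY_NONE):
    """Group-mean fold change (T24M vs T24) or an exclusivity sentinel.

    Returns None (with a warning) when both group means are zero for a
    non-exclusive protein; such proteins are dropped by the caller.
    """
    if exclusivity == ONLY_T24M:
        return ONLY_T24M
    if exclusivity == ONLY_T24:
        return ONLY_T24
    m_alt = float(np.mean(ppm_alt))
    m_ref = float(np.mean(ppm_ref))
    if m_alt <= 0 and m_ref <= 0:
        logger.warning("both group means zero for a non-exclusive protein; dropping")
        return None
    if m_ref <= 0:
        return ONLY_T24M
    if m_alt <= 0:
        return ONLY_T24
    return m_alt / m_ref


# ---------------------------------------------------------------------------
# Exact Mann-Whitney

def _u_matrix(values: np.ndarray, n_x: int) -> tuple[np.ndarray, np.ndarray]:
    """Doubled U statistic (integer) for every protein under every arrangement.

    ``values`` is (P, n) pooled per protein with the first ``n_x`` columns the
    observed x group.  Returns (U2_all, U2_obs): 2*U for all C(n, n_x)
    arrangements and for the observed one.  U counts x-over-y wins with ties
    at 1/2, so 2*U is exactly integral.
    """
    P, n = values.shape
    gt = (values[:, :, None] > values[:, None, :]).astype(np.int64)
    eq = (values[:, :, None] == values[:, None, :]).astype(np.int64)
    w2 = 2 * gt + eq  # doubled pairwise win score
    arr = list(combinations(range(n), n_x))
    A = np.zeros((len(arr), n), dtype=np.int64)
    for k, idx in enumerate(arr):
        A[k, list(idx)] = 1
    mask = (A[:, :, None] * (1 - A[:, None, :])).reshape(len(arr), n * n)
    u2_all = w2.reshape(P, n * n) @ mask.T
    obs = np.zeros(n, dtype=np.int64)
    obs[:n_x] = 1
    obs_mask = (obs[:, None] * (1 - obs[None, :])).reshape(n * n)
    # subtract the i==j equal terms contributed nowhere: obs_mask zeroes i==j anyway
    u2_obs = w2.reshape(P, n * n) @ obs_mask
    return u2_all, u2_obs


def mann_whitney_exact_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Two-sided exact Mann-Whitney p for each row of X against the same row of Y.

    Exact by full enumeration for pooled n <= 16; the two-sided p is twice
    the smaller one-sided tail (point included), capped at 1.  Larger pooled
    sizes fall back to the normal approximation with tie-corrected variance
    and continuity correction.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
        Y = Y[None, :]
    n_x, n_y = X.shape[1], Y.shape[1]
    if min(n_x, n_y) < 2:
        raise ValueError("each group needs at least 2 values")
    n = n_x + n_y
    pooled = np.concatenate([X, Y], axis=1)
    if n <= EXACT_MAX_N:
        u2_all, u2_obs = _u_matrix(pooled, n_x)
        n_arr = u2_all.shape[1]
        hi = (u2_all >= u2_obs[:, None]).sum(axis=1) / n_arr
        lo = (u2_all <= u2_obs[:, None]).sum(axis=1) / n_arr
        return np.minimum(1.0, 2.0 * np.minimum(hi, lo))
    return _mann_whitney_normal(pooled, n_x)


def _mann_whitney_normal(pooled: np.ndarray, n_x: int) -> np.ndarray:
    n = pooled.shape[1]
    n_y = n - n_x
    out = np.empty(pooled.shape[0])
    for i, row in enumerate(pooled):
        ranks = stats.rankdata(row)
        u = ranks[:n_x].sum() - n_x * (n_x + 1) / 2
        _, counts = np.unique(row, return_counts=True)
        tie_term = float(((counts**3 - counts)).sum())
        var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            out[i] = 1.0
            continue
        mu = n_x * n_y / 2.0
        diff = u - mu
        cc = 0.5 * np.sign(diff)
        z = (diff - cc) / math.sqrt(var)
        out[i] = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return out


def mann_whitney_exact(x, y) -> float:
    """Scalar convenience wrapper around :func:`mann_whitney_exact_matrix`."""
    return float(mann_whitney_exact_matrix(np.asarray(x, float), np.asarray(y, float))[0])


# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    pvals = np.asarray(list(pvals), dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def call_de(table: pd.DataFrame, cfg: DEConfig | None = None,
            fraction_label: str = "") -> pd.DataFrame:
    """Assign directions and significance calls to a fold-change/p table.

    ``table`` needs columns ``accession``, ``fc`` (float or sentinel) and
    ``p``; a ``p_adj`` column is computed here (BH within the table, i.e.
    per fraction) unless already present.
    """
    cfg = cfg or DEConfig()
    out = table.copy().reset_index(drop=True)
    if "p_adj" not in out.columns:
        out["p_adj"] = bh_adjust(out["p"]) if len(out) else []
    directions = []
    for fc in out["fc"]:
        if fc == ONLY_T24M:
            directions.append(DIRECTION_UP)
        elif fc == ONLY_T24:
            directions.append(DIRECTION_DOWN)
        elif float(fc) >= cfg.fc_threshold:
            directions.append(DIRECTION_UP)
        elif float(fc) <= 1.0 / cfg.fc_threshold:
            directions.append(DIRECTION_DOWN)
        else:
            directions.append(DIRECTION_NONE)
    out["direction"] = directions
    has_dir = out["direction"] != DIRECTION_NONE
    out["passes_nominal"] = has_dir & out["p"].map(cfg.p_passes)
    out["passes_fdr"] = has_dir & out["p_adj"].map(cfg.p_passes)
    if fraction_label:
        out.insert(1, "fraction", fraction_label)
    return out


def de_summary(de: pd.DataFrame, use_fdr: bool = False) -> dict:
    col = "passes_fdr" if use_fdr else "passes_nominal"
    called = de[de[col]]
    return {
        "up": int((called["direction"] == DIRECTION_UP).sum()),
        "down": int((called["direction"] == DIRECTION_DOWN).sum()),
        "total": int(len(called)),
    }


def differential_expression(
    imputed: NormalizedDataset,
    mask: DetectionMask,
    cfg: DEConfig | None = None,
) -> pd.DataFrame:
    """Fold change + exact Mann-Whitney + BH for every retained protein.

    Exclusive proteins keep their sentinel fold change but are tested like
    any other protein on the zero-imputed ppm vectors; proteins whose group
    means are both zero without exclusivity are dropped with a warning.
    """
    cfg = cfg or DEConfig()
    retained = mask.retained_accessions()
    cols_ref = imputed.samples_of(GROUP_REF)
    cols_alt = imputed.samples_of(GROUP_ALT)
    ppm = imputed.ppm.loc[retained]
    fcs, keep = [], []
    for acc in retained:
        fc = fold_change(
            ppm.loc[acc, cols_alt].to_numpy(),
            ppm.loc[acc, cols_ref].to_numpy(),
            mask.exclusivity[acc],
        )
        if fc is None:
            continue
        keep.append(acc)
        fcs.append(fc)
    X = imputed.ppm.loc[keep, cols_alt].to_numpy()
    Y = imputed.ppm.loc[keep, cols_ref].to_numpy()
    pvals = mann_whitney_exact_matrix(X, Y) if keep else np.array([])
    table = pd.DataFrame({"accession": keep, "fc": fcs, "p": pvals})
    return call_de(table, cfg, fraction_label=imputed.fraction_label)


def write_de_table(de: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        de.to_csv(fh, sep="\t", index=False)


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["accession"] = df["accession"].astype(str)
    return df
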