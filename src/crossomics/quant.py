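"""Per-fraction label-free quantification: ingest, clean, normalize, filter.

Protein-level peak areas from three subcellular fractions (total cell
extract CE, ER/Golgi, conditioned medium CM) of two compared cell lines
(T24 and its metastatic subclone T24M, five replicates each) are read from
TSV, stripped of known contaminants, scaled to parts-per-million of each
sample's total signal, filtered by a unique-peptide/replicate detection
rule, and assessed for secretome-enrichment efficiency via signal-peptide
annotations and fraction marker proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FRACTIONS = ("CE", "ERGolgi", "CM")
GROUPS = ("T24", "T24M")
GROUP_REF = "T24"      # comparison baseline
GROUP_ALT = "T24M"     # metastatic subclone; fold changes are ALT vs REF

PPM_SCALE = 1e6

EXCLUSIVITY_NONE = "none"
ONLY_T24 = "only_T24"
ONLY_T24M = "only_T24M"


class QuantParseError(ValueError):
    """Malformed quantification table (bad header, negative or inconsistent cells)."""


def _sample_id(group: str, rep: int) -> str:
    return f"{group}_{rep}"


@dataclass
class FractionDataset:
    """Raw protein x sample peak areas and unique-peptide counts for one fraction.

    ``intensities`` and ``peptide_counts`` are DataFrames indexed by accession
    with identical sample columns; ``groups`` maps each sample column to its
    cell line and ``replicate_index`` to its replicate number.
    """

    fraction_label: str
    intensities: pd.DataFrame
    peptide_counts: pd.DataFrame
    groups: pd.Series
    replicate_index: pd.Series

    def __post_init__(self) -> None:
        if self.fraction_label not in FRACTIONS:
            raise ValueError(
                f"unknown fraction label {self.fraction_label!r}; expected one of {FRACTIONS}"
            )
        if self.intensities.shape != self.peptide_counts.shape:
            raise ValueError("intensities and peptide_counts must have identical shape")
        if not self.intensities.columns.equals(self.peptide_counts.columns):
            raise ValueError("intensities and peptide_counts must share sample columns")
        if not self.intensities.index.equals(self.peptide_counts.index):
            raise ValueError("intensities and peptide_counts must share accessions")
        if self.intensities.index.has_duplicates:
            dupes = self.intensities.index[self.intensities.index.duplicated()].unique()
            raise QuantParseError(f"duplicate accessions: {list(dupes[:5])}")
        if (self.intensities.to_numpy() < 0).any():
            raise QuantParseError("negative intensity values")
        if (self.peptide_counts.to_numpy() < 0).any():
            raise QuantParseError("negative peptide counts")
        counts = self.groups.value_counts()
        for g in GROUPS:
            if counts.get(g, 0) < 2:
                raise ValueError(f"group {g} has fewer than 2 samples")
        # undetected (no peptide) implies no quantifiable area
        bad = (self.peptide_counts.to_numpy() == 0) & (self.intensities.to_numpy() > 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise QuantParseError(
                "intensity > 0 with peptide_count == 0 at "
                f"protein {self.intensities.index[i]!r}, sample {self.intensities.columns[j]!r}"
            )

    @property
    def accessions(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def subset(self, accessions) -> "FractionDataset":
        keep = [a for a in self.accessions if a in set(accessions)]
        return FractionDataset(
            fraction_label=self.fraction_label,
            intensities=self.intensities.loc[keep],
            peptide_counts=self.peptide_counts.loc[keep],
            groups=self.groups,
            replicate_index=self.replicate_index,
        )


@dataclass
class NormalizedDataset:
    """ppm-normalized intensities; each sample's retained total sums to 1e6."""

    fraction_label: str
    ppm: pd.DataFrame
    total_area: pd.Series
    groups: pd.Series
    replicate_index: pd.Series

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.ppm.columns if self.groups[s] == group]


@dataclass
class DetectionMask:
    """Per-cell detection, per-protein retention and exclusive-detection calls."""

    detected: pd.DataFrame
    retained: pd.Series
    exclusivity: pd.Series
    min_unique_peptides: int
    min_replicates: int

    def retained_accessions(self) -> list[str]:
        return list(self.retained.index[self.retained])


@dataclass
class SignalAnnotation:
    """Accession -> has-signal-peptide map; absent accessions count as negative."""

    has_signal: dict = field(default_factory=dict)

    def lookup(self, accessions) -> pd.Series:
        missing = [a for a in accessions if a not in self.has_signal]
        if missing:
            logger.info(
                "signal-peptide annotation missing for %d/%d accessions; defaulting to False",
                len(missing), len(list(accessions)),
            )
        return pd.Series(
            [bool(self.has_signal.get(a, False)) for a in accessions],
            index=list(accessions), dtype=bool,
        )

    @classmethod
    def from_tsv(cls, path) -> "SignalAnnotation":
        df = _read_two_column_tsv(path, ("accession", "has_signal_peptide"))
        truthy = {"1", "true", "yes", "y"}
        return cls({
            str(a): str(v).strip().lower() in truthy
            for a, v in zip(df.iloc[:, 0], df.iloc[:, 1])
        })


@dataclass
class EnrichmentReport:
    """Fraction-enrichment assessment: signal-peptide shares and marker ratios."""

    fraction_label: str
    pct_signal_proteins: float
    pct_signal_intensity: float
    n_retained: int
    n_signal: int
    marker_ratios: dict = field(default_factory=dict)

    def formatted(self) -> str:
        lines = [
            f"fraction: {self.fraction_label}",
            f"retained proteins: {self.n_retained}",
            f"signal-peptide proteins: {self.n_signal} "
            f"({_round_half_up(self.pct_signal_proteins)}%)",
            f"signal-peptide intensity share: {_round_half_up(self.pct_signal_intensity)}%",
        ]
        for marker, ratios in self.marker_ratios.items():
            for other, r in ratios.items():
                lines.append(f"marker {marker}: {r:.2f}-fold vs {other}")
        return "\n".join(lines)


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _read_two_column_tsv(path, expected_cols) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise QuantParseError(f"{path}: expected 2 columns {expected_cols}")
    return df


# ---------------------------------------------------------------------------
# TSV ingest / emit

def read_quant_table(path, fraction_label: str, group_map: dict | None = None) -> FractionDataset:
    """Read a per-fraction quantification TSV into a :class:`FractionDataset`.

    Expected header: ``accession`` then paired ``area_<group>_<rep>`` /
    ``pep_<group>_<rep>`` columns.  ``group_map`` optionally overrides the
    group encoded in the column names (sample id -> group).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "accession":
        raise QuantParseError(f"{path}: first column must be 'accession', got {df.columns[0]!r}")
    area_cols = [c for c in df.columns if c.startswith("area_")]
    pep_cols = [c for c in df.columns if c.startswith("pep_")]
    if not area_cols or len(area_cols) != len(pep_cols):
        raise QuantParseError(f"{path}: need paired area_*/pep_* columns")
    sample_ids, groups, reps = [], {}, {}
    for c in area_cols:
        sid = c[len("area_"):]
        if f"pep_{sid}" not in pep_cols:
            raise QuantParseError(f"{path}: column {c} has no matching pep_{sid}")
        try:
            group, rep = sid.rsplit("_", 1)
            rep = int(rep)
        except ValueError as exc:
            raise QuantParseError(f"{path}: malformed sample column {c!r}") from exc
        if group_map is not None:
            group = group_map[sid]
        if group not in GROUPS:
            raise QuantParseError(f"{path}: unknown group {group!r} in column {c!r}")
        sample_ids.append(sid)
        groups[sid] = group
        reps[sid] = rep
    if df["accession"].duplicated().any():
        dupes = df.loc[df["accession"].duplicated(), "accession"].tolist()
        raise QuantParseError(f"{path}: duplicate accession rows {dupes[:5]}")
    acc = df["accession"].astype(str)
    intens = df[[f"area_{s}" for s in sample_ids]].astype(float)
    intens.columns = sample_ids
    intens.index = acc
    peps = df[[f"pep_{s}" for s in sample_ids]].astype(int)
    peps.columns = sample_ids
    peps.index = acc
    return FractionDataset(
        fraction_label=fraction_label,
        intensities=intens,
        peptide_counts=peps,
        groups=pd.Series(groups),
        replicate_index=pd.Series(reps),
    )


def write_quant_table(d: FractionDataset, path, header_comment: str | None = None) -> None:
    """Write a dataset back to the TSV dialect :func:`read_quant_table` accepts."""
    out = pd.DataFrame({"accession": d.accessions})
    for s in d.samples:
        out[f"area_{s}"] = d.intensities[s].to_numpy()
        out[f"pep_{s}"] = d.peptide_counts[s].to_numpy()
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cleaning, normalization, filtering

def exclude_contaminants(d: FractionDataset, contaminants) -> FractionDataset:
    """Drop known contaminant accessions (e.g. serum proteins); order preserved."""
    contaminants = set(contaminants)
    present = [a for a in d.accessions if a in contaminants]
    absent = contaminants - set(present)
    if absent:
        logger.info("%d contaminants not present in %s table", len(absent), d.fraction_label)
    if not present:
        return d
    logger.info("excluding %d contaminant proteins from %s", len(present), d.fraction_label)
    keep = [a for a in d.accessions if a not in contaminants]
    return d.subset(keep)


def ppm_normalize(d: FractionDataset) -> NormalizedDataset:
    """Scale each sample's areas to parts-per-million of its total area.

    ppm[i, s] = area[i, s] / total_area[s] * 1e6, where the total area is the
    sum of all protein areas in that sample.
    """
    total = d.intensities.sum(axis=0)
    zero = total[total <= 0]
    if len(zero):
        raise ValueError(f"zero total area in sample(s) {list(zero.index)}")
    ppm = d.intensities.div(total, axis=1) * PPM_SCALE
    return NormalizedDataset(
        fraction_label=d.fraction_label,
        ppm=ppm,
        total_area=total,
        groups=d.groups,
        replicate_index=d.replicate_index,
    )


def detection_filter(
    d: FractionDataset, min_unique_peptides: int = 2, min_replicates: int = 3
) -> DetectionMask:
    """Apply the identification filter and derive exclusive-detection calls.

    A protein is detected in a run when that run identified it with at least
    ``min_unique_peptides`` unique peptides; it is retained when detected in at
    least ``min_replicates`` replicates of at least one cell line.  A retained
    protein with zero detections in the other cell line is called exclusive
    (``only_T24`` / ``only_T24M``).
    """
    for g in GROUPS:
        if min_replicates > len(d.samples_of(g)):
            raise ValueError(f"min_replicates={min_replicates} exceeds size of group {g}")
    detected = d.peptide_counts >= min_unique_peptides
    n_ref = detected[d.samples_of(GROUP_REF)].sum(axis=1)
    n_alt = detected[d.samples_of(GROUP_ALT)].sum(axis=1)
    retained = (n_ref >= min_replicates) | (n_alt >= min_replicates)
    exclusivity = pd.Series(EXCLUSIVITY_NONE, index=detected.index, dtype=object)
    exclusivity[retained & (n_ref == 0)] = ONLY_T24M
    exclusivity[retained & (n_alt == 0)] = ONLY_T24
    return DetectionMask(
        detected=detected,
        retained=retained,
        exclusivity=exclusivity,
        min_unique_peptides=min_unique_peptides,
        min_replicates=min_replicates,
    )


def impute_missing(
    n: NormalizedDataset,
    m: DetectionMask,
    software_error_flags: pd.DataFrame | None = None,
) -> NormalizedDataset:
    """Resolve missing values: undetected cells become zero; cells the
    quantification software identified but failed to integrate (flagged) get
    the mean ppm of that protein over the non-flagged samples of the same
    group, computed after zero replacement."""
    ppm = n.ppm.copy()
    ppm[~m.detected] = 0.0
    if software_error_flags is not None:
        flags = software_error_flags.reindex_like(ppm).fillna(False).astype(bool)
        for g in set(n.groups):
            cols = [s for s in ppm.columns if n.groups[s] == g]
            sub_flags = flags[cols]
            rows = sub_flags.any(axis=1)
            for acc in ppm.index[rows]:
                ok = [c for c in cols if not flags.at[acc, c]]
                if not ok:
                    raise ValueError(
                        f"protein {acc!r}: every {g} sample flagged; group mean undefined"
                    )
                mean = float(ppm.loc[acc, ok].mean())
                for c in cols:
                    if flags.at[acc, c]:
                        ppm.at[acc, c] = mean
    return NormalizedDataset(
        fraction_label=n.fraction_label,
        ppm=ppm,
        total_area=n.total_area,
        groups=n.groups,
        replicate_index=n.replicate_index,
    )


# ---------------------------------------------------------------------------
# Cross-fraction identification overlap

def core_proteome(retained_sets: dict) -> dict:
    """Venn-region counts of retained accessions across fractions.

    Returns ``{(labels...): count}`` with one key per non-empty combination of
    fraction labels (sorted tuples); a protein counts toward exactly the
    region of fractions it appears in, so the counts sum to the union size.
    The full-intersection region is the core proteome.
    """
    labels = sorted(retained_sets)
    if len(labels) < 2:
        raise ValueError("need at least two fractions for an overlap analysis")
    sets = {k: set(v) for k, v in retained_sets.items()}
    regions = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(set(), *(sets[c] for c in labels if c not in combo))
            regions[tuple(combo)] = len(inside - outside)
    return regions


# ---------------------------------------------------------------------------
# Enrichment assessment

def enrichment_report(
    n: NormalizedDataset,
    m: DetectionMask,
    ann: SignalAnnotation,
    markers: dict | None = None,
    other_fractions: dict | None = None,
) -> EnrichmentReport:
    """Assess secretome-enrichment efficiency of one fraction.

    Reports the percentage of retained proteins annotated with a signal
    peptide, the average share of total ppm intensity those proteins carry,
    and (when ``markers`` maps marker accessions to their home fraction and
    ``other_fractions`` provides the other fractions' normalized data) the
    fold difference of each marker's mean ppm versus every other fraction,
    pooled over both cell lines.
    """
    retained = m.retained_accessions()
    if not retained:
        raise ValueError("no retained proteins; cannot assess enrichment")
    signal = ann.lookup(retained)
    n_signal = int(signal.sum())
    pct_proteins = 100.0 * n_signal / len(retained)
    sig_acc = list(signal.index[signal])
    share = n.ppm.loc[sig_acc].sum(axis=0) / PPM_SCALE if sig_acc else pd.Series(
        0.0, index=n.ppm.columns
    )
    pct_intensity = 100.0 * float(share.mean())
    ratios: dict = {}
    if markers and other_fractions:
        for acc, home in markers.items():
            if home != n.fraction_label or acc not in n.ppm.index:
                continue
            own_mean = float(n.ppm.loc[acc].mean())
            ratios[acc] = {}
            for label, other in other_fractions.items():
                if label == n.fraction_label or acc not in other.ppm.index:
                    continue
                other_mean = float(other.ppm.loc[acc].mean())
                ratios[acc][label] = own_mean / other_mean if other_mean > 0 else float("inf")
    return EnrichmentReport(
        fraction_label=n.fraction_label,
        pct_signal_proteins=pct_proteins,
        pct_signal_intensity=pct_intensity,
        n_retained=len(retained),
        n_signal=n_signal,
        marker_ratios=ratios,
    )


def read_contaminant_list(path) -> set:
    """One accession per line (or first TSV column); '#' comments skipped."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        first = line.split("\t")[0]
        if first == "accession":  # optional header
            continue
        out.add(first)
    return out
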