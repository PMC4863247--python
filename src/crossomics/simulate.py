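"""Ground-truthed synthetic data for the whole pipeline.

The generator emulates a compartment-resolved label-free experiment: three
subcellular fractions (CE, ER/Golgi, CM) of two cell lines (T24, T24M) with
five replicates each, log-normal protein peak areas, planted multiplicative
fold changes and exclusive-detection proteins, intensity-dependent dropout,
fraction-specific signal-peptide prevalence, a negative-binomial
transcriptome (two replicates per line) whose fold changes agree with the
protein truth with a configurable concordance probability, two partially
overlapping literature reference lists enriched for true positives, and a
pathway collection with one planted enriched pathway.

Defaults mirror the study conditions the pipeline targets: per-fraction
retained-scale protein counts 1359/1062/816 with a shared core of 498 and
fraction-exclusive regions 408/166/219, signal-peptide prevalences
0.09/0.14/0.30 (CE/ER-Golgi/CM), and literature lists of 627 and 671 genes
overlapping in 179.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .quant import (
    FRACTIONS,
    GROUP_ALT,
    GROUP_REF,
    FractionDataset,
    SignalAnnotation,
    write_quant_table,
)
from .literature import ReferenceList, write_gmt

logger = logging.getLogger(__name__)

MRNA_CONCORDANT = "concordant"
MRNA_OPPOSITE = "opposite"
MRNA_SUBTHRESHOLD = "subthreshold"
MRNA_NULL = "null"


def _default_n_proteins() -> dict:
    return {"CE": 1359, "ERGolgi": 1062, "CM": 816}


def _default_exclusive_ids() -> dict:
    return {"CE": 408, "ERGolgi": 166, "CM": 219}


def _default_signal_prevalence() -> dict:
    return {"CE": 0.09, "ERGolgi": 0.14, "CM": 0.30}


@dataclass
class SimConfig:
    """All knobs of the generator; ``seed`` is mandatory.

    n_proteins: proteins per fraction.
    core_size / exclusive_identified: Venn structure of fraction membership
        (core = identified in all three; exclusive = identified in one only);
        the pairwise-only regions are derived.
    de_fraction / exclusive_fraction: per-gene probabilities of a planted
        multiplicative effect resp. exclusive detection (one group only).
    log2fc_range: magnitude range of planted protein log2 fold changes.
    baseline_log_mean / baseline_log_sd: natural-log location/scale of
        protein baseline areas (arbitrary units) across proteins.
    within_group_log_sd: replicate noise on the natural-log scale.
    detect_prob_top / detect_prob_bottom: per-replicate detection
        probability for the highest- resp. lowest-abundance protein
        (linear in the within-fraction intensity rank).
    single_peptide_prob: chance a detected run yields only one unique
        peptide (which the >=2-peptide rule discards).
    signal_prevalence: target signal-peptide prevalence per fraction.
    mrna_concordance: probability a planted-DE gene's transcript shows a
        same-direction fold change above the verification threshold.
    mrna_opposite_prob: probability of an above-threshold opposite trend.
    mrna_dispersion: negative-binomial dispersion of transcript counts.
    lit_sizes / lit_overlap: sizes of the two literature lists and of their
        intersection (emitted exactly).
    lit_enrichment: sampling-weight ratio of true-DE genes vs background
        when building the literature lists.
    """

    seed: int
    n_proteins: dict = field(default_factory=_default_n_proteins)
    n_replicates: int = 5
    core_size: int = 498
    exclusive_identified: dict = field(default_factory=_default_exclusive_ids)
    de_fraction: float = 0.20
    exclusive_fraction: float = 0.02
    log2fc_range: tuple = (1.2, 3.0)
    baseline_log_mean: float = 16.0
    baseline_log_sd: float = 1.8
    within_group_log_sd: float = 0.25
    detect_prob_top: float = 0.99
    detect_prob_bottom: float = 0.55
    single_peptide_prob: float = 0.03
    signal_prevalence: dict = field(default_factory=_default_signal_prevalence)
    shared_region_signal_rates: dict = field(
        default_factory=lambda: {"core": 0.06, "CE+CM": 0.10, "CE+ERGolgi": 0.06,
                                 "ERGolgi+CM": 0.20}
    )
    mrna_concordance: float = 0.7
    mrna_opposite_prob: float = 0.05
    mrna_dispersion: float = 0.02
    mrna_baseline_log_mean: float = 5.7
    mrna_baseline_log_sd: float = 1.2
    mrna_missing_prob: float = 0.005
    n_transcript_replicates: int = 2
    lit_sizes: tuple = (627, 671)
    lit_overlap: int = 179
    lit_enrichment: float = 3.0
    n_decoy_symbols: int = 3000
    n_pathways: int = 40
    pathway_size_range: tuple = (15, 60)
    planted_pathway_size: int = 30
    planted_pathway_de_share: float = 0.8
    n_contaminants: int = 12
    symbol_collision_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        if self.n_replicates < 3:
            raise ValueError("n_replicates must be >= 3")
        for name in ("de_fraction", "exclusive_fraction", "mrna_concordance",
                     "mrna_opposite_prob", "single_peptide_prob",
                     "detect_prob_top", "detect_prob_bottom", "mrna_missing_prob",
                     "symbol_collision_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.de_fraction + self.exclusive_fraction > 1:
            raise ValueError("de_fraction + exclusive_fraction exceeds 1")
        if self.mrna_concordance + self.mrna_opposite_prob > 1:
            raise ValueError("mrna_concordance + mrna_opposite_prob exceeds 1")
        for f in FRACTIONS:
            if f not in self.n_proteins:
                raise ValueError(f"n_proteins missing fraction {f}")
        pairwise = self._pairwise_regions()
        if any(v < 0 for v in pairwise.values()):
            raise ValueError(
                f"infeasible Venn structure: derived pairwise regions {pairwise}"
            )
        if self.lit_overlap > min(self.lit_sizes):
            raise ValueError("literature overlap exceeds a list size")

    def _pairwise_regions(self) -> dict:
        """Solve the three pairwise-only region sizes from totals/core/exclusives."""
        rest = {
            f: self.n_proteins[f] - self.core_size - self.exclusive_identified[f]
            for f in FRACTIONS
        }
        # rest[CE] = ce_erg + ce_cm; rest[ERGolgi] = ce_erg + erg_cm; rest[CM] = ce_cm + erg_cm
        total = sum(rest.values())
        if total % 2:
            raise ValueError("Venn structure does not close (odd pairwise total)")
        s = total // 2
        return {
            ("CE", "ERGolgi"): s - rest["CM"],
            ("CE", "CM"): s - rest["ERGolgi"],
            ("ERGolgi", "CM"): s - rest["CE"],
        }


@dataclass
class SimTruth:
    """Planted ground truth, aligned with the emitted data by construction."""

    genes: pd.DataFrame  # one row per gene, see generate_proteome
    config: SimConfig

    def true_de_symbols(self) -> set:
        g = self.genes
        return set(g.loc[g["is_de"] | g["is_exclusive"], "symbol"])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# crossomics stage=simulate truth table\n")
            self.genes.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# membership and signal-peptide structure

def _assign_membership(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    pairwise = cfg._pairwise_regions()
    regions = (
        [("CE", "ERGolgi", "CM")] * cfg.core_size
        + [("CE",)] * cfg.exclusive_identified["CE"]
        + [("ERGolgi",)] * cfg.exclusive_identified["ERGolgi"]
        + [("CM",)] * cfg.exclusive_identified["CM"]
        + [("CE", "ERGolgi")] * pairwise[("CE", "ERGolgi")]
        + [("CE", "CM")] * pairwise[("CE", "CM")]
        + [("ERGolgi", "CM")] * pairwise[("ERGolgi", "CM")]
    )
    n = len(regions)
    acc = [f"SIM{i:05d}" for i in range(n)]
    symbols = [f"GENE{i:05d}" for i in range(n)]
    if cfg.symbol_collision_rate > 0:
        # many-to-one accession->symbol mode: fold a slice of symbols onto others
        n_fold = int(round(cfg.symbol_collision_rate * n))
        targets = rng.integers(0, n, size=n_fold)
        idx = rng.choice(n, size=n_fold, replace=False)
        for i, t in zip(idx, targets):
            symbols[i] = symbols[t]
    df = pd.DataFrame({"accession": acc, "symbol": symbols})
    for f in FRACTIONS:
        df[f"in_{f}"] = [f in r for r in regions]
    df["region"] = ["+".join(r) for r in regions]
    return df


def _solve_signal_rates(cfg: SimConfig, genes: pd.DataFrame) -> dict:
    """Per-region signal-peptide rates hitting each fraction's target prevalence.

    Shared-region rates are fixed configuration; the three fraction-exclusive
    region rates are solved so each fraction's expected prevalence equals its
    target, then clipped to [0, 1] (with a warning when clipping shifts the
    achievable prevalence).
    """
    region_n = genes["region"].value_counts().to_dict()
    fixed = {
        "CE+ERGolgi+CM": cfg.shared_region_signal_rates["core"],
        "CE+CM": cfg.shared_region_signal_rates["CE+CM"],
        "CE+ERGolgi": cfg.shared_region_signal_rates["CE+ERGolgi"],
        "ERGolgi+CM": cfg.shared_region_signal_rates["ERGolgi+CM"],
    }
    rates = dict(fixed)
    for f in FRACTIONS:
        in_regions = [r for r in region_n if f in r.split("+")]
        target_count = cfg.signal_prevalence[f] * cfg.n_proteins[f]
        fixed_count = sum(
            region_n[r] * fixed[r] for r in in_regions if r in fixed
        )
        n_excl = region_n.get(f, 0)
        if n_excl == 0:
            continue
        rate = (target_count - fixed_count) / n_excl
        clipped = min(1.0, max(0.0, rate))
        if clipped != rate:
            logger.warning(
                "signal rate for %s-exclusive region clipped from %.3f to %.3f; "
                "prevalence target %.2f not exactly achievable",
                f, rate, clipped, cfg.signal_prevalence[f],
            )
        rates[f] = clipped
    return rates


# ---------------------------------------------------------------------------
# proteome

def generate_proteome(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Generate the three fraction datasets plus the planted truth.

    Returns ``(datasets, truth)`` where ``datasets`` maps fraction label ->
    :class:`FractionDataset` (contaminant proteins included, listed in
    ``truth.genes``).  Deterministic given ``cfg.seed``.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(cfg.seed))
    genes = _assign_membership(cfg, rng)
    n = len(genes)

    rates = _solve_signal_rates(cfg, genes)
    genes["signal_peptide"] = rng.random(n) < genes["region"].map(rates).to_numpy()

    u = rng.random(n)
    genes["is_de"] = u < cfg.de_fraction
    genes["is_exclusive"] = (u >= cfg.de_fraction) & (
        u < cfg.de_fraction + cfg.exclusive_fraction
    )
    direction = np.where(rng.random(n) < 0.5, "up", "down")
    genes["direction"] = np.where(genes["is_de"] | genes["is_exclusive"], direction, "")

    lo, hi = cfg.log2fc_range
    log2fc = rng.uniform(lo, hi, size=n)
    sign = np.where(genes["direction"] == "down", -1.0, 1.0)
    genes["log2fc"] = np.where(genes["is_de"], log2fc * sign, 0.0)

    genes["baseline_log"] = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n)

    datasets = {}
    for f in FRACTIONS:
        datasets[f] = _generate_fraction(cfg, genes, f, rng)
    return datasets, SimTruth(genes=genes, config=cfg)


def _generate_fraction(cfg, genes: pd.DataFrame, fraction: str,
                       rng: np.random.Generator) -> FractionDataset:
    sub = genes[genes[f"in_{fraction}"]]
    p = len(sub)
    reps = cfg.n_replicates
    samples = [f"{g}_{r}" for g in (GROUP_REF, GROUP_ALT) for r in range(1, reps + 1)]
    groups = pd.Series({s: s.rsplit("_", 1)[0] for s in samples})
    rep_idx = pd.Series({s: int(s.rsplit("_", 1)[1]) for s in samples})

    base = sub["baseline_log"].to_numpy()
    delta = sub["log2fc"].to_numpy() * np.log(2)
    mu = np.empty((p, 2 * reps))
    mu[:, :reps] = (base - delta / 2)[:, None]      # T24
    mu[:, reps:] = (base + delta / 2)[:, None]      # T24M
    log_area = mu + rng.normal(0.0, cfg.within_group_log_sd, size=(p, 2 * reps))
    area = np.exp(log_area)

    # intensity-rank-dependent detection probability (0 = most abundant)
    order = np.argsort(np.argsort(-base))
    q = order / max(p - 1, 1)
    p_det = cfg.detect_prob_top - (cfg.detect_prob_top - cfg.detect_prob_bottom) * q
    detected = rng.random((p, 2 * reps)) < p_det[:, None]

    # exclusive proteins: absent in one group, solidly detected in the other
    excl = sub["is_exclusive"].to_numpy()
    up = (sub["direction"] == "up").to_numpy()
    absent_ref = excl & up       # only in T24M -> T24 columns empty
    absent_alt = excl & ~up
    detected[absent_ref, :reps] = False
    detected[absent_ref, reps:] = True
    detected[absent_alt, reps:] = False
    detected[absent_alt, :reps] = True

    lam = 0.5 + 5.0 * (1 - q)
    peps = np.where(detected, 2 + rng.poisson(lam[:, None], size=(p, 2 * reps)), 0)
    # occasional single-peptide identifications (discarded by the >=2 rule)
    single = detected & ~excl[:, None] & (rng.random((p, 2 * reps)) < cfg.single_peptide_prob)
    peps[single] = 1
    area = np.where(peps > 0, area, 0.0)

    idx = pd.Index(sub["accession"], name="accession")
    intens = pd.DataFrame(area, index=idx, columns=samples)
    pep_df = pd.DataFrame(peps, index=idx, columns=samples)

    # spiked contaminants (e.g. serum carry-over), constant across groups
    if cfg.n_contaminants:
        cacc = [f"CONT{i:03d}" for i in range(cfg.n_contaminants)]
        cbase = rng.normal(cfg.baseline_log_mean + 1.0, 0.5, size=cfg.n_contaminants)
        carea = np.exp(
            cbase[:, None] + rng.normal(0, cfg.within_group_log_sd,
                                        size=(cfg.n_contaminants, 2 * reps))
        )
        cpep = 2 + rng.poisson(4.0, size=(cfg.n_contaminants, 2 * reps))
        intens = pd.concat([intens, pd.DataFrame(carea, index=pd.Index(cacc), columns=samples)])
        pep_df = pd.concat([pep_df, pd.DataFrame(cpep, index=pd.Index(cacc), columns=samples)])

    return FractionDataset(
        fraction_label=fraction,
        intensities=intens,
        peptide_counts=pep_df,
        groups=groups,
        replicate_index=rep_idx,
    )


def contaminant_accessions(cfg: SimConfig) -> list[str]:
    return [f"CONT{i:03d}" for i in range(cfg.n_contaminants)]


# ---------------------------------------------------------------------------
# transcriptome

def generate_transcriptome(cfg: SimConfig, truth: SimTruth,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Negative-binomial transcript counts, 2 replicates per cell line.

    Planted-DE genes (including exclusives) receive a same-direction mRNA
    fold change above the verification threshold with probability
    ``mrna_concordance``, an opposite above-threshold trend with probability
    ``mrna_opposite_prob``, and a sub-threshold wobble otherwise; the planted
    class is recorded in ``truth.genes['mrna_class']``.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    genes = truth.genes
    n = len(genes)
    measured = (rng.random(n) >= cfg.mrna_missing_prob) & ~genes["accession"].str.startswith("CONT")

    is_true = (genes["is_de"] | genes["is_exclusive"]).to_numpy()
    u = rng.random(n)
    cls = np.where(
        is_true,
        np.where(
            u < cfg.mrna_concordance, MRNA_CONCORDANT,
            np.where(u < cfg.mrna_concordance + cfg.mrna_opposite_prob,
                     MRNA_OPPOSITE, MRNA_SUBTHRESHOLD),
        ),
        MRNA_NULL,
    )
    sign = np.where(genes["direction"] == "down", -1.0, 1.0)
    mag_hi = rng.uniform(0.9, 2.5, size=n)      # log2 fc magnitude, >= 1.87-fold
    mag_lo = rng.uniform(0.0, 0.25, size=n)     # sub-threshold, <= 1.19-fold
    lfc = np.select(
        [cls == MRNA_CONCORDANT, cls == MRNA_OPPOSITE, cls == MRNA_SUBTHRESHOLD],
        [mag_hi * sign, -mag_hi * sign, mag_lo * np.where(rng.random(n) < 0.5, 1, -1)],
        default=rng.normal(0.0, 0.1, size=n),
    )
    genes["mrna_class"] = np.where(measured, cls, "missing")
    genes["mrna_log2fc"] = np.where(measured, lfc, np.nan)

    base = np.exp(rng.normal(cfg.mrna_baseline_log_mean, cfg.mrna_baseline_log_sd, size=n))
    reps = cfg.n_transcript_replicates
    samples = [f"{g}_{r}" for g in (GROUP_REF, GROUP_ALT) for r in range(1, reps + 1)]
    delta = lfc * np.log(2)
    mean = np.empty((n, 2 * reps))
    mean[:, :reps] = (base * np.exp(-delta / 2))[:, None]
    mean[:, reps:] = (base * np.exp(delta / 2))[:, None]
    r_nb = 1.0 / cfg.mrna_dispersion
    counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mean))
    df = pd.DataFrame(counts[measured],
                      index=pd.Index(genes["symbol"].to_numpy()[measured], name="symbol"),
                      columns=samples)
    df = df[~df.index.duplicated()]  # collided symbols keep the first transcript
    return df


# ---------------------------------------------------------------------------
# literature lists and pathways

def generate_reference_and_pathways(cfg: SimConfig, truth: SimTruth,
                                    rng: np.random.Generator | None = None):
    """Two literature lists (exact sizes and overlap) plus a GMT collection.

    List members are drawn without replacement from the data genes plus a
    decoy-symbol background, with true-DE genes weighted ``lit_enrichment``
    times the background weight.  The pathway collection holds random gene
    sets and one planted set dominated by true-DE genes.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    genes = truth.genes
    data_symbols = [s for s, a in zip(genes["symbol"], genes["accession"])
                    if not a.startswith("CONT")]
    data_symbols = list(dict.fromkeys(data_symbols))
    decoys = [f"LIT{i:05d}" for i in range(cfg.n_decoy_symbols)]
    universe = np.array(data_symbols + decoys)
    true_de = truth.true_de_symbols()
    w = np.where(np.isin(universe, list(true_de)), cfg.lit_enrichment, 1.0)
    w = w / w.sum()

    n_a, n_b = cfg.lit_sizes
    total_needed = n_a + n_b - cfg.lit_overlap
    if total_needed > len(universe):
        raise ValueError("universe too small for requested literature lists")
    drawn = rng.choice(universe, size=total_needed, replace=False, p=w, shuffle=False)
    shared = set(drawn[: cfg.lit_overlap])
    only_a = set(drawn[cfg.lit_overlap: n_a])
    only_b = set(drawn[n_a: total_needed])
    list_a = ReferenceList("bccluster_like", frozenset(shared | only_a))
    list_b = ReferenceList("glad4u_like", frozenset(shared | only_b))

    genes["in_bccluster_like"] = genes["symbol"].str.upper().isin(list_a.genes)
    genes["in_glad4u_like"] = genes["symbol"].str.upper().isin(list_b.genes)

    pathways = {}
    pool = np.array(data_symbols)
    for i in range(cfg.n_pathways):
        size = int(rng.integers(cfg.pathway_size_range[0], cfg.pathway_size_range[1] + 1))
        members = rng.choice(pool, size=min(size, len(pool)), replace=False)
        pathways[f"PW_{i:03d}"] = frozenset(str(m) for m in members)
    de_pool = np.array(sorted(true_de))
    n_de = min(int(round(cfg.planted_pathway_size * cfg.planted_pathway_de_share)),
               len(de_pool))
    bg_pool = np.array([s for s in data_symbols if s not in true_de])
    planted = set(rng.choice(de_pool, size=n_de, replace=False)) | set(
        rng.choice(bg_pool, size=cfg.planted_pathway_size - n_de, replace=False)
    )
    pathways["PW_PLANTED"] = frozenset(str(m) for m in planted)
    return list_a, list_b, pathways


# ---------------------------------------------------------------------------
# workspace

def simulate_workspace(cfg: SimConfig, outdir) -> Path:
    """Write a self-contained analysis workspace (all inputs + truth + config)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets, truth = generate_proteome(cfg)
    rng_t = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    transcripts = generate_transcriptome(cfg, truth, rng_t)
    rng_l = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    list_a, list_b, pathways = generate_reference_and_pathways(cfg, truth, rng_l)

    for f, d in datasets.items():
        write_quant_table(d, outdir / f"quant_{f}.tsv",
                          header_comment=f"crossomics stage=simulate fraction={f}")
    with open(outdir / "transcripts.tsv", "w") as fh:
        fh.write("# crossomics stage=simulate transcript counts\n")
        transcripts.to_csv(fh, sep="\t")
    genes = truth.genes
    keep = ~genes["accession"].str.startswith("CONT")
    with open(outdir / "idmap.tsv", "w") as fh:
        fh.write("accession\tsymbol\n")
        for a, s in zip(genes.loc[keep, "accession"], genes.loc[keep, "symbol"]):
            fh.write(f"{a}\t{s}\n")
    with open(outdir / "signal_annotation.tsv", "w") as fh:
        fh.write("accession\thas_signal_peptide\n")
        for a, s in zip(genes.loc[keep, "accession"], genes.loc[keep, "signal_peptide"]):
            fh.write(f"{a}\t{int(s)}\n")
    with open(outdir / "contaminants.tsv", "w") as fh:
        fh.write("accession\tnote\n")
        for a in contaminant_accessions(cfg):
            fh.write(f"{a}\tspiked contaminant\n")
    for ref in (list_a, list_b):
        (outdir / f"reference_{ref.name}.txt").write_text(
            "\n".join(sorted(ref.genes)) + "\n"
        )
    write_gmt(pathways, outdir / "pathways.gmt")
    truth.to_tsv(outdir / "truth.tsv")
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(_config_dict(cfg), fh, sort_keys=True)
    return outdir


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
        elif isinstance(v, dict):
            d[k] = {str(kk): (vv.item() if hasattr(vv, "item") else vv)
                    for kk, vv in v.items()}
    return d


def signal_annotation_from_truth(truth: SimTruth) -> SignalAnnotation:
    g = truth.genes
    return SignalAnnotation(dict(zip(g["accession"], g["signal_peptide"])))
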