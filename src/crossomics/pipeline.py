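"""End-to-end orchestration: simulated or real workspace -> report bundle.

Stages run in a fixed order (normalize -> detect/filter -> enrichment ->
differential expression -> strategy matrix / verified set -> literature
overlap -> pathway over-representation -> summary); every output file
carries a header naming the producing stage and the configuration hash, and
all stages are deterministic given fixed inputs.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, integrate, literature, quant

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "fc_threshold": 1.5,
    "alpha": 0.05,
    "p_rule": "strict_less",
    "use_fdr": False,
    "min_support": 2,
    "universe": "quantified",   # union of retained proteins across fractions
    "top_k_pathways": 15,
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def load_config(path) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    with open(path) as fh:
        cfg.update(yaml.safe_load(fh) or {})
    return cfg


def config_hash(cfg: dict) -> str:
    """Hash of the analysis-relevant configuration (output location excluded)."""
    material = {k: v for k, v in cfg.items() if k != "outdir"}
    return hashlib.md5(
        yaml.safe_dump(material, sort_keys=True).encode()
    ).hexdigest()[:12]


def workspace_config(workspace, outdir=None, **overrides) -> dict:
    """Pipeline configuration pointing at a simulated workspace directory."""
    ws = Path(workspace)
    cfg = dict(DEFAULT_CONFIG)
    cfg.update({
        "quant_tables": {f: str(ws / f"quant_{f}.tsv") for f in quant.FRACTIONS},
        "contaminants": str(ws / "contaminants.tsv"),
        "signal_annotation": str(ws / "signal_annotation.tsv"),
        "idmap": str(ws / "idmap.tsv"),
        "transcripts": str(ws / "transcripts.tsv"),
        "references": [str(p) for p in sorted(ws.glob("reference_*.txt"))],
        "pathways": str(ws / "pathways.gmt"),
        "outdir": str(outdir if outdir is not None else ws / "results"),
    })
    cfg.update(overrides)
    return cfg


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


@_stage("normalize")
def stage_normalize(cfg: dict):
    """Read, decontaminate, ppm-normalize and filter every fraction."""
    contaminants = (
        quant.read_contaminant_list(cfg["contaminants"])
        if cfg.get("contaminants") else set()
    )
    out = {}
    for label, path in cfg["quant_tables"].items():
        d = quant.read_quant_table(path, label)
        d = quant.exclude_contaminants(d, contaminants)
        norm = quant.ppm_normalize(d)
        mask = quant.detection_filter(d)
        imputed = quant.impute_missing(norm, mask)
        out[label] = {"raw": d, "norm": norm, "mask": mask, "imputed": imputed}
    return out


@_stage("enrichment")
def stage_enrichment(cfg: dict, stages: dict):
    ann = quant.SignalAnnotation.from_tsv(cfg["signal_annotation"])
    reports = {}
    norms = {label: s["norm"] for label, s in stages.items()}
    markers = cfg.get("markers")
    for label, s in stages.items():
        reports[label] = quant.enrichment_report(
            s["norm"], s["mask"], ann, markers=markers, other_fractions=norms,
        )
    return reports


@_stage("de")
def stage_de(cfg: dict, stages: dict):
    decfg = diffexpr.DEConfig(
        fc_threshold=cfg["fc_threshold"], alpha=cfg["alpha"],
        p_rule=cfg["p_rule"], use_fdr=cfg["use_fdr"],
    )
    return {
        label: diffexpr.differential_expression(s["imputed"], s["mask"], decfg)
        for label, s in stages.items()
    }


@_stage("integrate")
def stage_integrate(cfg: dict, de_tables: dict):
    idmap = integrate.read_id_map(cfg["idmap"]) if cfg.get("idmap") else {}
    mrna = None
    if cfg.get("transcripts"):
        counts, groups = integrate.read_transcript_table(cfg["transcripts"])
        mrna = integrate.transcript_fold_change(
            counts, groups, fc_threshold=cfg["fc_threshold"]
        )
    matrix = integrate.build_strategy_matrix(de_tables, mrna, idmap)
    verified = integrate.verified_set(matrix, cfg["min_support"])
    suggestive = integrate.suggestive_support(matrix, de_tables, idmap)
    return matrix, verified, suggestive


@_stage("validate")
def stage_validate(cfg: dict, de_tables: dict, matrix, verified, idmap: dict):
    refs = [literature.ReferenceList.from_file(p) for p in cfg.get("references", [])]
    de_symbol_sets = {}
    for label, de in de_tables.items():
        called = de[de["passes_nominal"]]
        de_symbol_sets[label] = {
            idmap.get(a, a).upper() for a in called["accession"].astype(str)
        }
    compiled = set().union(*de_symbol_sets.values()) if de_symbol_sets else set()
    queries = dict(de_symbol_sets)
    queries["compiled"] = compiled
    queries["verified"] = set(verified.index)
    nonempty = {k: v for k, v in queries.items() if v}
    for k in queries.keys() - nonempty.keys():
        logger.info("query set %r is empty; skipped in overlap scoring", k)
    overlaps = literature.overlap_table(nonempty, refs) if refs else pd.DataFrame()

    ora = pd.DataFrame()
    ora_per_strategy = {}
    if cfg.get("pathways"):
        gene_sets = literature.read_gmt(cfg["pathways"])
        universe = set(matrix.index) if cfg["universe"] == "quantified" else set(
            literature.ReferenceList.from_file(cfg["universe"]).genes
        )
        logger.info("ORA universe: %d symbols (%s)", len(universe), cfg["universe"])
        ora = literature.fisher_ora(queries["verified"], gene_sets, universe)
        for label, q in de_symbol_sets.items():
            if q:
                ora_per_strategy[label] = literature.fisher_ora(q, gene_sets, universe)
    return overlaps, ora, ora_per_strategy


def run_pipeline(cfg: dict) -> dict:
    """Run every stage and write the report bundle to ``cfg['outdir']``.

    Returns a dict with all in-memory results plus the summary counts.
    """
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    h = config_hash(cfg)

    stages = stage_normalize(cfg)
    enrichment = stage_enrichment(cfg, stages) if cfg.get("signal_annotation") else {}
    de_tables = stage_de(cfg, stages)
    matrix, verified, suggestive = stage_integrate(cfg, de_tables)
    idmap = integrate.read_id_map(cfg["idmap"]) if cfg.get("idmap") else {}
    overlaps, ora, ora_per_strategy = stage_validate(
        cfg, de_tables, matrix, verified, idmap
    )

    for label, s in stages.items():
        with open(outdir / f"ppm_{label}.tsv", "w") as fh:
            fh.write(f"# crossomics stage=normalize config={h}\n")
            s["imputed"].ppm.to_csv(fh, sep="\t")
        mask_df = pd.DataFrame({
            "retained": s["mask"].retained,
            "exclusivity": s["mask"].exclusivity,
        })
        with open(outdir / f"detection_{label}.tsv", "w") as fh:
            fh.write(f"# crossomics stage=normalize config={h}\n")
            mask_df.to_csv(fh, sep="\t")
        diffexpr.write_de_table(
            de_tables[label], outdir / f"de_{label}.tsv",
            header_comment=f"crossomics stage=de config={h}",
        )
    for label, rep in enrichment.items():
        (outdir / f"enrichment_{label}.txt").write_text(
            f"# crossomics stage=enrichment config={h}\n" + rep.formatted() + "\n"
        )
    integrate.write_strategy_matrix(
        matrix, outdir / "strategy_matrix.tsv",
        header_comment=f"crossomics stage=integrate config={h}",
    )
    integrate.write_strategy_matrix(
        verified, outdir / "verified_set.tsv",
        header_comment=f"crossomics stage=integrate config={h}",
    )
    if len(suggestive):
        literature.write_report(
            suggestive, outdir / "suggestive_support.tsv",
            header_comment=f"crossomics stage=integrate config={h}",
        )
    if len(overlaps):
        literature.write_report(
            overlaps, outdir / "literature_overlap.tsv",
            header_comment=f"crossomics stage=validate config={h}",
        )
    if len(ora):
        literature.write_report(
            ora, outdir / "pathway_ora.tsv",
            header_comment=f"crossomics stage=validate config={h}",
        )
        if ora_per_strategy:
            cmp_tab = literature.rank_comparison(
                ora, ora_per_strategy, top_k=cfg["top_k_pathways"]
            )
            literature.write_report(
                cmp_tab, outdir / "pathway_rank_comparison.tsv",
                header_comment=f"crossomics stage=validate config={h}",
            )

    summary = _summary(cfg, stages, enrichment, de_tables, matrix, verified)
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(f"# crossomics stage=report config={h}\n")
        for k, v in summary.items():
            fh.write(f"{k}: {v}\n")
    with open(outdir / "resolved_config.yaml", "w") as fh:
        fh.write(f"# crossomics stage=report config={h}\n")
        yaml.safe_dump(cfg, fh, sort_keys=True)

    return {
        "stages": stages, "enrichment": enrichment, "de": de_tables,
        "matrix": matrix, "verified": verified, "suggestive": suggestive,
        "overlaps": overlaps, "ora": ora, "summary": summary,
    }


def _summary(cfg, stages, enrichment, de_tables, matrix, verified) -> dict:
    summary = {}
    retained_sets = {}
    for label, s in stages.items():
        retained_sets[label] = set(s["mask"].retained_accessions())
        summary[f"retained_{label}"] = len(retained_sets[label])
        counts = diffexpr.de_summary(de_tables[label], use_fdr=cfg["use_fdr"])
        summary[f"de_{label}"] = (
            f"{counts['total']} ({counts['up']} up, {counts['down']} down)"
        )
    if len(retained_sets) >= 2:
        regions = quant.core_proteome(retained_sets)
        core = regions.get(tuple(sorted(retained_sets)), 0)
        summary["core_proteome"] = core
    for label, rep in enrichment.items():
        summary[f"signal_pct_{label}"] = round(rep.pct_signal_proteins, 1)
    stats = integrate.integration_summary(matrix, cfg["min_support"])
    summary.update({
        "compiled_de_features": len(
            set().union(*(
                set(de[de["passes_nominal"]]["accession"]) for de in de_tables.values()
            ))
        ) if de_tables else 0,
        "verified": stats["verified"],
        "verified_all4": stats["all4"],
        "verified_two_or_three": stats["two_or_three"],
        "cross_validated_proteomics": stats["cross_validated_proteomics"],
        "conflicting_trends": stats["conflicting"],
    })
    return summary
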