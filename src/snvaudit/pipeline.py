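"""Stage orchestration: config, sequencing, reports.

``run`` executes the enabled stages in dependency order (classify →
evaluate / conservation / sites → genes → polycomb), writes one TSV per
report plus a machine-readable ``summary.json`` holding every statistic
and p-value (including comparisons reported missing, so silent omission
is impossible), and a run log recording the resolved configuration and
its hash. All stages are deterministic given the inputs; re-running
reproduces integer counts exactly and floating statistics to 1e-9.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons_mod
from . import gene_level, polycomb, site_stats, tool_evaluation
from .variant_model import (
    DEFAULT_TERM_MAP,
    TOOLS,
    ParsedVariant,
    SiteAnnotation,
    annotate_sites,
    call_tool,
    parse_variant_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "variant_labels", "build_calls", "load_quartets"]

ALL_STAGES = ("classify", "evaluate", "conservation", "sites", "genes", "polycomb")


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    variants: str
    out: str
    genes: str | None = None
    expression: str | None = None
    degrees: str | None = None
    chromatin: str | None = None
    quartets: str | None = None
    term_map: dict[str, str] | None = None
    thresholds: dict[str, float] | None = None
    conservation_cutoff: float = 0.5
    conservation_clade: str = "vertebrate"
    sens_prop: float = 0.30
    tol_min_poly: int = 50
    ref_conventions: tuple[str, ...] = ("zero", "mean-of-alts")
    states: dict[str, object] = field(
        default_factory=lambda: {
            "ReprPC": "ReprPC",
            "ReprPCWk": "ReprPCWk",
            "ReprPC_or_Wk": ("ReprPC", "ReprPCWk"),
        }
    )
    covered_only: bool = False
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if not (0.0 < self.conservation_cutoff < 1.0):
            raise ValueError("conservation_cutoff must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("ref_conventions", "stages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "states" in raw and raw["states"] is not None:
            raw["states"] = {
                k: tuple(v) if isinstance(v, list) else v for k, v in raw["states"].items()
            }
        return cls(**raw)


def variant_labels(
    variants: Sequence[ParsedVariant],
    annotations: Mapping[tuple[str, int], SiteAnnotation],
) -> tuple[list[str | None], list[str | None]]:
    """Per-variant truth labels for the two analysis arms.

    ClinVar arm: the site group when it is pathogenic/benign, else None
    (sites "both"/"other" are excluded from evaluation truth). HGMD arm:
    pathogenic for variants at DM-flagged sites, benign for variants at
    ClinVar-benign non-DM sites, else None.
    """
    clinvar: list[str | None] = []
    hgmd: list[str | None] = []
    for pv in variants:
        ann = annotations[pv.record.site_key]
        clinvar.append(ann.group if ann.group in ("pathogenic", "benign") else None)
        if ann.is_dm:
            hgmd.append("pathogenic")
        elif ann.group == "benign":
            hgmd.append("benign")
        else:
            hgmd.append(None)
    return clinvar, hgmd


def build_calls(
    variants: Sequence[ParsedVariant],
    thresholds: Mapping[str, float] | None = None,
) -> dict[str, list[str]]:
    """Per-tool binary calls for every variant (missing scores propagate)."""
    return {
        tool: [call_tool(pv.scores.get(tool), tool, thresholds) for pv in variants]
        for tool in TOOLS
    }


def load_quartets(path: str | Path) -> pd.DataFrame:
    """Read the long-format quartet table (site x tool x alt rows)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "tool", "alt", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"quartet table lacks column(s): {sorted(missing)}")
    return df


def _metrics_row(tool: str, table: tool_evaluation.ConfusionTable) -> dict[str, object]:
    m = tool_evaluation.metrics(table)
    return {
        "tool": tool,
        "tp": table.tp, "fp": table.fp, "tn": table.tn, "fn": table.fn,
        "unclassified": table.unclassified,
        "sensitivity": m.sensitivity, "specificity": m.specificity,
        "accuracy": m.accuracy,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return None if (isinstance(obj, float) and obj != obj) or (
            isinstance(obj, np.floating) and np.isnan(obj)
        ) else float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run(config: RunConfig) -> dict:
    """Execute the enabled stages and assemble the report bundle.

    Returns the summary dictionary (also written to ``summary.json``).
    A stage failure aborts with the stage named; the partial summary is
    flagged incomplete and still written.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    term_map = config.term_map or DEFAULT_TERM_MAP
    summary: dict = {"stages": [], "incomplete": False}

    resolved = dataclasses.asdict(config)
    resolved["term_map"] = dict(term_map)
    resolved_text = json.dumps(_jsonable(resolved), sort_keys=True)
    summary["config"] = _jsonable(resolved)
    summary["config_hash"] = hashlib.sha256(resolved_text.encode()).hexdigest()
    summary["seed"] = config.seed
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"config_hash\t{summary['config_hash']}\n")
        fh.write(f"seed\t{config.seed}\n")
        fh.write(resolved_text + "\n")

    # shared state across stages
    variants: list[ParsedVariant] = []
    annotations: dict[tuple[str, int], SiteAnnotation] = {}
    calls: dict[str, list[str]] = {}
    labels_clinvar: list[str | None] = []
    labels_hgmd: list[str | None] = []

    def _stage_classify() -> None:
        nonlocal variants, annotations, calls, labels_clinvar, labels_hgmd
        result = parse_variant_table(config.variants)
        if result.errors:
            logger.warning("%d malformed rows in %s", len(result.errors), config.variants)
        variants = result.variants
        annotations = annotate_sites(variants, term_map)
        calls = build_calls(variants, config.thresholds)
        labels_clinvar, labels_hgmd = variant_labels(variants, annotations)
        sites_df = pd.DataFrame(
            {
                "chrom": [a.chrom for a in annotations.values()],
                "pos": [a.pos for a in annotations.values()],
                "group": [a.group for a in annotations.values()],
                "is_dm": [int(a.is_dm) for a in annotations.values()],
            }
        )
        sites_df.to_csv(out / "sites.tsv", sep="\t", index=False)
        calls_df = pd.DataFrame(
            {
                "chrom": [pv.record.chrom for pv in variants],
                "pos": [pv.record.pos for pv in variants],
                "alt": [pv.record.alt for pv in variants],
                "label_clinvar": [x or "." for x in labels_clinvar],
                "label_hgmd": [x or "." for x in labels_hgmd],
                **calls,
            }
        )
        calls_df.to_csv(out / "calls.tsv", sep="\t", index=False)
        summary["classify"] = {
            "n_variants": len(variants),
            "n_sites": len(annotations),
            "n_parse_errors": len(result.errors),
            "site_groups": dict(
                pd.Series([a.group for a in annotations.values()]).value_counts()
            ),
            "n_dm_sites": int(sum(a.is_dm for a in annotations.values())),
        }

    def _labeled(labels: Sequence[str | None]):
        idx = [i for i, lab in enumerate(labels) if lab is not None]
        sub_labels = [labels[i] for i in idx]
        sub_calls = {t: [calls[t][i] for i in idx] for t in TOOLS}
        return idx, sub_labels, sub_calls

    def _stage_evaluate() -> None:
        _, sub_labels, sub_calls = _labeled(labels_clinvar)
        per_tool = []
        for tool in TOOLS:
            table = tool_evaluation.confusion(sub_calls[tool], sub_labels)
            per_tool.append(_metrics_row(tool, table))
        pd.DataFrame(per_tool).to_csv(out / "tool_metrics.tsv", sep="\t", index=False)
        agreement = tool_evaluation.pairwise_agreement(sub_calls)
        agreement.to_csv(out / "pairwise_agreement.tsv", sep="\t")
        results = tool_evaluation.scan_combinations(TOOLS, sub_calls, sub_labels)
        tool_evaluation.results_to_frame(results).to_csv(
            out / "combination_scan.tsv", sep="\t", index=False
        )
        by_size = tool_evaluation.summarize_by_size(results)
        by_size.to_csv(out / "combinations_by_size.tsv", sep="\t", index=False)
        off_diag = agreement.to_numpy()[~np.eye(len(TOOLS), dtype=bool)]
        summary["evaluate"] = {
            "n_labeled": len(sub_labels),
            "n_combinations": len(results),
            "agreement_min": float(np.nanmin(off_diag)),
            "agreement_max": float(np.nanmax(off_diag)),
            "per_tool": {row["tool"]: row for row in per_tool},
            "by_size": by_size.to_dict(orient="records"),
        }

    def _conservation_vector() -> list[float | None]:
        return [
            pv.conservation.phastcons.get(config.conservation_clade) for pv in variants
        ]

    def _stage_conservation() -> None:
        cons_vec = _conservation_vector()
        labels_by_arm = {"clinvar": labels_clinvar, "hgmd_dm": labels_hgmd}
        # error_conservation_profile skips unlabeled entries via truth-class filter
        table_rows = []
        for arm, labels in labels_by_arm.items():
            idx = [i for i, lab in enumerate(labels) if lab is not None]
            arm_labels = [labels[i] for i in idx]
            arm_cons = [cons_vec[i] for i in idx]
            arm_calls = {t: [calls[t][i] for i in idx] for t in TOOLS}
            df = cons_mod.conservation_error_table(
                arm_calls, {arm: arm_labels}, arm_cons, cutoff=config.conservation_cutoff
            )
            table_rows.append(df)
        enrich = pd.concat(table_rows, ignore_index=True)
        enrich.to_csv(out / "conservation_enrichment.tsv", sep="\t", index=False)
        phylop = cons_mod.phylop_sign_summary(
            variants, {k: a.group for k, a in annotations.items()}
        )
        phylop.to_csv(out / "phylop_summary.tsv", sep="\t", index=False)
        back_table, back_summary = cons_mod.back_mutation_report(variants, term_map=term_map)
        back_table.to_csv(out / "back_mutations.tsv", sep="\t", index=False)
        summary["conservation"] = {
            "enrichment": enrich.to_dict(orient="records"),
            "back_mutations": back_summary,
        }

    def _stage_sites() -> None:
        if config.quartets is None:
            summary["sites"] = {"skipped": "no quartet table configured"}
            return
        quartets = load_quartets(config.quartets)
        if "group" not in quartets.columns or "is_dm" not in quartets.columns:
            key_series = list(
                zip(quartets["chrom"].astype(str), quartets["pos"].astype(int))
            )
            if "group" not in quartets.columns:
                quartets["group"] = [
                    annotations[k].group if k in annotations else "other" for k in key_series
                ]
            if "is_dm" not in quartets.columns:
                quartets["is_dm"] = [
                    int(annotations[k].is_dm) if k in annotations else 0 for k in key_series
                ]
        cons_by_site = {
            key: ann.conservation.phastcons.get(config.conservation_clade)
            for key, ann in annotations.items()
        }
        stat_frames = []
        comparisons = []
        correlations = {}
        for convention in config.ref_conventions:
            stats_df = site_stats.quartet_table_stats(quartets, ref_convention=convention)
            stats_df["cons"] = [
                cons_by_site.get((str(c), int(p)))
                for c, p in zip(stats_df["chrom"], stats_df["pos"])
            ]
            stat_frames.append(stats_df.drop(columns="cons"))
            for tool, tool_df in stats_df.groupby("tool", sort=True):
                for stat in ("max", "cv"):
                    values = tool_df[stat].to_numpy(dtype=float)
                    keep = ~np.isnan(values)
                    values_by_group: dict[str, np.ndarray] = {}
                    for g in ("pathogenic", "benign", "both", "other"):
                        values_by_group[g] = values[keep & (tool_df["group"] == g).to_numpy()]
                    values_by_group["DM"] = values[keep & (tool_df["is_dm"] == 1).to_numpy()]
                    cmp_df = site_stats.compare_groups(values_by_group)
                    cmp_df.insert(0, "statistic", stat)
                    cmp_df.insert(0, "tool", tool)
                    cmp_df.insert(0, "convention", convention)
                    comparisons.append(cmp_df)
                    cons_values = tool_df["cons"].to_numpy(dtype=float)
                    pair = keep & ~np.isnan(cons_values)
                    corr = site_stats.stat_conservation_correlation(
                        values[pair], cons_values[pair]
                    )
                    correlations[f"{convention}/{tool}/{stat}"] = (
                        None if corr is None else {"r": corr[0], "p": corr[1]}
                    )
        pd.concat(stat_frames, ignore_index=True).to_csv(
            out / "site_statistics.tsv", sep="\t", index=False
        )
        cmp_all = pd.concat(comparisons, ignore_index=True)
        cmp_all.to_csv(out / "site_stat_comparisons.tsv", sep="\t", index=False)
        summary["sites"] = {
            "comparisons": cmp_all.to_dict(orient="records"),
            "conservation_correlations": correlations,
        }

    def _stage_genes() -> None:
        if config.genes is None:
            summary["genes"] = {"skipped": "no gene table configured"}
            return
        gene_table = pd.read_csv(config.genes, sep="\t")
        expression = (
            pd.read_csv(config.expression, sep="\t", index_col=0)
            if config.expression
            else None
        )
        degrees = None
        if config.degrees:
            deg_df = pd.read_csv(config.degrees, sep="\t")
            degrees = dict(zip(deg_df["gene"].astype(str), deg_df["degree"].astype(int)))
        summaries = gene_level.build_gene_summaries(
            variants, gene_table, expression, degrees, term_map
        )
        rank_fractions = gene_level.ranked_degree(
            {g: s.ppi_degree for g, s in summaries.items()}
        )
        rows = []
        for g, s in summaries.items():
            rows.append(
                {
                    "gene": g,
                    "exon_length_bp": s.exon_length_bp,
                    "n_polymorphic": s.n_polymorphic,
                    "snv_rate_per_kb": gene_level.snv_rate(s),
                    "n_pathogenic_sites": s.n_pathogenic_sites,
                    "n_dm_sites": s.n_dm_sites,
                    "n_annotated_sites": s.n_annotated_sites,
                    "susceptibility": gene_level.classify_susceptibility(
                        s, sens_prop=config.sens_prop, tol_min_poly=config.tol_min_poly
                    ),
                    "expression_max": (
                        gene_level.expression_max(s.expression) if s.expression else None
                    ),
                    "tissue_specificity": (
                        gene_level.tissue_specificity(s.expression) if s.expression else None
                    ),
                    "ppi_degree": s.ppi_degree,
                    "ranked_degree": rank_fractions.get(g),
                }
            )
        per_gene = pd.DataFrame(rows)
        per_gene.to_csv(out / "gene_summaries.tsv", sep="\t", index=False)
        cmp = pd.concat(
            [
                gene_level.gene_group_comparisons(summaries, arm="clinvar"),
                gene_level.gene_group_comparisons(summaries, arm="hgmd"),
            ],
            ignore_index=True,
        )
        cmp.to_csv(out / "gene_group_comparisons.tsv", sep="\t", index=False)
        corr = gene_level.length_rate_correlation(summaries)
        rates = per_gene.loc[per_gene["n_polymorphic"] > 0, "snv_rate_per_kb"]
        summary["genes"] = {
            "n_genes": len(per_gene),
            "susceptibility_counts": dict(per_gene["susceptibility"].value_counts()),
            "snv_rate_mean": float(rates.mean()) if len(rates) else None,
            "snv_rate_min": float(rates.min()) if len(rates) else None,
            "snv_rate_max": float(rates.max()) if len(rates) else None,
            "length_rate_correlation": (
                None if corr is None else {"r": corr[0], "p": corr[1]}
            ),
            "comparisons": cmp.to_dict(orient="records"),
        }

    def _stage_polycomb() -> None:
        if config.chromatin is None:
            summary["polycomb"] = {"skipped": "no chromatin track configured"}
            return
        path = Path(config.chromatin)
        if path.is_dir():
            tracks = [polycomb.read_state_bed(p) for p in sorted(path.glob("*.bed"))]
        else:
            tracks = polycomb.read_concatenated_bed(path)
        keys = [
            key
            for key, ann in annotations.items()
            if ann.group in ("pathogenic", "benign") or ann.is_dm
        ]
        fractions = polycomb.state_fraction_table(
            keys, tracks, config.states, covered_only=config.covered_only
        )
        meta = pd.DataFrame(
            {
                "chrom": [k[0] for k in keys],
                "pos": [k[1] for k in keys],
                "group": [annotations[k].group for k in keys],
                "is_dm": [int(annotations[k].is_dm) for k in keys],
            }
        )
        fractions = meta.merge(fractions, on=["chrom", "pos"])
        fractions.to_csv(out / "polycomb_fractions.tsv", sep="\t", index=False)

        frac_by_key = fractions.set_index(
            fractions["chrom"].astype(str) + ":" + fractions["pos"].astype(str)
        )
        comparisons = []
        for state_name in config.states:
            by_group = {
                "pathogenic": fractions.loc[fractions["group"] == "pathogenic", state_name],
                "DM": fractions.loc[fractions["is_dm"] == 1, state_name],
                "benign": fractions.loc[
                    (fractions["group"] == "benign") & (fractions["is_dm"] == 0), state_name
                ],
            }
            cmp_df = polycomb.group_state_comparison(
                {k: v.to_numpy() for k, v in by_group.items()}
            )
            cmp_df.insert(0, "comparison", "site-class")
            cmp_df.insert(0, "tool", "")
            cmp_df.insert(0, "state", state_name)
            comparisons.append(cmp_df)
        # per tool: FN vs TP among pathogenic (ClinVar) and DM (HGMD) variants
        for arm, labels in (("clinvar", labels_clinvar), ("hgmd_dm", labels_hgmd)):
            for tool in TOOLS:
                fn_keys, tp_keys = [], []
                for i, pv in enumerate(variants):
                    if labels[i] != "pathogenic":
                        continue
                    call = calls[tool][i]
                    key = f"{pv.record.chrom}:{pv.record.pos}"
                    if key not in frac_by_key.index:
                        continue
                    if call == "benign":
                        fn_keys.append(key)
                    elif call == "pathogenic":
                        tp_keys.append(key)
                for state_name in config.states:
                    groups = {
                        "FN": frac_by_key.loc[
                            frac_by_key.index.isin(fn_keys), state_name
                        ].to_numpy(),
                        "TP": frac_by_key.loc[
                            frac_by_key.index.isin(tp_keys), state_name
                        ].to_numpy(),
                    }
                    cmp_df = polycomb.group_state_comparison(groups)
                    cmp_df.insert(0, "comparison", f"FN-vs-TP/{arm}")
                    cmp_df.insert(0, "tool", tool)
                    cmp_df.insert(0, "state", state_name)
                    comparisons.append(cmp_df)
        cmp_all = pd.concat(comparisons, ignore_index=True)
        cmp_all.to_csv(out / "polycomb_comparisons.tsv", sep="\t", index=False)
        summary["polycomb"] = {
            "n_sites": len(fractions),
            "n_epigenomes": len(tracks),
            "comparisons": cmp_all.to_dict(orient="records"),
        }

    stage_impl = {
        "classify": _stage_classify,
        "evaluate": _stage_evaluate,
        "conservation": _stage_conservation,
        "sites": _stage_sites,
        "genes": _stage_genes,
        "polycomb": _stage_polycomb,
    }
    enabled = [s for s in ALL_STAGES if s in config.stages]
    if enabled and enabled[0] != "classify":
        enabled = ["classify"] + enabled  # classify feeds every other stage

    for name in enabled:
        try:
            logger.info("running stage %s", name)
            stage_impl[name]()
            summary["stages"].append(name)
        except Exception as exc:
            summary["incomplete"] = True
            summary["failed_stage"] = name
            with open(out / "summary.json", "w") as fh:
                json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
            raise RuntimeError(f"stage {name!r} failed on input {config.variants}: {exc}") from exc

    summary = _jsonable(summary)  # NaN -> None, numpy scalars -> native
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
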