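"""Seeded synthetic cohort generator with planted, recoverable effects.

The generator emits the full input bundle the pipeline consumes — variant
table, gene metadata, expression matrix, PPI degrees, chromatin-state BED —
together with truth tables recording every planted class and effect, so
each analysis stage can be scored against a known ground truth.

Planted structure (each knob can be set to zero for a null generator):

* **conservation over-reliance** — for the configured tools, scores are a
  convex mixture of the class score and the site's vertebrate phastCons
  value, so benign variants at conserved positions draw false positives
  and pathogenic variants at unconserved positions draw false negatives;
* **four-allele statistics** — pathogenic-class sites draw their three
  alternative-allele scores with a higher location and a lower relative
  dispersion than benign-class sites, shifting the per-site maximum up and
  the coefficient of variation down; the score model is multiplicative
  (score = location x (1 + dispersion x noise)), so the CV — a scale-free
  statistic — responds to the dispersion knob only and the two effects are
  exactly separable;
* **gene-level susceptibility** — a per-gene latent propensity couples the
  allocation of pathogenic sites to expression abundance, tissue
  specificity and PPI degree;
* **PolyComb upshift** — pathogenic sites at low conservation (the sites
  the over-reliant tools will miss) get an upshifted probability of the
  repressed-PolyComb states across epigenomes.

All randomness flows from a single seed through ``SeedSequence.spawn``:
one child stream per stage (genes, sites, scores, conservation, ancestral,
expression, chromatin), so sub-bundles are reproducible independently.
Generated files round-trip through the package's own readers, and the same
seed yields byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .variant_model import NUCLEOTIDES, TOOLS

__all__ = ["CohortConfig", "CohortBundle", "generate_bundle", "generate_cohort",
           "generate_nondegenerate_quartets", "null_config"]

_BACKGROUND_STATES = ("Quies", "TssA", "Enh", "Tx")
_BACKGROUND_PROBS = (0.7, 0.1, 0.1, 0.1)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort. ``seed`` is mandatory."""

    seed: int

    # cohort size
    n_genes: int = 500
    mean_variants_per_gene: float = 4.0

    # four-group site class fractions (must sum to 1)
    fraction_pathogenic: float = 0.22
    fraction_benign: float = 0.33
    fraction_both: float = 0.03
    fraction_other: float = 0.42

    # HGMD DM flags
    dm_given_pathogenic: float = 0.6
    dm_given_other: float = 0.02

    # tool score model. Each (site, tool) has a location m drawn from a
    # Beta around the class mean; the three alternative-allele scores are
    # m * (1 + disp * eps) with eps ~ Uniform(-1, 1). Because the quartet
    # CV = sigma/mu is scale-free, it depends only on the relative
    # dispersion disp and not on m — so the location and dispersion effect
    # knobs are exactly separable: the location effect moves the quartet
    # maximum without touching the CV distribution.
    benign_score_mean: float = 0.42
    other_score_mean: float = 0.38
    both_score_mean: float = 0.55
    score_site_spread: float = 10.0   # Beta concentration of the per-site location
    benign_score_disp: float = 0.28   # relative within-site dispersion, non-pathogenic
    quartet_location_effect: float = 0.36   # pathogenic mean - benign mean
    quartet_dispersion_effect: float = 0.20  # benign disp - pathogenic disp
    tool_mean_jitter: float = 0.08  # deterministic per-tool spread of class means
    score_missing_rate: float = 0.03

    # conservation model
    pathogenic_high_cons_frac: float = 0.8
    benign_high_cons_frac: float = 0.4
    both_high_cons_frac: float = 0.6
    other_high_cons_frac: float = 0.5
    conservation_missing_rate: float = 0.02

    # planted conservation over-reliance
    overreliant_tools: tuple[str, ...] = ("SIFT", "PROVEAN", "MutationTaster")
    overreliance_weight: float = 0.6

    # ancestral calls
    back_mutation_rate: float = 0.01
    low_confidence_rate: float = 0.1

    # non-degenerate flag
    nondegenerate_fraction: float = 0.75

    # gene level
    n_tissues: int = 53
    gene_trait_coupling: float = 0.75
    gene_pathogenic_coupling: float = 1.2

    # chromatin states
    n_epigenomes: int = 127
    polycomb_pc_base: float = 0.12
    polycomb_wk_base: float = 0.12
    fn_polycomb_shift: float = 0.25

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("field 'seed' is mandatory")
        fractions = (
            self.fraction_pathogenic + self.fraction_benign
            + self.fraction_both + self.fraction_other
        )
        if abs(fractions - 1.0) > 1e-9:
            raise ValueError("fields 'fraction_*' must sum to 1")
        for name in ("n_genes", "n_tissues", "n_epigenomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"field {name!r} must be >= 1")
        for name in (
            "dm_given_pathogenic", "dm_given_other", "score_missing_rate",
            "pathogenic_high_cons_frac", "benign_high_cons_frac",
            "both_high_cons_frac", "other_high_cons_frac",
            "conservation_missing_rate", "overreliance_weight",
            "back_mutation_rate", "low_confidence_rate",
            "nondegenerate_fraction", "polycomb_pc_base", "polycomb_wk_base",
            "fn_polycomb_shift",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"field {name!r} must lie in [0, 1], got {value}")
        for name in ("benign_score_mean", "other_score_mean", "both_score_mean"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"field {name!r} must lie in (0, 1)")
        if not (0.0 < self.benign_score_mean + self.quartet_location_effect < 1.0):
            raise ValueError("field 'quartet_location_effect' pushes the pathogenic mean outside (0, 1)")
        if not (0.0 <= self.benign_score_disp < 1.0):
            raise ValueError("field 'benign_score_disp' must lie in [0, 1)")
        if not (0.0 <= self.quartet_dispersion_effect <= self.benign_score_disp):
            raise ValueError(
                "field 'quartet_dispersion_effect' must lie in [0, benign_score_disp]"
            )
        if self.score_site_spread <= 0:
            raise ValueError("field 'score_site_spread' must be positive")
        unknown = set(self.overreliant_tools) - set(TOOLS)
        if unknown:
            raise ValueError(f"field 'overreliant_tools' has unknown tools {sorted(unknown)}")

    @property
    def pathogenic_score_mean(self) -> float:
        return self.benign_score_mean + self.quartet_location_effect

    @property
    def pathogenic_score_disp(self) -> float:
        return self.benign_score_disp - self.quartet_dispersion_effect

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "overreliant_tools" in raw and raw["overreliant_tools"] is not None:
            raw["overreliant_tools"] = tuple(raw["overreliant_tools"])
        return cls(**raw)


def null_config(seed: int, **overrides) -> CohortConfig:
    """A configuration with every planted effect switched off."""
    params = dict(
        seed=seed,
        overreliance_weight=0.0,
        quartet_location_effect=0.0,
        quartet_dispersion_effect=0.0,
        gene_pathogenic_coupling=0.0,
        fn_polycomb_shift=0.0,
    )
    params.update(overrides)
    return CohortConfig(**params)


@dataclass
class CohortBundle:
    """In-memory cohort: the tables that :func:`generate_cohort` writes."""

    config: CohortConfig
    variants: pd.DataFrame
    genes: pd.DataFrame
    expression: pd.DataFrame
    degrees: pd.DataFrame
    chromatin: pd.DataFrame
    quartets: pd.DataFrame
    truth_sites: pd.DataFrame
    truth_genes: pd.DataFrame


def _tool_means(cfg: CohortConfig, base_mean: float) -> np.ndarray:
    """Deterministic per-tool class means: the base spread across the panel."""
    k = len(TOOLS)
    offsets = cfg.tool_mean_jitter * (2.0 * np.arange(k) / (k - 1) - 1.0)
    return np.clip(base_mean + offsets, 0.05, 0.95)


def _draw_beta(rng: np.random.Generator, mean: np.ndarray, conc: float, size) -> np.ndarray:
    a = np.broadcast_to(mean, size) * conc
    b = (1.0 - np.broadcast_to(mean, size)) * conc
    return rng.beta(a, b)


def _draw_phastcons(rng: np.random.Generator, n: int, high_frac: float) -> np.ndarray:
    """Mixture of a conserved (Beta(10,2)) and an unconserved (Beta(2,10)) mode."""
    high = rng.random(n) < high_frac
    out = np.where(high, rng.beta(10, 2, n), rng.beta(2, 10, n))
    return out


def generate_bundle(cfg: CohortConfig) -> CohortBundle:
    """Generate the full cohort in memory (deterministic given cfg.seed)."""
    root = np.random.SeedSequence(cfg.seed)
    (ss_genes, ss_sites, ss_scores, ss_cons,
     ss_ancestral, ss_expr, ss_chrom) = root.spawn(7)
    rng_genes = np.random.default_rng(ss_genes)
    rng_sites = np.random.default_rng(ss_sites)
    rng_scores = np.random.default_rng(ss_scores)
    rng_cons = np.random.default_rng(ss_cons)
    rng_anc = np.random.default_rng(ss_ancestral)
    rng_expr = np.random.default_rng(ss_expr)
    rng_chrom = np.random.default_rng(ss_chrom)

    # ------------------------------------------------------------------ genes
    n_genes = cfg.n_genes
    gene_names = np.array([f"G{i:04d}" for i in range(n_genes)])
    z = rng_genes.standard_normal(n_genes)
    exon_length = np.maximum(
        300, np.round(rng_genes.lognormal(np.log(1500), 0.5, n_genes))
    ).astype(int)
    # polymorphic-site rates per Kb: 15 + Gamma(2, 7.5), capped at 80
    rate_per_kb = np.minimum(15.0 + rng_genes.gamma(2.0, 7.5, n_genes), 80.0)
    n_polymorphic = rng_genes.poisson(exon_length / 1000.0 * rate_per_kb)

    rho = cfg.gene_trait_coupling
    noise = rng_genes.standard_normal((3, n_genes))
    latent = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
    # expression: total abundance and dominant-tissue share both follow the latent
    total_abundance = np.exp(2.0 + 1.2 * latent[0])
    dominant_share = 1.0 / (1.0 + np.exp(-(0.0 + 1.5 * latent[1])))
    dominant_share = np.clip(dominant_share, 1.0 / cfg.n_tissues + 1e-6, 0.999)
    dominant_tissue = rng_expr.integers(0, cfg.n_tissues, n_genes)
    rest = rng_expr.dirichlet(np.ones(cfg.n_tissues - 1), size=n_genes)
    expression = np.empty((n_genes, cfg.n_tissues))
    for i in range(n_genes):
        p = np.empty(cfg.n_tissues)
        others = [t for t in range(cfg.n_tissues) if t != dominant_tissue[i]]
        p[dominant_tissue[i]] = dominant_share[i]
        p[others] = (1.0 - dominant_share[i]) * rest[i]
        expression[i] = total_abundance[i] * p
    degree = np.maximum(1, np.round(np.exp(1.5 + 0.9 * latent[2]))).astype(int)

    # ------------------------------------------------------------------ sites
    n_per_gene = rng_sites.poisson(cfg.mean_variants_per_gene, n_genes)
    gene_of_site = np.repeat(np.arange(n_genes), n_per_gene)
    n_sites = gene_of_site.size
    fractions = np.array([
        cfg.fraction_pathogenic, cfg.fraction_benign,
        cfg.fraction_both, cfg.fraction_other,
    ])
    class_counts = rng_sites.multinomial(n_sites, fractions)
    n_path = int(class_counts[0])
    site_class = np.full(n_sites, "other", dtype=object)
    # pathogenic sites land preferentially in high-propensity genes
    beta = cfg.gene_pathogenic_coupling
    weights = np.exp(beta * z[gene_of_site])
    path_idx = rng_sites.choice(
        n_sites, size=min(n_path, n_sites), replace=False, p=weights / weights.sum()
    )
    site_class[path_idx] = "pathogenic"
    remaining = np.setdiff1d(np.arange(n_sites), path_idx)
    remaining = rng_sites.permutation(remaining)
    n_ben, n_both = int(class_counts[1]), int(class_counts[2])
    site_class[remaining[:n_ben]] = "benign"
    site_class[remaining[n_ben:n_ben + n_both]] = "both"

    is_dm = np.zeros(n_sites, dtype=bool)
    is_path = site_class == "pathogenic"
    is_dm[is_path] = rng_sites.random(is_path.sum()) < cfg.dm_given_pathogenic
    non_path = ~is_path & (site_class != "both")
    is_dm[non_path] |= rng_sites.random(non_path.sum()) < cfg.dm_given_other

    # genomic layout: 22 chromosomes, one 1 Mb block per gene, sites 200 bp apart
    chrom_of_gene = (np.arange(n_genes) % 22 + 1).astype(str)
    block_of_gene = 1_000_000 + (np.arange(n_genes) // 22) * 1_000_000
    site_offset = np.concatenate([np.arange(k) for k in n_per_gene]) if n_sites else np.array([], int)
    chrom = chrom_of_gene[gene_of_site]
    pos = block_of_gene[gene_of_site] + site_offset * 200

    ref_idx = rng_sites.integers(0, 4, n_sites)
    ref = np.array(NUCLEOTIDES)[ref_idx]

    nondegenerate = rng_sites.random(n_sites) < cfg.nondegenerate_fraction

    # ----------------------------------------------------------- conservation
    high_frac = {
        "pathogenic": cfg.pathogenic_high_cons_frac,
        "benign": cfg.benign_high_cons_frac,
        "both": cfg.both_high_cons_frac,
        "other": cfg.other_high_cons_frac,
    }
    phastcons_vert = np.empty(n_sites)
    for cls, frac in high_frac.items():
        mask = site_class == cls
        phastcons_vert[mask] = _draw_phastcons(rng_cons, int(mask.sum()), frac)
    phastcons_mam = np.clip(phastcons_vert + rng_cons.normal(0, 0.08, n_sites), 0, 1)
    phastcons_pri = np.clip(phastcons_vert + rng_cons.normal(0, 0.12, n_sites), 0, 1)
    phylop_loc = {"pathogenic": 3.0, "benign": 0.5, "both": 1.5, "other": 1.0}
    phylop_base = np.empty(n_sites)
    for cls, loc in phylop_loc.items():
        mask = site_class == cls
        phylop_base[mask] = rng_cons.normal(loc, 1.6, int(mask.sum()))
    phylop_vert = phylop_base + rng_cons.normal(0, 0.5, n_sites)
    phylop_mam = phylop_base + rng_cons.normal(0, 0.5, n_sites)
    phylop_pri = phylop_base + rng_cons.normal(0, 0.5, n_sites)
    cons_missing = rng_cons.random(n_sites) < cfg.conservation_missing_rate

    # ------------------------------------------------------------- tool scores
    # per-(site, tool) location m around the class mean, then three
    # alternative-allele scores m * (1 + disp * eps); disp is the planted
    # relative dispersion (lower for the pathogenic class)
    class_mean = {
        "pathogenic": _tool_means(cfg, cfg.pathogenic_score_mean),
        "benign": _tool_means(cfg, cfg.benign_score_mean),
        "both": _tool_means(cfg, cfg.both_score_mean),
        "other": _tool_means(cfg, cfg.other_score_mean),
    }
    class_disp = {
        "pathogenic": cfg.pathogenic_score_disp,
        "benign": cfg.benign_score_disp,
        "both": cfg.benign_score_disp,
        "other": cfg.benign_score_disp,
    }
    k = len(TOOLS)
    location = np.empty((n_sites, k))
    disp_of_site = np.empty(n_sites)
    for cls in ("pathogenic", "benign", "both", "other"):
        mask = site_class == cls
        m = int(mask.sum())
        if m == 0:
            continue
        draw = _draw_beta(
            rng_scores, class_mean[cls][None, :], cfg.score_site_spread, (m, k)
        )
        # keep m * (1 + disp) inside [0, 1] so no clipping disturbs the CV
        location[mask] = np.minimum(draw, 1.0 / (1.0 + class_disp[cls] + 1e-9))
        disp_of_site[mask] = class_disp[cls]
    eps = rng_scores.uniform(-1.0, 1.0, (n_sites, k, 3))
    alt_scores = location[:, :, None] * (1.0 + disp_of_site[:, None, None] * eps)
    # planted over-reliance: mix scores toward the site's conservation value
    w = cfg.overreliance_weight
    if w > 0:
        over = np.array([t in cfg.overreliant_tools for t in TOOLS])
        alt_scores[:, over, :] = (
            (1.0 - w) * alt_scores[:, over, :]
            + w * phastcons_vert[:, None, None]
        )
    alt_scores = np.clip(alt_scores, 0.0, 1.0)

    # observed alternative allele(s): index into the 3 non-ref nucleotides
    obs_alt_choice = rng_scores.integers(0, 3, n_sites)
    # second allele for "both" sites
    second_alt_choice = (obs_alt_choice + 1 + rng_scores.integers(0, 2, n_sites)) % 3

    alt_nt_table = np.array([[nt for nt in NUCLEOTIDES if nt != r] for r in NUCLEOTIDES])
    site_alt_nts = alt_nt_table[ref_idx]  # (n_sites, 3)
    obs_alt = site_alt_nts[np.arange(n_sites), obs_alt_choice]
    second_alt = site_alt_nts[np.arange(n_sites), second_alt_choice]

    obs_scores = alt_scores[np.arange(n_sites), :, obs_alt_choice]  # (n_sites, k)
    second_scores = alt_scores[np.arange(n_sites), :, second_alt_choice]
    missing_mask = rng_scores.random((n_sites, k)) < cfg.score_missing_rate
    second_missing = rng_scores.random((n_sites, k)) < cfg.score_missing_rate

    # FN-prone pathogenic/DM sites: the weakly conserved ones the
    # conservation-leaning tools will miss; they receive the PolyComb upshift
    fn_prone = (is_path | is_dm) & (phastcons_vert < 0.5)

    # --------------------------------------------------------------- ancestral
    anc_is_alt = rng_anc.random(n_sites) < cfg.back_mutation_rate
    anc_low_conf = rng_anc.random(n_sites) < cfg.low_confidence_rate
    ancestral = np.where(anc_is_alt, obs_alt, ref)
    ancestral = np.array(
        [a.lower() if low else a for a, low in zip(ancestral, anc_low_conf)]
    )

    # ------------------------------------------------------------ ClinVar/HGMD
    term_pick = rng_sites.random(n_sites)
    clinvar = np.full(n_sites, ".", dtype=object)
    clinvar[site_class == "pathogenic"] = np.where(
        term_pick[site_class == "pathogenic"] < 0.7, "Pathogenic", "Likely pathogenic"
    )
    clinvar[site_class == "benign"] = np.where(
        term_pick[site_class == "benign"] < 0.7, "Benign", "Likely benign"
    )
    other_mask = site_class == "other"
    clinvar[other_mask] = np.where(
        term_pick[other_mask] < 0.4, "Uncertain significance", "."
    )
    hgmd = np.where(is_dm, "DM", ".")

    # ----------------------------------------------------------- variant table
    def _fmt_scores(values: np.ndarray, missing: np.ndarray) -> np.ndarray:
        out = np.char.mod("%.6f", values)
        return np.where(missing, ".", out)

    obs_fmt = _fmt_scores(obs_scores, missing_mask)
    second_fmt = _fmt_scores(second_scores, second_missing)

    def _cons_col(values: np.ndarray) -> np.ndarray:
        return np.where(cons_missing, ".", np.char.mod("%.4f", values))

    pc_v, pc_m, pc_p = map(_cons_col, (phastcons_vert, phastcons_mam, phastcons_pri))
    pl_v, pl_m, pl_p = map(_cons_col, (phylop_vert, phylop_mam, phylop_pri))

    both_term = term_pick < 0.7
    is_both = site_class == "both"
    first_terms = np.where(
        is_both,
        np.where(both_term, "Pathogenic", "Likely pathogenic"),
        clinvar.astype(str),
    )
    second_terms = np.where(both_term, "Benign", "Likely benign")

    hgvs = np.char.add(
        np.char.add(np.char.add(np.char.mod("c.%d", site_offset + 1), ref), ">"), obs_alt
    )
    hgvs_second = np.char.add(
        np.char.add(np.char.add(np.char.mod("c.%d", site_offset + 1), ref), ">"), second_alt
    )

    def _site_frame(alt_col, term_col, score_fmt, hgvs_col, mask) -> pd.DataFrame:
        data = {
            "chrom": chrom[mask],
            "pos": pos[mask],
            "ref": ref[mask],
            "alt": alt_col[mask],
            "gene": gene_names[gene_of_site[mask]],
            "hgvs": hgvs_col[mask],
            "clinvar": term_col[mask],
            "hgmd_class": hgmd[mask],
            "ancestral": ancestral[mask],
            "nondegenerate": nondegenerate[mask].astype(int),
            "phastcons_vertebrate": pc_v[mask],
            "phastcons_mammal": pc_m[mask],
            "phastcons_primate": pc_p[mask],
            "phylop_vertebrate": pl_v[mask],
            "phylop_mammal": pl_m[mask],
            "phylop_primate": pl_p[mask],
        }
        for t_idx, tool in enumerate(TOOLS):
            data[tool] = score_fmt[mask, t_idx]
        df = pd.DataFrame(data)
        df["_order"] = 2 * np.flatnonzero(mask)
        return df

    all_mask = np.ones(n_sites, dtype=bool)
    first_df = _site_frame(obs_alt, first_terms, obs_fmt, hgvs, all_mask)
    second_df = _site_frame(second_alt, second_terms, second_fmt, hgvs_second, is_both)
    second_df["_order"] += 1
    variants = (
        pd.concat([first_df, second_df], ignore_index=True)
        .sort_values("_order", kind="mergesort")
        .drop(columns="_order")
        .reset_index(drop=True)
    )

    # --------------------------------------------------------------- quartets
    nd_idx = np.flatnonzero(nondegenerate)
    n_nd = nd_idx.size
    k3 = k * 3
    quartets = pd.DataFrame({
        "chrom": np.repeat(chrom[nd_idx], k3),
        "pos": np.repeat(pos[nd_idx], k3),
        "ref": np.repeat(ref[nd_idx], k3),
        "group": np.repeat(site_class[nd_idx].astype(str), k3),
        "is_dm": np.repeat(is_dm[nd_idx].astype(int), k3),
        "tool": np.tile(np.repeat(np.array(TOOLS), 3), n_nd),
        "alt": np.tile(site_alt_nts[nd_idx].reshape(n_nd, 1, 3), (1, k, 1)).ravel(),
        "score": np.char.mod("%.6f", alt_scores[nd_idx].ravel()),
    })

    # ------------------------------------------------------------- gene tables
    genes = pd.DataFrame({
        "gene": gene_names,
        "exon_length_bp": exon_length,
        "n_polymorphic": n_polymorphic,
    })
    expr = pd.DataFrame(
        np.round(expression, 4),
        index=pd.Index(gene_names, name="gene"),
        columns=[f"tissue_{j:02d}" for j in range(cfg.n_tissues)],
    )
    degrees = pd.DataFrame({"gene": gene_names, "degree": degree})

    # -------------------------------------------------------- chromatin states
    e = cfg.n_epigenomes
    q_pc = np.full(n_sites, cfg.polycomb_pc_base)
    q_wk = np.full(n_sites, cfg.polycomb_wk_base)
    q_pc = q_pc + cfg.fn_polycomb_shift * fn_prone
    q_wk = q_wk + cfg.fn_polycomb_shift * fn_prone
    q_pc = np.clip(q_pc, 0.0, 0.45)
    q_wk = np.clip(q_wk, 0.0, 0.45)

    u = rng_chrom.random((n_sites, e))
    in_pc = u < q_pc[:, None]
    in_wk = (~in_pc) & (u < (q_pc + q_wk)[:, None])
    bg_pick = rng_chrom.choice(
        len(_BACKGROUND_STATES), size=(n_sites, e), p=_BACKGROUND_PROBS
    ).astype(np.int8)
    state_labels = ["ReprPC", "ReprPCWk", *_BACKGROUND_STATES]
    state_codes = bg_pick + 2
    state_codes[in_pc] = 0
    state_codes[in_wk] = 1
    r1 = rng_chrom.integers(10, 80, (n_sites, e))
    r2 = rng_chrom.integers(10, 80, (n_sites, e))
    starts = pos[:, None] - 1 - r1
    ends = pos[:, None] + r2
    chrom_labels, chrom_codes = np.unique(chrom, return_inverse=True)
    chromatin = pd.DataFrame({
        "chrom": pd.Categorical.from_codes(
            np.repeat(chrom_codes, e), categories=list(chrom_labels)
        ),
        "start": starts.ravel(),
        "end": ends.ravel(),
        "state": pd.Categorical.from_codes(state_codes.ravel(), categories=state_labels),
        "epigenome": pd.Categorical.from_codes(
            np.tile(np.arange(e), n_sites), categories=[f"E{j + 1:03d}" for j in range(e)]
        ),
    })
    chromatin = chromatin.sort_values(
        ["epigenome", "chrom", "start"], kind="mergesort"
    ).reset_index(drop=True)

    # ------------------------------------------------------------ truth tables
    truth_sites = pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "gene": gene_names[gene_of_site],
        "class": site_class,
        "is_dm": is_dm.astype(int),
        "nondegenerate": nondegenerate.astype(int),
        "fn_prone": fn_prone.astype(int),
        "phastcons_vertebrate": np.round(phastcons_vert, 4),
        "back_mutation": anc_is_alt.astype(int),
    })
    truth_genes = pd.DataFrame({
        "gene": gene_names,
        "z": np.round(z, 4),
        "exon_length_bp": exon_length,
        "rate_per_kb": np.round(rate_per_kb, 3),
        "n_polymorphic": n_polymorphic,
        "degree": degree,
        "n_pathogenic_true": np.bincount(
            gene_of_site[is_path], minlength=n_genes
        ) if n_sites else np.zeros(n_genes, int),
    })

    return CohortBundle(
        config=cfg,
        variants=variants,
        genes=genes,
        expression=expr,
        degrees=degrees,
        chromatin=chromatin,
        quartets=quartets,
        truth_sites=truth_sites,
        truth_genes=truth_genes,
    )


def generate_cohort(cfg: CohortConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write the file bundle to ``outdir``.

    Returns a name -> path mapping. Files: ``variants.tsv``, ``genes.tsv``,
    ``expression.tsv``, ``degrees.tsv``, ``chromatin_states.bed``
    (concatenated BED with an epigenome column), ``quartets.tsv``,
    ``truth_sites.tsv``, ``truth_genes.tsv`` and the resolved config
    ``config.yaml``. Deterministic: the same seed yields byte-identical
    bundles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(cfg)
    paths = {
        "variants": outdir / "variants.tsv",
        "genes": outdir / "genes.tsv",
        "expression": outdir / "expression.tsv",
        "degrees": outdir / "degrees.tsv",
        "chromatin": outdir / "chromatin_states.bed",
        "quartets": outdir / "quartets.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "config": outdir / "config.yaml",
    }
    bundle.variants.to_csv(paths["variants"], sep="\t", index=False)
    bundle.genes.to_csv(paths["genes"], sep="\t", index=False)
    bundle.expression.to_csv(paths["expression"], sep="\t")
    bundle.degrees.to_csv(paths["degrees"], sep="\t", index=False)
    bundle.chromatin.to_csv(paths["chromatin"], sep="\t", index=False, header=False)
    bundle.quartets.to_csv(paths["quartets"], sep="\t", index=False)
    bundle.truth_sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    bundle.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
    return paths


def generate_nondegenerate_quartets(cfg: CohortConfig) -> pd.DataFrame:
    """Per-site, per-tool alternative-allele score triples with truth class.

    Long format (one row per site x tool x alternative allele), restricted
    to non-degenerate sites; identical to the ``quartets.tsv`` member of
    the full bundle for the same config.
    """
    return generate_bundle(cfg).quartets
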