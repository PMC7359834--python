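"""Orchestration: simulate or load data, run every analysis, write a bundle.

The bundle mirrors the study's result tables: per-sample locus summaries
(diversity and F_IS), pairwise temporal F_ST matrices for microsatellites
and for the candidate locus, the Fisher year-by-year homogeneity matrix of
candidate genotype categories, genotype-survival fitness values with their
pairwise comparisons, the per-epoch expression ratio of change, and the
water-chemistry PCAs (joint and per site).  A manifest records the seed,
configuration hash, permutation counts and package versions so a bundle is
reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import CANDIDATE, CATEGORIES, GenotypeSample, POOLED_CATEGORIES
from .expression import ratio_report
from .io_formats import (
    read_expression_table,
    read_genepop,
    read_water_table,
    write_genepop,
    write_genotype_csv,
)
from .popgen import locus_summaries, pairwise_fst
from .scenarios import (
    AFFECTED_SITE,
    AFTER_GENERATIONS,
    BEFORE_GENERATIONS,
    CONTROL_SITE,
    FOCAL_ALLELE,
    paper_like_expression_config,
    paper_like_genotype_config,
    paper_like_water_config,
)
from .selection import category_counts, compare_fitness, fisher_exact_rxc, fitness_ratios
from .simulate import generate_expression, generate_water, simulate_two_deme
from .water_pca import group_separation, run_pca

logger = logging.getLogger(__name__)

ALL_ANALYSES = ("popgen", "selection", "expression", "water")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything a run needs; unset data sources fall back to simulation."""

    seed: int = 0
    out_dir: str = "tempsel_out"
    genotypes_path: str | None = None  # Genepop file; None -> simulate
    expression_path: str | None = None  # CSV; None -> simulate
    water_path: str | None = None  # CSV; None -> simulate
    focal_allele: str = FOCAL_ALLELE
    affected_site: str = AFFECTED_SITE
    control_site: str = CONTROL_SITE
    before_years: list[int] = field(default_factory=lambda: list(BEFORE_GENERATIONS))
    after_years: list[int] = field(default_factory=lambda: list(AFTER_GENERATIONS))
    analyses: list[str] = field(default_factory=lambda: list(ALL_ANALYSES))
    n_perm_fis: int = 5000
    n_perm_fst: int = 1000
    deme_size: int = 2000
    sample_size: int = 24
    log_level: str = "INFO"

    def validate(self) -> None:
        overlap = set(self.before_years) & set(self.after_years)
        if overlap:
            raise PipelineError(f"before/after year sets overlap: {sorted(overlap)}")
        if not self.analyses:
            raise PipelineError("at least one analysis must be enabled")
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise PipelineError(f"unknown analyses {sorted(unknown)}")
        if self.n_perm_fis < 1 or self.n_perm_fst < 1:
            raise PipelineError("permutation counts must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _derived_seeds(seed: int, n: int) -> list[int]:
    """Independent per-module seeds below 2**31, derived from one root."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def simulate_inputs(config: PipelineConfig, out: Path) -> dict[str, Path]:
    """Generate study-like genotype, expression and water inputs."""
    s_geno, s_expr, s_water = _derived_seeds(config.seed, 3)
    paths = {}
    sim = paper_like_genotype_config(
        seed=s_geno, deme_size=config.deme_size, sample_size=config.sample_size
    )
    samples = simulate_two_deme(sim)
    paths["genotypes"] = out / "genotypes.gen"
    write_genepop(samples, paths["genotypes"])
    write_genotype_csv(samples, out / "genotypes.csv")
    expr = generate_expression(paper_like_expression_config(seed=s_expr))
    paths["expression"] = out / "expression.csv"
    expr.to_csv(paths["expression"], index=False)
    water = generate_water(paper_like_water_config(seed=s_water))
    paths["water"] = out / "water.csv"
    water.to_csv(paths["water"], index=False)
    return paths


def _matrix_frame(labels, matrix) -> pd.DataFrame:
    names = [f"{site}_{year}" for site, year in labels]
    return pd.DataFrame(np.asarray(matrix), index=names, columns=names)


def _analyze_popgen(samples, config, out, seeds) -> dict:
    info = {}
    rows = []
    for s in samples:
        for summ in locus_summaries(
            s, n_perm=config.n_perm_fis, seed=seeds.pop()
        ):
            rows.append(
                {
                    "site": s.site,
                    "year": s.year,
                    "locus": summ.locus,
                    "n_typed": summ.n_typed,
                    "n_alleles": summ.n_alleles,
                    "Ho": round(summ.ho, 6),
                    "He": round(summ.he, 6),
                    "Fis": None if summ.fis is None else round(summ.fis, 6),
                    "p_Fis": summ.p_fis,
                    "monomorphic": summ.monomorphic,
                }
            )
    pd.DataFrame(rows).to_csv(out / "locus_summaries.tsv", sep="\t", index=False)
    info["n_locus_summaries"] = len(rows)

    micro_loci = [l.name for l in samples[0].loci if l.kind != CANDIDATE]
    cand_loci = [l.name for l in samples[0].loci if l.kind == CANDIDATE]
    for site in sorted({s.site for s in samples}):
        site_samples = sorted(
            [s for s in samples if s.site == site], key=lambda s: s.year
        )
        for tag, loci in (("microsats", micro_loci), ("candidate", cand_loci)):
            if not loci:
                continue
            pw = pairwise_fst(
                site_samples, loci=loci, n_perm=config.n_perm_fst, seed=seeds.pop()
            )
            _matrix_frame(pw.labels, np.round(pw.theta, 6)).to_csv(
                out / f"fst_{tag}_{site}.tsv", sep="\t"
            )
            _matrix_frame(pw.labels, pw.p_values).to_csv(
                out / f"fst_{tag}_{site}_pvalues.tsv", sep="\t"
            )
            info[f"fst_{tag}_{site}_max"] = float(np.max(pw.theta))
    return info


def _analyze_selection(samples, config, out, seeds) -> dict:
    info = {}
    for site in sorted({s.site for s in samples}):
        site_samples = sorted(
            [s for s in samples if s.site == site], key=lambda s: s.year
        )
        tables = [category_counts(s, config.focal_allele) for s in site_samples]
        freq_rows = []
        for t in tables:
            for cat, cnt in t.counts.items():
                freq_rows.append(
                    {
                        "site": site,
                        "year": t.year,
                        "category": cat,
                        "count": cnt,
                        "frequency": cnt / t.total if t.total else float("nan"),
                    }
                )
        pd.DataFrame(freq_rows).to_csv(
            out / f"genotype_freqs_{site}.tsv", sep="\t", index=False
        )
        years = [t.year for t in tables]
        pmat = pd.DataFrame(np.nan, index=years, columns=years)
        for i in range(len(tables)):
            for j in range(i + 1, len(tables)):
                tab = np.array(
                    [
                        [tables[i].counts[c] for c in CATEGORIES],
                        [tables[j].counts[c] for c in CATEGORIES],
                    ]
                )
                res = fisher_exact_rxc(tab, seed=seeds.pop())
                pmat.loc[years[i], years[j]] = res.p
                pmat.loc[years[j], years[i]] = res.p
        pmat.to_csv(out / f"fisher_candidate_{site}.tsv", sep="\t")
        try:
            fit = fitness_ratios(tables, config.before_years, config.after_years)
        except Exception as exc:  # zero before-frequency etc.
            logger.warning("fitness ratios failed for %s: %s", site, exc)
            info[f"fitness_{site}"] = f"failed: {exc}"
            continue
        fit_rows = []
        pairs = [
            (b, a) for b in config.before_years for a in config.after_years
        ]
        for cat in POOLED_CATEGORIES:
            for (b, a), w in zip(pairs, fit.values[cat]):
                fit_rows.append(
                    {"site": site, "category": cat, "before": b, "after": a, "w": w}
                )
            fit_rows.append(
                {
                    "site": site,
                    "category": cat,
                    "before": "median",
                    "after": "median",
                    "w": fit.medians[cat],
                }
            )
        pd.DataFrame(fit_rows).to_csv(
            out / f"fitness_{site}.tsv", sep="\t", index=False
        )
        test_rows = [
            {"site": site, "category_a": a, "category_b": b, "U": u, "p": p}
            for (a, b), (u, p) in compare_fitness(fit).items()
        ]
        pd.DataFrame(test_rows).to_csv(
            out / f"fitness_tests_{site}.tsv", sep="\t", index=False
        )
        info[f"fitness_{site}_medians"] = fit.medians
    return info


def _analyze_expression(table, config, out) -> dict:
    rep = ratio_report(table, config.affected_site, config.control_site)
    rep.to_csv(out / "expression_ratio.tsv", sep="\t", index=False)
    from .expression import add_normalized

    add_normalized(table).to_csv(out / "expression_long.tsv", sep="\t", index=False)
    return {
        "expression_ratios": {
            row["epoch"]: round(row["ratio_affected_over_control"], 4)
            for _, row in rep.iterrows()
        }
    }


def _analyze_water(table, config, out) -> dict:
    info = {}
    meta_cols = {"site", "year", "epoch"}
    variables = [c for c in table.columns if c not in meta_cols]
    scopes = {"all": table}
    for site in sorted(table["site"].unique()):
        scopes[site] = table[table["site"] == site]
    for scope, sub in scopes.items():
        if len(sub) < 3:
            continue
        result = run_pca(sub.reset_index(drop=True), variables)
        eig = pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(result.eigenvalues))],
                "eigenvalue": np.round(result.eigenvalues, 6),
                "percent_variance": np.round(result.percent_variance, 4),
            }
        )
        eig.to_csv(out / f"water_pca_{scope}_eigenvalues.tsv", sep="\t", index=False)
        pd.DataFrame(
            np.round(result.loadings, 6),
            index=result.variables,
            columns=eig["component"],
        ).to_csv(out / f"water_pca_{scope}_loadings.tsv", sep="\t")
        scores = pd.DataFrame(
            np.round(result.scores, 6), columns=eig["component"]
        )
        meta = sub.reset_index(drop=True).loc[result.sample_index, ["site", "year", "epoch"]]
        scores = pd.concat([meta.reset_index(drop=True), scores], axis=1)
        scores.to_csv(out / f"water_pca_{scope}_scores.tsv", sep="\t", index=False)
        grouping = {
            i: (row["site"], row["epoch"])
            for i, row in sub.reset_index(drop=True).iterrows()
        }
        sep_info = group_separation(result, grouping)
        cent_rows = [
            {"site": g[0], "epoch": g[1], **{f"PC{k + 1}": round(v, 6) for k, v in enumerate(vec)}}
            for g, vec in sep_info["centroids"].items()
        ]
        pd.DataFrame(cent_rows).to_csv(
            out / f"water_pca_{scope}_centroids.tsv", sep="\t", index=False
        )
        info[f"pca_{scope}_pc1_percent"] = float(result.percent_variance[0])
    return info


def run(config: PipelineConfig) -> dict:
    """Execute the configured analyses; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {
        "package": "tempsel",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "n_perm_fis": config.n_perm_fis,
        "n_perm_fst": config.n_perm_fst,
        "results": {},
    }
    sim_paths = {}
    needs_sim = (
        config.genotypes_path is None
        or (config.expression_path is None and "expression" in config.analyses)
        or (config.water_path is None and "water" in config.analyses)
    )
    if needs_sim:
        sim_paths = simulate_inputs(config, out)

    samples: list[GenotypeSample] | None = None
    if {"popgen", "selection"} & set(config.analyses):
        geno = config.genotypes_path or sim_paths.get("genotypes")
        samples = read_genepop(geno)
        manifest["genotypes"] = str(geno)

    analysis_seeds = _derived_seeds(config.seed + 1, 4096)
    try:
        if "popgen" in config.analyses:
            manifest["results"].update(
                _analyze_popgen(samples, config, out, analysis_seeds)
            )
        if "selection" in config.analyses:
            manifest["results"].update(
                _analyze_selection(samples, config, out, analysis_seeds)
            )
        if "expression" in config.analyses:
            expr = read_expression_table(
                config.expression_path or sim_paths["expression"]
            )
            manifest["results"].update(_analyze_expression(expr, config, out))
        if "water" in config.analyses:
            water = read_water_table(config.water_path or sim_paths["water"])
            manifest["results"].update(_analyze_water(water, config, out))
    except Exception as exc:
        (out / "INCOMPLETE").write_text(f"{type(exc).__name__}: {exc}\n")
        raise PipelineError(f"analysis failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    _write_summary(manifest, out)
    return manifest


def _write_summary(manifest: dict, out: Path) -> None:
    lines = [
        f"tempsel {manifest['version']} run summary",
        f"seed: {manifest['seed']}  config hash: {manifest['config_sha256'][:12]}",
        f"permutations: F_IS {manifest['n_perm_fis']}, F_ST {manifest['n_perm_fst']}",
        "",
    ]
    for key, val in sorted(manifest["results"].items()):
        lines.append(f"{key}: {val}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
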