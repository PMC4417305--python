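"""End-to-end orchestration: classify -> methylate -> rates -> stump -> tables.

A declarative :class:`PipelineConfig` (loadable from YAML) names the
input files and thresholds; :func:`run_pipeline` executes the stages in
order, writes every intermediate table as TSV into the output directory,
and records a manifest with per-stage row counts.  Outputs are
deterministic for a fixed config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import methylome, regions, stump, subrates, summaries

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """A stage failed on its input data (CLI exit code 3)."""


@dataclass
class SampleSpec:
    """One methylation sample: its site-call file and estimator variant."""

    name: str
    sites: str
    estimator: str = "pooled_strand_averaged"
    min_reads_per_site: int = 0


@dataclass
class PipelineConfig:
    cgi_bed: str = ""
    genes_tsv: str = ""
    maf: str = ""
    samples: list[SampleSpec] = field(default_factory=list)
    sperm_sample: str = "sperm"        # label source for the rate stump
    h1_sample: str = "H1"              # stratifier for partition reports
    min_total_calls: int = 5
    lm_max: float = 20.0
    hm_min: float = 80.0
    coverage_threshold: float = 0.5
    min_leaf_size: int = 1
    fixed_threshold: float | None = None
    species: tuple[str, str, str] = ("human", "chimp", "ancestor")
    outdir: str = "cgievol_out"
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.lm_max < self.hm_min <= 100):
            raise ConfigError("label thresholds must satisfy 0<=LM<HM<=100")
        if not 0 <= self.coverage_threshold <= 1:
            raise ConfigError("coverage_threshold must be in [0,1]")
        if self.min_total_calls < 0:
            raise ConfigError("min_total_calls must be >= 0")
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate sample names")
        for path_attr in ("cgi_bed", "genes_tsv", "maf"):
            p = getattr(self, path_attr)
            if p and not Path(p).exists():
                raise ConfigError(f"{path_attr}: no such file {p!r}")
        for s in self.samples:
            if not Path(s.sites).exists():
                raise ConfigError(f"sample {s.name}: no such file {s.sites!r}")
            if s.estimator not in methylome.ESTIMATORS:
                raise ConfigError(
                    f"sample {s.name}: unknown estimator {s.estimator!r}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        samples = [SampleSpec(**s) for s in raw.pop("samples", [])]
        config = PipelineConfig(samples=samples, **raw)
    except TypeError as exc:
        raise ConfigError(f"bad config key: {exc}") from exc
    config.validate()
    return config


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    Stage order: positional classification, per-sample methylation,
    substitution rates, rate-threshold stump, summary tables.  Any stage
    failure raises DataError naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                n = fn()
            except (ConfigError, DataError):
                raise
            except Exception as exc:
                raise DataError(f"stage {name}: {exc}") from exc
            manifest["stages"][name] = n
            log.info("stage %s: %s", name, n)
        return wrap

    state: dict = {}

    @stage("regions")
    def _():
        cgis = regions.load_cgi_bed(config.cgi_bed)
        genes = regions.load_gene_models(config.genes_tsv)
        cls = regions.classify_all(cgis, genes)
        cls.to_csv(outdir / "classification.tsv", sep="\t", index=False)
        state["cgis"], state["classification"] = cgis, cls
        return {"cgis": len(cgis), "genes": len(genes)}

    @stage("methylome")
    def _():
        tables = []
        for spec in config.samples:
            sites = methylome.read_site_calls(spec.sites)
            tables.append(methylome.cgi_methylation_table(
                sites, state["cgis"], spec.name,
                estimator=spec.estimator,
                min_reads_per_site=spec.min_reads_per_site,
                min_total_calls=config.min_total_calls,
                lm_max=config.lm_max, hm_min=config.hm_min,
            ))
        meth = (pd.concat(tables, ignore_index=True) if tables
                else pd.DataFrame(columns=["cgi_id", "sample", "estimator",
                                           "level", "n_calls", "label"]))
        meth.to_csv(outdir / "methylation.tsv", sep="\t", index=False,
                    float_format="%.6g")
        state["methylation"] = meth
        excluded = int((meth["label"] == "excluded").sum())
        return {"rows": len(meth), "excluded": excluded}

    @stage("subrates")
    def _():
        aln = subrates.read_triple_alignment(config.maf, *config.species)
        rates = subrates.cgi_rate_table(
            state["cgis"], aln, min_coverage=config.coverage_threshold)
        rates.to_csv(outdir / "rates.tsv", sep="\t", index=False,
                     float_format="%.6g")
        state["rates"] = rates
        return {"blocks": len(aln.blocks), "rejected_blocks": aln.n_rejected,
                "cgis_passing_coverage": int(rates["passed_coverage"].sum())}

    @stage("stump")
    def _():
        meth = state["methylation"]
        lab = meth.loc[meth["sample"] == config.sperm_sample,
                       ["cgi_id", "label"]]
        data = state["rates"].merge(lab, on="cgi_id")
        data = data[data["label"].isin(stump.LABELS)
                    & data["cpg_to_tpg_cpa"].notna()]
        data = data.rename(columns={"cpg_to_tpg_cpa": "rate"})
        fit = stump.fit_stump_frame(data[["rate", "label"]],
                                    min_leaf_size=config.min_leaf_size)
        with open(outdir / "stump.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=1)
            fh.write("\n")
        threshold = (config.fixed_threshold if config.fixed_threshold
                     is not None else fit.threshold)
        state["fit"], state["threshold"] = fit, threshold
        leaves = state["rates"][["cgi_id"]].copy()
        if threshold is not None:
            leaves["leaf"] = stump.assign_leaves(
                state["rates"]["cpg_to_tpg_cpa"].to_numpy(), threshold)
        else:
            leaves["leaf"] = "excluded"
        leaves.to_csv(outdir / "stump_leaves.tsv", sep="\t", index=False)
        state["leaves"] = leaves
        return {"n_labeled": len(data), "threshold": threshold,
                "degenerate": fit.degenerate}

    @stage("summaries")
    def _():
        prof = summaries.build_profiles(
            state["classification"], state["methylation"], state["rates"],
            state["leaves"])
        prof.to_csv(outdir / "profiles.tsv", sep="\t", index=False,
                    float_format="%.6g")
        n_tables = 0
        for spec in config.samples:
            t = summaries.position_label_counts(prof, spec.name)
            t.to_csv(outdir / f"position_counts_{spec.name}.tsv",
                     sep="\t", index=False)
            n_tables += 1
        sample_names = {s.name for s in config.samples}
        if {config.h1_sample, config.sperm_sample} <= sample_names:
            ct = summaries.crosstab(prof, config.h1_sample, config.sperm_sample)
            ct.to_csv(outdir / "crosstab.tsv", sep="\t", index=False)
            n_tables += 1
            if state["threshold"] is not None:
                part = summaries.threshold_partition_report(
                    prof, state["threshold"], config.sperm_sample,
                    config.h1_sample)
                part.to_csv(outdir / "threshold_partition.tsv", sep="\t",
                            index=False, float_format="%.4f")
                n_tables += 1
        if f"label_{config.sperm_sample}" in prof.columns:
            gs = summaries.group_rate_summary(
                prof, ["category", "coding", f"label_{config.sperm_sample}"])
            gs.to_csv(outdir / "group_rates.tsv", sep="\t", index=False,
                      float_format="%.6g")
            n_tables += 1
        return {"profiles": len(prof), "tables": n_tables}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
        fh.write("\n")
    return outdir


def config_to_yaml(config: PipelineConfig, path: str | Path) -> None:
    d = asdict(config)
    d["species"] = list(config.species)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
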