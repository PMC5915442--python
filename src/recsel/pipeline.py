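"""Orchestration: simulate -> filter -> score -> enrichment stages as one
reproducible run writing TSV outputs and a plain-text log.

One master seed lives in the config; each stage derives its own sub-seed by
stable hashing of ``(seed, stage name)``, so toggling one stage never
shifts another stage's randomness.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import GenomeLayout, IntervalSet, default_layout
from .heterogeneity import score_heterogeneity
from .introgression import rotation_permutation
from .io import write_intervals, write_table
from .sds import GENOME_WIDE_ALPHA, BinScheme, compute_sds
from .simulate import (
    SelectedLocus,
    SimulationConfig,
    simulate_panel,
    simulate_regional_counts,
    simulate_tracts,
    simulate_trait_sets,
)
from .singletons import apply_mask, density_filter
from .traits import enrich_traits


def stage_seed(seed: int, stage: str) -> int:
    """Stable 31-bit sub-seed for a named stage."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run (defaults mirror the study design)."""

    seed: int = 0
    out_dir: str = "run"
    # simulation
    dataset_sizes: tuple[int, ...] = (200, 200, 200)
    n_common_sites: int = 2500
    singleton_rate: float = 1e-4
    selected_loci: tuple[SelectedLocus, ...] = ()
    selected_ld_copies: int = 0
    # singleton filters
    window_bp: int = 20_000
    step_bp: int = 10_000
    k_sd: float = 4.0
    mask: tuple[tuple[str, int, int], ...] = ()
    # scoring
    maf_min: float = 0.01
    min_class_count: int = 10
    sig_threshold: float = GENOME_WIDE_ALPHA
    # heterogeneity
    het_half_width: float = 0.005
    het_min_null: int = 100
    n_het_variants: int = 1500
    # introgression
    tract_total_bp: int = 1_000_000
    n_tracts: int = 20
    rotation_iterations: int = 10_000
    increment_fraction: float = 1e-4
    # traits
    n_traits: int = 20
    k_per_trait: int = 20
    enriched_fraction: float = 0.0
    alpha: float = 0.05
    # stage toggles
    stages: tuple[str, ...] = ("simulate", "singletons", "sds", "dafhet", "introgression", "trait-enrich")

    @staticmethod
    def from_yaml(path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "selected_loci" in raw:
            raw["selected_loci"] = tuple(
                SelectedLocus(**d) for d in raw["selected_loci"]
            )
        for key in ("dataset_sizes", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "mask" in raw:
            raw["mask"] = tuple(tuple(iv) for iv in raw["mask"])
        return RunConfig(**raw)

    def to_simulation_config(self, layout: GenomeLayout) -> SimulationConfig:
        return SimulationConfig(
            seed=stage_seed(self.seed, "simulate"),
            layout=layout,
            dataset_sizes=self.dataset_sizes,
            n_common_sites=self.n_common_sites,
            singleton_rate=self.singleton_rate,
            selected_loci=self.selected_loci,
            selected_ld_copies=self.selected_ld_copies,
        )


class PipelineError(RuntimeError):
    pass


def _param_hash(config: RunConfig) -> str:
    # out_dir is excluded: two runs of the same analysis into different
    # directories are the same analysis
    blob = json.dumps(
        {k: str(v) for k, v in asdict(config).items() if k != "out_dir"},
        sort_keys=True,
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(
    config: RunConfig,
    layout: GenomeLayout | None = None,
    sample_filter_regions: tuple[str, ...] | None = None,
) -> dict:
    """Execute the enabled stages in dependency order.

    Returns a dict of in-memory stage results; TSV outputs, the config echo
    and a timestamped log land in ``config.out_dir``. Re-running with an
    identical config reproduces identical outputs.
    """
    layout = layout or default_layout()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%Y-%m-%dT%H:%M:%S')}] {msg}")

    header = [
        f"recsel {__version__}",
        f"seed {config.seed}",
        f"params {_param_hash(config)}",
    ]
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump({k: str(v) for k, v in asdict(config).items()}, fh)
    log(f"run start, seed={config.seed}, params={_param_hash(config)}")

    results: dict = {}
    stages = set(config.stages)

    if "simulate" in stages:
        sim = config.to_simulation_config(layout)
        panel, catalog, truth = simulate_panel(sim)
        if sample_filter_regions is not None:
            keep = panel.samples["region"].isin(sample_filter_regions).to_numpy()
            if not keep.any():
                raise PipelineError("sample filter leaves no samples")
            kept_ids = set(panel.samples["sample"][keep])
            panel = panel.subset_samples(keep)
            ent = catalog.entries
            catalog = type(catalog)(ent[ent["carrier"].isin(kept_ids)])
            log(f"subset to regions {sample_filter_regions}: {keep.sum()} samples")
            for d in panel.samples["dataset"].unique():
                log(f"cohort size {d}: {(panel.samples['dataset'] == d).sum()}")
        results.update(panel=panel, catalog=catalog, truth=truth)
        log(
            f"simulate: {panel.n_sites} sites, {panel.n_samples} samples, "
            f"{len(catalog)} singleton events"
        )
    else:
        raise PipelineError("stage 'simulate' is required for a synthetic run")

    if "singletons" in stages:
        mask = IntervalSet(config.mask)
        catalog = apply_mask(results["catalog"], mask)
        catalog, density_report = density_filter(
            catalog, layout, config.window_bp, config.step_bp, config.k_sd
        )
        results["catalog"] = catalog
        results["density_report"] = density_report
        write_table(density_report.stats, str(out / "density_report.tsv"), header)
        removed = (~catalog.entries["retained"]).sum()
        log(f"singleton filters: {removed} of {len(catalog)} events removed")

    if "sds" in stages:
        if "singletons" not in stages:
            raise PipelineError("stage 'sds' requires stage 'singletons'")
        sds_table = compute_sds(
            results["panel"], results["catalog"], layout,
            scheme=BinScheme(), maf_min=config.maf_min,
            min_class_count=config.min_class_count,
        )
        results["sds"] = sds_table
        write_table(sds_table, str(out / "sds.tsv"), header)
        n_sig = int(sds_table["significant"].sum())
        log(f"sds: {len(sds_table)} variants scored, {n_sig} genome-wide significant")

    if "dafhet" in stages:
        if "sds" not in stages:
            raise PipelineError("stage 'dafhet' requires stage 'sds'")
        rng = np.random.default_rng(stage_seed(config.seed, "dafhet"))
        sds_table = results["sds"]
        truth = results["truth"]
        sel_ids = set(
            f"{r.chrom}:{r.pos}" for r in truth.selected.itertuples()
        ) & set(sds_table["variant"])
        focal = sorted(sel_ids) or list(sds_table.nlargest(3, "final_z")["variant"])
        n_null = min(config.n_het_variants, len(sds_table))
        pick = rng.choice(len(sds_table), size=n_null, replace=False)
        chosen = set(sds_table["variant"].iloc[pick]) | sel_ids | set(focal)
        tables = {}
        for _, row in sds_table.iterrows():
            if row["variant"] not in chosen:
                continue
            tables[row["variant"]] = simulate_regional_counts(
                config.to_simulation_config(layout),
                float(row["daf"]),
                selected=row["variant"] in sel_ids,
                rng=rng,
                variant_id=row["variant"],
            )
        het = score_heterogeneity(
            tables, focal, config.het_half_width, config.het_min_null
        )
        results["heterogeneity"] = het
        write_table(het, str(out / "heterogeneity.tsv"), header)
        log(f"dafhet: {len(het)} focal variants against {len(tables)} scored")

    if "introgression" in stages:
        if "sds" not in stages:
            raise PipelineError("stage 'introgression' requires stage 'sds'")
        rng = np.random.default_rng(stage_seed(config.seed, "introgression"))
        tracts = simulate_tracts(
            config.to_simulation_config(layout), config.tract_total_bp,
            config.n_tracts, rng=rng,
        )
        perm = rotation_permutation(
            tracts, results["sds"], layout,
            iterations=config.rotation_iterations,
            increment_fraction=config.increment_fraction,
        )
        results["introgression"] = perm
        write_intervals(tracts, str(out / "tracts.bed"))
        write_table(perm.summary(), str(out / "introgression.tsv"), header)
        log(f"introgression: mean z {perm.observed_mean_z:.3f}, P {perm.p:.4f}")

    if "trait-enrich" in stages:
        if "sds" not in stages:
            raise PipelineError("stage 'trait-enrich' requires stage 'sds'")
        rng = np.random.default_rng(stage_seed(config.seed, "traits"))
        sets, trait_truth = simulate_trait_sets(
            config.to_simulation_config(layout),
            results["sds"][["chrom", "pos"]],
            config.n_traits, config.k_per_trait, config.enriched_fraction,
            rng=rng,
        )
        enr = enrich_traits(sets, results["sds"], alpha=config.alpha)
        results["trait_enrichment"] = enr
        results["trait_truth"] = trait_truth
        write_table(enr, str(out / "trait_enrichment.tsv"), header)
        log(
            f"trait-enrich: {len(enr)} traits, "
            f"{int(enr['bonferroni_significant'].sum())} Bonferroni-significant"
        )

    log("run complete")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    results["log"] = log_lines
    return results


def subset_rerun(
    config: RunConfig,
    regions: tuple[str, ...],
    layout: GenomeLayout | None = None,
) -> dict:
    """Re-execute the pipeline on the samples of the given region labels.

    Writes a comparison of genome-wide-significant variants between the
    full and subset runs into the subset run directory.
    """
    if not regions:
        raise PipelineError("empty region filter")
    full = run_pipeline(config, layout)
    sub_cfg = replace(config, out_dir=str(Path(config.out_dir) / "subset"))
    sub = run_pipeline(sub_cfg, layout, sample_filter_regions=regions)
    if "sds" in full and "sds" in sub:
        full_sig = set(full["sds"].loc[full["sds"]["significant"], "variant"])
        sub_sig = set(sub["sds"].loc[sub["sds"]["significant"], "variant"])
        cmp = pd.DataFrame(
            {
                "variant": sorted(full_sig | sub_sig),
            }
        )
        cmp["significant_full"] = cmp["variant"].isin(full_sig)
        cmp["significant_subset"] = cmp["variant"].isin(sub_sig)
        write_table(cmp, str(Path(sub_cfg.out_dir) / "significance_comparison.tsv"))
        sub["significance_comparison"] = cmp
    sub["full_run"] = full
    return sub
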