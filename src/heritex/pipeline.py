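"""End-to-end orchestration of the analysis stages on one config.

Stages run in dependency order on a synthetic or user-supplied fixture:
heritability -> PSI -> eQTL -> sQTL -> colocalization -> ICA -> sweep.
Every stage writes flat TSV outputs plus a manifest (input checksums,
parameters, seed, package version) so a rerun with an identical config
reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import boxcox_transform, compute_pcs, filter_expressed_genes
from .simulate import FixtureSet, build_default_fixture, write_fixture_set

DEFAULT_STAGES = ("h2", "psi", "eqtl", "sqtl", "coloc", "ica", "sweep")


@dataclass
class PipelineConfig:
    out_dir: str = "heritex_run"
    seed: int = 0
    stages: tuple[str, ...] = DEFAULT_STAGES
    fixture_dir: str | None = None  # None -> simulate the default fixture
    alpha: float = 0.05
    gap_max: int = 1_000_000
    min_snps: int = 3
    max_peaks: int = 10
    sqtl_min_beta: float = 0.05
    coloc_r2_min: float = 0.6
    ica_var_target: float = 0.80
    ica_kurtosis_min: float = 6.0
    ica_fdr: float = 0.01
    sweep_window: int = 100_000
    sweep_step: int = 10_000
    sweep_decile: float = 0.90
    n_pcs: int = 5
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    fixture: dict = field(default_factory=dict)  # build_default_fixture overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _write_manifest(stage_dir: Path, params: dict, inputs: list[Path]) -> None:
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "parameters": params,
        "inputs": {str(p): _checksum(p) for p in inputs if p.exists()},
        "outputs": {
            p.name: _checksum(p) for p in sorted(stage_dir.glob("*.tsv"))
        },
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    from . import association, coloc, heritability, ica, splicing, sweep as sweep_mod

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.fixture_dir is None:
        from .simulate import SimulationConfig

        sim_cfg = SimulationConfig(seed=config.seed, **config.sim) if config.sim else None
        fx = build_default_fixture(seed=config.seed, config=sim_cfg, **config.fixture)
        fixture_dir = out / "fixture"
        write_fixture_set(fx, fixture_dir)
    else:
        raise NotImplementedError(
            "loading external fixtures: use the library API; the pipeline "
            "driver currently runs on the synthetic study design"
        )

    genotypes, labels, expr = fx.genotypes, fx.labels, fx.expression
    gene_models = {g.gene_id: g for g in fx.gene_models}
    rmap = expr.replicate_map

    expressed = filter_expressed_genes(expr)
    fpkm = expr.fpkm[expressed]
    transformed = pd.DataFrame(
        {g: boxcox_transform(fpkm[g].to_numpy())[0] for g in fpkm.columns},
        index=fpkm.index,
    )
    geno_of = rmap.loc[transformed.index]
    trait_means = transformed.groupby(geno_of.to_numpy()).mean().loc[genotypes.sample_ids]
    pcs = compute_pcs(genotypes, k=config.n_pcs, seed=config.seed)

    results: dict[str, pd.DataFrame] = {}

    def stage(name: str):
        return name in config.stages

    try:
        if stage("h2"):
            d = out / "h2"
            d.mkdir(exist_ok=True)
            h2 = heritability.h2_table(transformed, rmap)
            h2.to_csv(d / "variance_components.tsv", sep="\t")
            pops = list(pd.unique(labels))
            comp = heritability.compare_subpopulation_h2(
                transformed, rmap, labels, pops[0], pops[1]
            )
            comp.to_csv(d / "subpopulation_h2.tsv", sep="\t")
            shift = heritability.go_heritability_shift(h2["h2"], fx.go_annotations)
            shift.to_csv(d / "go_h2_shift.tsv", sep="\t", index=False)
            results["h2"] = h2
            _write_manifest(d, {"seed": config.seed}, [])

        if stage("psi"):
            d = out / "psi"
            d.mkdir(exist_ok=True)
            sizes = pd.Series(
                (fx.introns["end"] - fx.introns["start"] + 1).to_numpy(),
                index=fx.introns["intron_id"],
            )
            psi = splicing.psi_matrix(fx.ucount, fx.depth, sizes)
            kept = splicing.filter_s_traits(fx.ucount, psi)
            psi[kept].to_csv(d / "psi_matrix.tsv", sep="\t")
            results["psi"] = psi[kept]
            _write_manifest(d, {"seed": config.seed}, [])

        threshold = association.bonferroni_threshold(
            config.alpha, genotypes.n_markers * max(len(expressed), 1)
        )

        if stage("eqtl"):
            d = out / "eqtl"
            d.mkdir(exist_ok=True)
            peaks = association.map_qtl(
                trait_means,
                genotypes,
                pcs,
                threshold.p,
                gene_models=gene_models,
                gap_max=config.gap_max,
                min_snps=config.min_snps,
                max_peaks=config.max_peaks,
            )
            peaks.to_csv(d / "eqtl_peaks.tsv", sep="\t", index=False)
            results["eqtl"] = peaks
            _write_manifest(d, {"threshold_p": threshold.p}, [])

        if stage("sqtl") and "psi" in results:
            d = out / "sqtl"
            d.mkdir(exist_ok=True)
            psi_means = (
                results["psi"].groupby(rmap.loc[results["psi"].index].to_numpy()).mean()
            ).loc[genotypes.sample_ids]
            intron_gene = dict(zip(fx.introns["intron_id"], fx.introns["gene_id"]))
            s_models = {
                i: gene_models[g] for i, g in intron_gene.items() if g in gene_models
            }
            speaks = association.map_qtl(
                psi_means.fillna(psi_means.mean()),
                genotypes,
                pcs,
                threshold.p,
                gene_models=s_models,
                gap_max=config.gap_max,
                min_snps=config.min_snps,
                max_peaks=config.max_peaks,
                min_beta=config.sqtl_min_beta,
            )
            speaks.to_csv(d / "sqtl_peaks.tsv", sep="\t", index=False)
            results["sqtl"] = speaks
            _write_manifest(d, {"min_beta": config.sqtl_min_beta}, [])

        if stage("coloc") and "eqtl" in results and "sqtl" in results:
            d = out / "coloc"
            d.mkdir(exist_ok=True)
            intron_to_gene = pd.Series(
                fx.introns["gene_id"].to_numpy(), index=fx.introns["intron_id"]
            )
            pairs = coloc.coloc_lead_snps(
                results["eqtl"], results["sqtl"], intron_to_gene,
                genotypes, r2_min=config.coloc_r2_min,
            ) if len(results["eqtl"]) and len(results["sqtl"]) else pd.DataFrame()
            pairs.to_csv(d / "coloc_pairs.tsv", sep="\t", index=False)
            results["coloc"] = pairs
            _write_manifest(d, {"r2_min": config.coloc_r2_min}, [])

        if stage("ica") and "h2" in results:
            d = out / "ica"
            d.mkdir(exist_ok=True)
            sd_floor = float(np.median(transformed.std(axis=0)))
            genes = ica.select_ica_genes(
                transformed, results["h2"]["h2"], sd_min=sd_floor * 0.5
            )
            mat = transformed[genes]
            k = min(ica.n_components_for_variance(mat, config.ica_var_target), 30)
            decomp = ica.run_ica(mat, k, seed=config.seed)
            decomp = ica.filter_components(decomp, config.ica_kurtosis_min, seed=config.seed)
            modules = ica.assign_module_membership(decomp, config.ica_fdr)
            decomp.mixing.to_csv(d / "ic_coefficients.tsv", sep="\t")
            pd.DataFrame(
                [(c, g) for c, gs in modules.items() for g in gs],
                columns=["component", "gene"],
            ).to_csv(d / "module_membership.tsv", sep="\t", index=False)
            blups = {}
            for comp in modules:
                b, h2c = ica.blup_ic_coefficients(decomp.mixing[comp], rmap)
                blups[comp] = b
            if blups:
                pd.DataFrame(blups).to_csv(d / "ic_blups.tsv", sep="\t")
            results["ica_modules"] = modules
            _write_manifest(d, {"var_target": config.ica_var_target}, [])

        if stage("sweep"):
            d = out / "sweep"
            d.mkdir(exist_ok=True)
            lengths = sweep_mod.chrom_lengths_from_markers(genotypes.markers)
            gmap = sweep_mod.GeneticMap.uniform(lengths)
            windows = sweep_mod.make_windows(lengths, config.sweep_window, config.sweep_step)
            fst = sweep_mod.windowed_fst(
                genotypes, labels, config.sweep_window, config.sweep_step
            )
            pi = sweep_mod.window_pi(genotypes, labels, windows)
            clr = sweep_mod.xpclr_scan(genotypes, labels, gmap)
            table = sweep_mod.combine_window_stats(fst, clr, pi, config.sweep_decile)
            table.to_csv(d / "window_stats.tsv", sep="\t", index=False)
            candidates = sweep_mod.sweep_candidate_genes(table, fx.gene_models)
            pd.Series(candidates, name="gene").to_csv(
                d / "sweep_candidate_genes.tsv", sep="\t", index=False
            )
            results["sweep"] = table
            _write_manifest(d, {"window": config.sweep_window}, [])
    except Exception as exc:  # stage-scoped failure
        raise StageError(_current_stage(out), exc) from exc

    (out / "run_manifest.json").write_text(
        json.dumps(
            {"version": __version__, "seed": config.seed, "stages": list(config.stages)},
            indent=1,
        )
    )
    return out


def _current_stage(out: Path) -> str:
    done = [p.name for p in out.iterdir() if p.is_dir()]
    for s in DEFAULT_STAGES:
        if s not in done:
            return s
    return done[-1] if done else "?"
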