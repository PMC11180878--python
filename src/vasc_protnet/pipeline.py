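"""End-to-end orchestration: simulate/ingest -> correct -> network -> report.

Stage order: missingness filtering, TAMPOR batch correction, cell-type
proportions and outlier removal, protected covariate regression, signed
co-expression network with kME reassignment, module preservation in the
paired bulk matrix, module/trait statistics and differential abundance,
marker / biofluid / GWAS enrichment, and Abeta peptide ratios.  Every
intermediate is written as TSV and recorded (with a content digest) in a run
manifest, so reruns with the same configuration and seed are verifiably
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition, enrich, network, peptides, simulate, stats
from .io import (AbundanceMatrix, filter_missingness, read_abundance_table,
                 read_marker_sets, read_sample_meta, read_traits,
                 write_abundance_table, write_marker_sets, write_sample_meta,
                 write_traits, zeros_to_missing)
from .tampor import TamporParams, tampor

logger = logging.getLogger("vasc_protnet")

TRAIT_COLUMNS = ("is_ad", "is_psp", "cerad", "braak", "caa", "gliosis", "apoe4_dose")


@dataclass
class RunManifest:
    config: dict
    seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # filename -> sha256
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "seeds": self.seeds, "outputs": self.outputs,
             "timings": {k: round(v, 3) for k, v in self.timings.items()},
             "warnings": self.warnings},
            indent=2, default=str))


def _stage_seeds(seed: int) -> dict[str, int]:
    return {name: (seed * 1000 + k) % (2 ** 31)
            for k, name in enumerate(
                ["study", "gwas", "biofluid", "peptide", "regression", "preservation", "magma"])}


def _dataclass_from_config(cls, overrides: dict | None):
    known = {f.name for f in fields(cls)}
    overrides = overrides or {}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} options: {sorted(unknown)}")
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()}
    return cls(**kwargs)


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run every stage from a configuration mapping; returns the result bundle.

    ``config`` keys: ``simulate`` (bool), ``seed``, ``out_dir``, plus optional
    per-stage overrides (``study``, ``tampor``, ``regression``, ``network``,
    ``preservation``, ``gwas``) and, in real-data mode, an ``inputs`` mapping
    with ``abundance``, ``meta``, ``traits``, ``markers`` and optionally
    ``bulk`` paths.
    """
    t0 = time.time()
    out_dir = Path(out_dir or config.get("out_dir", "vasc_protnet_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    seeds = _stage_seeds(seed)
    manifest = RunManifest(config=dict(config), seeds=seeds)
    results: dict = {"manifest": manifest}

    def save(obj, name: str, **kwargs) -> None:
        path = out_dir / name
        if isinstance(obj, AbundanceMatrix):
            write_abundance_table(obj, path)
        elif isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t", na_rep="NA", **kwargs)
        elif isinstance(obj, pd.Series):
            obj.to_frame().to_csv(path, sep="\t", na_rep="NA")
        else:
            path.write_text(str(obj))
        manifest.record(path)

    def tic(stage: str):
        manifest.timings[stage] = time.time() - t0

    # ------------------------------------------------------------------ inputs
    if config.get("simulate", True):
        study_cfg = _dataclass_from_config(simulate.StudyConfig, config.get("study"))
        study = simulate.generate_study(study_cfg, seed=seeds["study"])
        abundance, meta, traits = study.abundance, study.meta, study.traits
        markers, truth, bulk = study.markers, study.truth, study.bulk_abundance
        save(abundance, "abundance_raw.tsv")
        save(bulk, "bulk_abundance_raw.tsv")
        write_sample_meta(meta, out_dir / "meta.tsv"); manifest.record(out_dir / "meta.tsv")
        write_traits(traits, out_dir / "traits.tsv"); manifest.record(out_dir / "traits.tsv")
        write_marker_sets(markers, out_dir / "markers.gmt"); manifest.record(out_dir / "markers.gmt")
        celltype_sets = study.celltype_sets
        write_marker_sets(celltype_sets, out_dir / "celltype_sets.gmt")
        manifest.record(out_dir / "celltype_sets.gmt")
        save(truth.module_labels, "truth_modules.tsv")
        results["truth"] = truth
    else:
        inputs = config.get("inputs") or {}
        for key in ("abundance", "meta", "traits", "markers"):
            if key not in inputs:
                raise ValueError(f"real-data mode requires inputs.{key} in the configuration")
        abundance = read_abundance_table(inputs["abundance"])
        meta = read_sample_meta(inputs["meta"], abundance)
        traits = read_traits(inputs["traits"])
        markers = read_marker_sets(inputs["markers"])
        bulk = read_abundance_table(inputs["bulk"]) if "bulk" in inputs else None
        celltype_sets = markers
        truth = None
        study_cfg = None
    tic("inputs")

    # ------------------------------------------------------------ filter + TAMPOR
    abundance = filter_missingness(zeros_to_missing(abundance))
    tampor_params = _dataclass_from_config(TamporParams, config.get("tampor"))
    tampor_vasc = tampor(abundance, meta, tampor_params)
    results["tampor"] = tampor_vasc
    save(tampor_vasc.corrected, "corrected_log2.tsv")
    tampor_bulk = None
    if bulk is not None:
        bulk_f = filter_missingness(zeros_to_missing(bulk))
        tampor_bulk = tampor(bulk_f, meta, tampor_params)
        save(tampor_bulk.corrected, "bulk_corrected_log2.tsv")
    tic("tampor")

    # ------------------------------------- proportions, outliers, regression
    corrected = tampor_vasc.corrected
    proportions = composition.estimate_cell_proportions(corrected, markers)
    save(proportions, "cell_proportions.tsv")
    outliers = composition.detect_endothelial_outliers(proportions)
    save(outliers, "outliers.tsv")
    keep = [s for s in corrected.sample_ids if not outliers.get(s, False)]
    logger.info("outlier removal: %d samples flagged, %d retained",
                int(outliers.sum()), len(keep))
    trimmed = AbundanceMatrix(corrected.data[keep], scale="log2")
    reg_spec = _dataclass_from_config(composition.RegressionSpec, config.get("regression"))
    reg_spec.seed = seeds["regression"]
    regressed = composition.bootstrap_regress(trimmed, meta, traits, proportions, reg_spec)
    save(regressed, "regressed_log2.tsv")
    results.update(proportions=proportions, outliers=outliers, regressed=regressed)
    tic("regression")

    # ------------------------------------------------------------------ network
    net_params = _dataclass_from_config(network.NetworkParams, config.get("network"))
    model = network.build_network(regressed, net_params)
    results["network"] = model
    assignments = model.assignments
    own_kme = pd.Series(
        [model.kme.at[p, assignments[p]] if assignments[p] in model.kme.columns else np.nan
         for p in assignments.index], index=assignments.index, name="kme_own")
    save(pd.concat([assignments, own_kme], axis=1), "modules.tsv")
    save(model.eigenproteins, "eigenproteins.tsv")
    save(model.kme, "kme.tsv")
    tic("network")

    # ------------------------------------------------------------- preservation
    if tampor_bulk is not None:
        pres_cfg = config.get("preservation") or {}
        bulk_trimmed = AbundanceMatrix(
            tampor_bulk.corrected.data[[s for s in keep if s in tampor_bulk.corrected.data.columns]],
            scale="log2")
        preservation = network.module_preservation(
            regressed, assignments, bulk_trimmed,
            n_perm=int(pres_cfg.get("n_perm", 500)), seed=seeds["preservation"],
            params=net_params)
        save(preservation, "preservation.tsv")
        results["preservation"] = preservation
    tic("preservation")

    # ------------------------------------------------------------------- stats
    diagnosis = meta.set_index("sample_id").loc[regressed.sample_ids, "diagnosis"]
    de = stats.anova_tukey_de(regressed, diagnosis)
    save(de, "differential_abundance.tsv")
    trait_df = traits.set_index("sample_id").loc[regressed.sample_ids, list(TRAIT_COLUMNS)]
    me_trait = stats.me_trait_correlation(model.eigenproteins, trait_df)
    save(me_trait, "me_trait_correlation.tsv", index=False)
    results.update(de=de, me_trait=me_trait)
    if tampor_bulk is not None:
        enr_prot, enr_mod = stats.vascular_bulk_enrichment(
            tampor_vasc.corrected_abundance(), tampor_bulk.corrected_abundance(), assignments)
        save(enr_prot, "vascular_bulk_enrichment.tsv")
        if enr_mod is not None:
            save(enr_mod, "vascular_bulk_enrichment_modules.tsv")
        classifiers = stats.select_classifier_proteins(de, enr_prot)
        save(pd.Series(classifiers, name="protein"), "classifier_proteins.tsv")
        results.update(vb_enrichment=enr_prot, vb_enrichment_modules=enr_mod,
                       classifiers=classifiers)
    tic("stats")

    # -------------------------------------------------------------- enrichment
    background = list(assignments.index)
    celltype_fet = enrich.fisher_overrepresentation(assignments, celltype_sets, background)
    save(celltype_fet, "celltype_enrichment.tsv", index=False)
    results["celltype_fet"] = celltype_fet
    if truth is not None:
        gwas_cfg = config.get("gwas") or {}
        gwas_table = simulate.generate_gwas_table(
            n_genes=len(background),
            enriched_module_labels=tuple(gwas_cfg.get("enriched_modules", ("M1",))),
            truth=truth, effect=float(gwas_cfg.get("effect", 5.0)), seed=seeds["gwas"])
        plasma, csf = simulate.generate_biofluid_tables(truth, seed=seeds["biofluid"])
        save(gwas_table, "gwas_gene_p.tsv", index=False)
        save(plasma, "plasma_de.tsv", index=False)
        save(csf, "csf_de.tsv", index=False)
    else:
        gwas_table = plasma = csf = None
    if plasma is not None:
        fluid_results = {}
        for fluid, table in (("plasma", plasma), ("csf", csf)):
            sets = {
                f"{fluid}_all": list(table["protein"]),
                f"{fluid}_increased": list(table.loc[(table["p"] < 0.05) & (table["log2_effect"] > 0), "protein"]),
                f"{fluid}_decreased": list(table.loc[(table["p"] < 0.05) & (table["log2_effect"] < 0), "protein"]),
            }
            fluid_results[fluid] = enrich.fisher_overrepresentation(assignments, sets, background)
        fluid_fet = pd.concat(fluid_results.values(), ignore_index=True)
        save(fluid_fet, "biofluid_enrichment.tsv", index=False)
        results["biofluid_fet"] = fluid_fet
    if gwas_table is not None:
        gwas_cfg = config.get("gwas") or {}
        risk = enrich.magma_spa(assignments, gwas_table,
                                n_perm=int(gwas_cfg.get("n_perm", 10_000)),
                                seed=seeds["magma"])
        save(risk, "gwas_risk_enrichment.tsv", index=False)
        results["risk"] = risk
    tic("enrichment")

    # ------------------------------------------------------------------- Abeta
    if truth is not None:
        pep_v, pep_b = simulate.generate_peptide_table(truth, meta, study_cfg, seed=seeds["peptide"])
        ratios = peptides.abeta_ratios(
            peptides.scale_reporter_intensities(pep_v),
            peptides.scale_reporter_intensities(pep_b),
            meta=meta, batch_corrected=True)
        save(ratios, "abeta_ratios.tsv")
        results["abeta_ratios"] = ratios
    tic("abeta")

    manifest.write(out_dir / "manifest.json")
    results["out_dir"] = out_dir
    return results
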