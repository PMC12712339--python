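"""End-to-end pipeline orchestration from a single YAML config.

Stage order: simulate (optional) -> annotate -> normalize -> diff -> enrich,
plus the independent plsda, rates and phenotype branches. Every output file
carries a provenance header (tool version, config hash, seed) and a
machine-readable run report records per-stage status and record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__, annotation, diffstats, enrichment, io, normalization
from . import phenotype as pheno
from . import plsda as plsda_mod
from . import rates as rates_mod
from . import synthetic
from .errors import ConfigurationError, EcmetError

log = logging.getLogger("ecmet")

STAGES = ("simulate", "annotate", "normalize", "diff", "enrich",
          "plsda", "rates", "phenotype")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=dict)
    params: dict[str, dict] = field(default_factory=dict)
    paths: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "outdir" not in raw:
            raise ConfigurationError(f"{path}: config needs an 'outdir'")
        stages = {s: bool(raw.get("stages", {}).get(s, s != "simulate"))
                  for s in STAGES}
        unknown = set(raw.get("stages", {})) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"{path}: unknown stages {sorted(unknown)}")
        params = {s: dict(raw.get(s, {}) or {}) for s in STAGES}
        return cls(
            outdir=str(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            stages=stages,
            params=params,
            paths=dict(raw.get("paths", {}) or {}),
        )

    def config_hash(self) -> str:
        # analytic parameters only: output location must not change results
        blob = json.dumps(
            {"seed": self.seed, "stages": self.stages, "params": self.params},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def validate(self) -> None:
        if not self.stages.get("simulate"):
            needed = {
                "annotate": ("ions", "masses"),
                "normalize": ("matrix", "metadata"),
                "diff": ("matrix", "metadata"),
                "enrich": ("gmt",),
                "plsda": ("matrix", "metadata"),
                "rates": ("supernatant",),
                "phenotype": ("growth", "migration"),
            }
            for stage, keys in needed.items():
                if not self.stages.get(stage):
                    continue
                for key in keys:
                    p = self.paths.get(key)
                    if not p:
                        raise ConfigurationError(
                            f"stage {stage!r} enabled but no path for {key!r}"
                        )
                    if not os.path.exists(p):
                        raise ConfigurationError(f"missing input file: {p}")


def _provenance(cfg: PipelineConfig) -> str:
    return (f"ecmet {__version__}\nconfig_hash {cfg.config_hash()}\n"
            f"seed {cfg.seed}")


def _write_tsv(df: pd.DataFrame, path: str, cfg: PipelineConfig,
               index: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in _provenance(cfg).splitlines():
            fh.write(f"# {line}\n")
        fh.write(df.to_csv(sep="\t", index=index))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run enabled stages in dependency order; abort on first failure.

    Returns the run report (also written to ``<outdir>/run_report.json``).
    """
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    report: dict = {"version": __version__, "config_hash": cfg.config_hash(),
                    "seed": cfg.seed, "stages": {}}
    prov = _provenance(cfg)
    out = lambda name: os.path.join(cfg.outdir, name)  # noqa: E731

    state: dict = {}

    def run_stage(name, fn):
        if not cfg.stages.get(name):
            report["stages"][name] = {"status": "skipped"}
            return
        log.info("stage %s: starting", name)
        try:
            counts = fn()
        except Exception as exc:
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            with open(out("run_report.json"), "w", encoding="utf-8") as fh:
                json.dump(report, fh, indent=2)
            raise EcmetError(f"stage {name!r} failed: {exc}") from exc
        report["stages"][name] = {"status": "ok", **counts}
        log.info("stage %s: ok", name)

    def stage_simulate():
        p = cfg.params["simulate"]
        sim = synthetic.SimulationConfig(seed=cfg.seed, **p)
        matrix, ann, truth = synthetic.gen_omics_matrix(sim)
        drifted = synthetic.gen_drifted_runs(sim, matrix, ann, truth)
        sup, sup_truth = synthetic.gen_supernatant_series(sim)
        truth.supernatant_slopes = sup_truth.supernatant_slopes
        growth, migration = synthetic.gen_phenotype_tables(sim)
        ions, ref = synthetic.gen_ion_table(sim)
        sets = synthetic.gen_gene_sets(
            matrix.feature_ids, truth, n_pathways=20,
            set_size=min(50, sim.n_features), seed=sim.seed + 4,
        )
        io.write_matrix(drifted, out("matrix.tsv"), header=prov)
        io.write_metadata(ann, out("metadata.tsv"), header=prov)
        sup.to_csv(out("supernatant.tsv"), sep="\t", index=False)
        growth.to_csv(out("growth.tsv"), sep="\t", index=False)
        migration.to_csv(out("migration.tsv"), sep="\t", index=False)
        ions.to_csv(out("ions.tsv"), sep="\t", index=False)
        io.write_mass_list(ref, out("masses.tsv"))
        io.write_gmt(sets, out("pathways.gmt"))
        synthetic.write_truth(truth, out("truth.json"))
        cfg.paths.update(
            matrix=out("matrix.tsv"), metadata=out("metadata.tsv"),
            supernatant=out("supernatant.tsv"), growth=out("growth.tsv"),
            migration=out("migration.tsv"), ions=out("ions.tsv"),
            masses=out("masses.tsv"), gmt=out("pathways.gmt"),
        )
        return {"n_features": matrix.shape[0], "n_samples": matrix.shape[1]}

    def stage_annotate():
        p = cfg.params["annotate"]
        ions = pd.read_csv(cfg.paths["ions"], sep="\t", comment="#")
        ref = io.read_mass_list(cfg.paths["masses"])
        hits = annotation.annotate_ions(
            ions, ref, tolerance=float(p.get("tolerance", 0.001)),
            adduct=p.get("adduct", "[M-H]-"),
        )
        _write_tsv(hits, out("annotation.tsv"), cfg)
        return {"n_hits": len(hits)}

    def stage_normalize():
        p = cfg.params["normalize"]
        m = io.read_matrix(cfg.paths["matrix"])
        ann = io.read_metadata(cfg.paths["metadata"])
        corrected, model = normalization.moving_median_drift_correct(
            m, ann.table["acquisition_index"], window=int(p.get("window", 15))
        )
        normalized = normalization.celltype_mean_normalize(corrected, ann)
        io.write_matrix(normalized, out("matrix_normalized.tsv"), header=prov)
        drift = pd.DataFrame(
            {"sample_id": model.scale_factors.index,
             "scale_factor": model.scale_factors.to_numpy()}
        )
        _write_tsv(drift, out("drift_report.tsv"), cfg)
        state["normalized"] = normalized
        state["metadata"] = ann
        return {"n_samples": normalized.shape[1]}

    def stage_diff():
        p = cfg.params["diff"]
        m = state.get("normalized") or io.read_matrix(cfg.paths["matrix"])
        ann = state.get("metadata") or io.read_metadata(cfg.paths["metadata"])
        quiescent = ann.samples_where(state="quiescent")
        proliferating = ann.samples_where(state="proliferating")
        quiescent = [s for s in quiescent if s in m.sample_ids]
        proliferating = [s for s in proliferating if s in m.sample_ids]
        records = diffstats.two_group_test(
            m, quiescent, proliferating, variant=p.get("variant", "welch")
        )
        records = diffstats.filter_significant(
            records,
            fc_cutoff=float(p.get("fc", 0.5)),
            alpha=float(p.get("alpha", 0.05)),
            correction=p.get("correction", "storey"),
        )
        _write_tsv(records.reset_index(names="feature_id"), out("diff.tsv"), cfg)
        state["diff"] = records
        return {"n_features": len(records),
                "n_significant": int(records["significant"].sum())}

    def stage_enrich():
        p = cfg.params["enrich"]
        sets = io.read_gmt(cfg.paths["gmt"])
        records = state.get("diff")
        if records is None:
            records = pd.read_csv(out("diff.tsv"), sep="\t", comment="#",
                                  index_col="feature_id")
        res = enrichment.directional_enrichment(
            records, sets, mode=p.get("mode", "protein")
        )
        _write_tsv(res, out("enrichment.tsv"), cfg)
        return {"n_pathways": len(res),
                "n_significant": int(res["significant"].sum()) if len(res) else 0}

    def stage_plsda():
        p = cfg.params["plsda"]
        m = state.get("normalized") or io.read_matrix(cfg.paths["matrix"])
        ann = state.get("metadata") or io.read_metadata(cfg.paths["metadata"])
        classes = ann.table.loc[m.sample_ids, "vascular_bed"]
        model = plsda_mod.fit_plsda(m, classes, n_components=2)
        sel = plsda_mod.bootstrap_select(
            m, classes,
            B=int(p.get("B", 1000)),
            tail_fraction=float(p.get("tail", 0.10)),
            consensus=float(p.get("consensus", 0.9)),
            seed=cfg.seed,
            mode=p.get("select_mode", "consensus"),
        )
        _write_tsv(model.weights.reset_index(names="feature_id"),
                   out("plsda_weights.tsv"), cfg)
        for fname, ids in (("lec_markers.txt", sel.lec_features),
                           ("bec_markers.txt", sel.bec_features)):
            with open(out(fname), "w", encoding="utf-8") as fh:
                fh.write("\n".join(sorted(ids)) + "\n")
        summary = {"n_lec": len(sel.lec_features), "n_bec": len(sel.bec_features)}
        n_perm = int(p.get("permutations", 0))
        if n_perm:
            perm = plsda_mod.permutation_null(
                m, classes, n_permutations=n_perm,
                tail_fraction=sel.tail_fraction, consensus=sel.consensus,
                B_inner=int(p.get("B_inner", 100)), seed=cfg.seed,
                level=p.get("permutation_level", "sample"),
                cell_types=ann.table.loc[m.sample_ids, "cell_type"],
            )
            summary.update(p_top=perm.p_top, p_bottom=perm.p_bottom,
                           p_combined=perm.p_combined)
        with open(out("plsda_summary.json"), "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2)
        return summary

    def stage_rates():
        sup = io.read_supernatant(cfg.paths["supernatant"])
        normalized = rates_mod.normalize_to_t0(sup)
        records = rates_mod.fit_rate(normalized)
        zmat = rates_mod.rate_zscore_table(records)
        _write_tsv(records, out("rates.tsv"), cfg)
        _write_tsv(zmat.reset_index(), out("rate_zscores.tsv"), cfg)
        return {"n_rates": len(records)}

    def stage_phenotype():
        p = cfg.params["phenotype"]
        control = p.get("control", "control")
        growth = io.read_growth(cfg.paths["growth"])
        migration = io.read_migration(cfg.paths["migration"])
        results = []
        for cond, grp in growth.groupby("condition"):
            if cond == control:
                continue
            cmp_ = pheno.growth_auc_test(grp, growth[growth["condition"] == control])
            results.append({"condition": cond, "welch_t": cmp_.welch_t, "p": cmp_.p,
                            "mean_auc_treated": float(cmp_.auc_treated.mean()),
                            "mean_auc_control": float(cmp_.auc_control.mean())})
        _write_tsv(pd.DataFrame(results), out("growth_tests.tsv"), cfg)
        mig = pheno.migration_rate(migration, control=control)
        _write_tsv(mig, out("migration_rates.tsv"), cfg)
        return {"n_growth_tests": len(results), "n_migration_wells": len(mig)}

    run_stage("simulate", stage_simulate)
    cfg.validate()
    run_stage("annotate", stage_annotate)
    run_stage("normalize", stage_normalize)
    run_stage("diff", stage_diff)
    run_stage("enrich", stage_enrich)
    run_stage("plsda", stage_plsda)
    run_stage("rates", stage_rates)
    run_stage("phenotype", stage_phenotype)

    with open(out("run_report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    return report
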