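"""End-to-end orchestration: simulate or ingest data, derive and score the
panel, stratify, run association and survival analyses, and emit a report
bundle of tab-delimited tables with a manifest, run log, and config echo.

Outputs contain no timestamps, so a rerun with the same configuration (and
seed) is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association, scoring, selection, simulate, survival
from .io import (
    ROLE_TUMOUR,
    GenePanel,
    load_gene_panel,
    read_expression_table,
    write_expression_table,
)

ALL_STAGES = ("de", "associations", "drugs", "survival", "treatment")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    mode: str = "simulate"                       # "simulate" | "ingest"
    sim: simulate.SimConfig | None = None
    paths: dict[str, str] | None = None          # expression / survival / drugs
    panel: str = "ces14"
    strata_mode: str = "quantile_tertile"
    stages: tuple[str, ...] = ALL_STAGES
    out_dir: str = "cescore_run"
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of human-readable issues; empty iff the run can start."""
    issues: list[str] = []
    if config.mode not in ("simulate", "ingest"):
        issues.append(f"mode: must be 'simulate' or 'ingest', got {config.mode!r}")
        return issues
    if config.sim is not None and config.paths is not None:
        issues.append("exactly one of sim / paths may be set, found both")
    if config.mode == "simulate" and config.paths is not None:
        issues.append("mode=simulate must not set paths")
    if config.mode == "ingest":
        if config.paths is None:
            issues.append("mode=ingest requires paths")
        else:
            if "expression" not in config.paths:
                issues.append("paths: missing mandatory 'expression' entry")
            if "survival" in config.stages and "survival" not in config.paths:
                issues.append("survival stage enabled without a survival table path")
            if "treatment" in config.stages and "survival" not in config.paths:
                issues.append("treatment stage enabled without a survival table path")
            if "drugs" in config.stages and "drugs" not in config.paths:
                issues.append("drugs stage enabled without a drug-response table path")
            for key, p in (config.paths or {}).items():
                if not Path(p).exists():
                    issues.append(f"paths.{key}: file not found: {p}")
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        issues.append(f"stages: unknown stage(s) {sorted(unknown)}")
    if config.strata_mode not in scoring.MODES:
        issues.append(f"strata_mode: unknown mode {config.strata_mode!r}")
    return issues


@dataclass
class ReportBundle:
    out_dir: Path
    manifest: dict[str, str] = field(default_factory=dict)
    stage_errors: dict[str, str] = field(default_factory=dict)
    log_lines: list[str] = field(default_factory=list)

    def path(self, key: str) -> Path:
        return self.out_dir / self.manifest[key]


class ConfigurationError(ValueError):
    pass


def _write_tsv(bundle: ReportBundle, key: str, df: pd.DataFrame, index: bool = True) -> None:
    name = f"{key}.tsv"
    df.to_csv(bundle.out_dir / name, sep="\t", index=index, lineterminator="\n")
    bundle.manifest[key] = name


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the enabled stages in dependency order.

    Optional-stage failures are recorded in ``stage_errors`` without aborting
    the remaining stages.  Missing mandatory inputs fail before any compute.
    """
    issues = validate_config(config)
    if issues:
        raise ConfigurationError("; ".join(issues))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out_dir)
    log = bundle.log_lines

    sim_cfg = config.sim
    if config.mode == "simulate" and sim_cfg is None:
        sim_cfg = simulate.SimConfig(seed=config.seed)

    # ---- stage: data -----------------------------------------------------
    truth: simulate.SimTruth | None = None
    if config.mode == "simulate":
        assert sim_cfg is not None
        if not sim_cfg.planted_log2fc:
            sim_cfg = dataclasses.replace(
                sim_cfg, planted_log2fc={g: 1.5 for g in sim_cfg.panel_genes}
            )
        datasets, truth = simulate.simulate_expression_datasets(sim_cfg)
        log.append(f"simulated {len(datasets)} expression dataset(s), seed={sim_cfg.seed}")
        for i, mat in enumerate(datasets):
            name = f"expression_dataset_{i}.tsv"
            write_expression_table(mat, out_dir / name)
            bundle.manifest[f"expression_dataset_{i}"] = name
        truth.to_json(out_dir / "sim_truth.json")
        bundle.manifest["sim_truth"] = "sim_truth.json"
        panel = GenePanel(name="sim_panel", genes=tuple(sim_cfg.panel_genes))
    else:
        assert config.paths is not None
        datasets = [read_expression_table(config.paths["expression"])]
        log.append(f"ingested expression from {config.paths['expression']}")
        panel = load_gene_panel(config.panel)

    # ---- stage: DE / panel selection -------------------------------------
    derived_panel = panel
    if "de" in config.stages:
        try:
            de_results = [
                selection.differential_expression(m, seed=config.seed) for m in datasets
            ]
            for i, de in enumerate(de_results):
                _write_tsv(bundle, f"de_dataset_{i}", de)
            upregulated = selection.cross_dataset_filter(de_results)
            log.append(f"cross-dataset filter kept {len(upregulated)} gene(s)")
            evidence: dict[str, set[str]] = (
                {"planted_truth": set(truth.planted_up_genes)}
                if truth is not None
                else {"upregulated": set(upregulated)}
            )
            derived = selection.derive_panel(upregulated, evidence)
            derived_panel = derived.panel
            prov = pd.DataFrame(
                {
                    "gene": list(derived.provenance),
                    "evidence": [",".join(v) for v in derived.provenance.values()],
                }
            )
            _write_tsv(bundle, "panel", prov, index=False)
        except Exception as exc:  # stage isolation
            bundle.stage_errors["de"] = str(exc)
            log.append(f"stage de FAILED: {exc}")
            derived_panel = panel

    # ---- stage: scoring + strata (always on) ------------------------------
    primary = datasets[0]
    tumours = primary.samples_with_role(ROLE_TUMOUR)
    score_matrix = primary.subset_samples(tumours) if tumours else primary
    ces = scoring.compute_ces(score_matrix, derived_panel, allow_missing=True)
    strata = scoring.stratify(ces, mode=config.strata_mode)
    scored = ces.to_frame().merge(strata.to_frame(), on="sample_id")
    _write_tsv(bundle, "scores", scored, index=False)
    log.append(
        f"scored {len(ces.scores)} sample(s) with panel {derived_panel.name!r} "
        f"({ces.n_genes_used}/{ces.panel_size} genes), strata mode {strata.mode}"
    )

    # ---- stage: associations ----------------------------------------------
    if "associations" in config.stages:
        try:
            if config.mode == "simulate":
                assert sim_cfg is not None
                metrics = simulate.simulate_instability(ces.scores, sim_cfg)
            elif config.paths and "instability" in config.paths:
                metrics = pd.read_csv(config.paths["instability"], sep="\t", index_col=0)
            else:
                raise ValueError("no instability metrics available")
            corr = association.spearman_with_fdr(
                {
                    "cohort": {
                        col: (ces.scores.loc[metrics.index].to_numpy(), metrics[col].to_numpy())
                        for col in metrics.columns
                    }
                }
            )
            _write_tsv(bundle, "associations", corr.table, index=False)
            net = association.coexpression_network(
                score_matrix.subset_genes(
                    [g for g in derived_panel.genes if g in score_matrix.values.index]
                )
            )
            _write_tsv(bundle, "network_edges", net.edges, index=False)
            _write_tsv(bundle, "network_degrees", net.degrees, index=False)
            log.append(
                f"associations: {len(corr.table)} correlation row(s), "
                f"{len(net.edges)} network edge(s)"
            )
        except Exception as exc:
            bundle.stage_errors["associations"] = str(exc)
            log.append(f"stage associations FAILED: {exc}")

    # ---- stage: survival (and shared cohort) -------------------------------
    cohort: pd.DataFrame | None = None
    if config.mode == "simulate" and (
        "survival" in config.stages or "treatment" in config.stages
    ):
        assert sim_cfg is not None
        cohort = simulate.simulate_cohort(sim_cfg, ces.scores)
        _write_tsv(bundle, "cohort", cohort)
    elif config.paths and "survival" in config.paths:
        cohort = pd.read_csv(config.paths["survival"], sep="\t", index_col=0)

    if "survival" in config.stages:
        try:
            if cohort is None:
                raise ValueError("no survival data available")
            strat_labels = strata.labels.loc[cohort.index]
            km_rows = []
            for label in strat_labels.unique():
                sub = cohort.loc[strat_labels == label]
                km = survival.km_estimate(sub["time"], sub["event"])
                frame = km.to_frame()
                frame.insert(0, "stratum", label)
                km_rows.append(frame)
            _write_tsv(bundle, "km_curves", pd.concat(km_rows, ignore_index=True), index=False)
            lr = survival.logrank_test(cohort["time"], cohort["event"], strat_labels)
            _write_tsv(
                bundle,
                "logrank",
                pd.DataFrame(
                    [{"statistic": lr.statistic, "p": lr.p_value, "df": lr.df, "n": lr.n}]
                ),
                index=False,
            )
            covs = ["z"] if "z" in cohort.columns else []
            for extra in ("grade", "er_status"):
                if extra in cohort.columns and cohort[extra].nunique() > 1:
                    covs.append(extra)
            if covs and cohort["event"].sum() >= len(covs) + 1:
                cox = survival.cox_fit(cohort, covs)
                _write_tsv(bundle, "cox", cox.table)
            log.append(f"survival: log-rank p={lr.p_value:.4g} over {lr.n} subjects")
        except Exception as exc:
            bundle.stage_errors["survival"] = str(exc)
            log.append(f"stage survival FAILED: {exc}")

    # ---- stage: treatment interaction --------------------------------------
    if "treatment" in config.stages:
        try:
            if cohort is None or "treated" not in (cohort.columns if cohort is not None else []):
                raise ValueError("no treatment-annotated cohort available")
            binary = scoring.stratify(ces.scores.loc[cohort.index], mode="top_tertile_vs_rest")
            tc = cohort.copy()
            tc["stratum"] = binary.labels
            forest = survival.stratified_treatment_analysis(tc)
            _write_tsv(bundle, "forest", forest.to_frame(), index=False)
            for note in forest.dropped:
                log.append(f"treatment: dropped {note}")
            log.append(f"treatment: {len(forest.rows)} forest row(s)")
        except Exception as exc:
            bundle.stage_errors["treatment"] = str(exc)
            log.append(f"stage treatment FAILED: {exc}")

    # ---- stage: drugs -------------------------------------------------------
    if "drugs" in config.stages:
        try:
            if config.mode == "simulate":
                assert sim_cfg is not None
                cl_matrix, drug_table, cl_truth = simulate.simulate_celllines(sim_cfg)
                cl_scores = scoring.compute_ces(cl_matrix, derived_panel, allow_missing=True).scores
            else:
                assert config.paths is not None
                drug_table = pd.read_csv(config.paths["drugs"], sep="\t", index_col=0)
                cl_scores = ces.scores
            res = association.drug_sensitivity_analysis(cl_scores, drug_table)
            summary = res.spearman.table.copy()
            _write_tsv(bundle, "drug_spearman", summary, index=False)
            _write_tsv(
                bundle,
                "drug_quartiles",
                pd.DataFrame(
                    [
                        {
                            "wilcoxon_statistic": res.quartile_statistic,
                            "wilcoxon_p": res.quartile_p,
                            "n_used": res.n_used,
                            "n_excluded": len(res.flagged_outliers),
                        }
                    ]
                ),
                index=False,
            )
            log.append(
                f"drugs: quartile p={res.quartile_p:.4g}, "
                f"{len(res.flagged_outliers)} outlier(s) excluded"
            )
        except Exception as exc:
            bundle.stage_errors["drugs"] = str(exc)
            log.append(f"stage drugs FAILED: {exc}")

    # ---- provenance ---------------------------------------------------------
    echo = config.to_jsonable()
    if config.mode == "simulate" and sim_cfg is not None:
        echo["sim"] = dataclasses.asdict(sim_cfg)
        echo["sim"]["panel_genes"] = list(echo["sim"]["panel_genes"])
    (out_dir / "config.json").write_text(json.dumps(echo, indent=2, sort_keys=True))
    bundle.manifest["config"] = "config.json"
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    bundle.manifest["run_log"] = "run.log"
    manifest = dict(sorted(bundle.manifest.items()))
    manifest["stage_errors"] = bundle.stage_errors  # type: ignore[assignment]
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return bundle
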