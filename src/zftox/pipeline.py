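"""End-to-end pipeline: simulate -> preprocess -> model -> annotate -> summarize.

Every stage writes plain-text artifacts (TSV/JSON/MGF) into the output
directory; a run manifest records per-stage input/output row counts and the
resolved configuration, so identical config + seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biotp import AnnotationConfig, annotate_biotps
from .containers import FeatureTable
from .endpoints import (
    CalibrationCurve,
    check_doses,
    hatching_comparison,
    summarize_endpoints,
)
from .modeling import (
    RdcvParams,
    build_model_suite,
    default_model_specs,
    elected_union,
    group_mean_matrix,
    permutation_test,
    rescale_rows,
    select_model_samples,
)
from .preprocessing import CascadeConfig, normalize_to_is, run_filter_cascade
from .synthetic import (
    SimConfig,
    make_plate_layout,
    predicted_biotp_mzs,
    reference_spectrum_library,
    simulate_feature_table,
    simulate_query_spectra,
)
from .spectra import write_mgf

STAGES = ("simulate", "preprocess", "model", "biotp", "endpoints")

# measured exposure-medium concentrations (ug/L) for the demo dose check,
# matched to the nominal ladder 0.5 .. 50000
DEFAULT_MEASURED_DOSES = (0.46, 3.85, 41.0, 445.0, 4854.0, 43367.0)


def _strict_init(cls, values: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    return cls(**values)


@dataclass
class ModelingConfig:
    """Desk-scale rdCV settings for pipeline runs; the engine-level defaults
    (10 repetitions, 6 outer folds) are heavier and set in RdcvParams."""

    n_repetitions: int = 2
    n_outer_folds: int = 5
    elimination_ratio: float = 0.4
    n_estimators: int = 30
    model_size: str = "mid"
    min_elected: int = 5
    n_permutations: int = 0  # permutations per model (0 = skip)
    permute_models: tuple[str, ...] = ("AllRegress", "AllClass")

    def rdcv(self) -> RdcvParams:
        return RdcvParams(
            n_repetitions=self.n_repetitions,
            n_outer_folds=self.n_outer_folds,
            elimination_ratio=self.elimination_ratio,
            n_estimators=self.n_estimators,
            model_size=self.model_size,
        )


@dataclass
class EndpointsConfig:
    measured_doses: tuple[float, ...] = DEFAULT_MEASURED_DOSES
    n_replicates: int = 3
    replicate_cv: float = 0.06


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "zftox_out"
    simulation: SimConfig | None = None
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    modeling: ModelingConfig = field(default_factory=ModelingConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    endpoints: EndpointsConfig = field(default_factory=EndpointsConfig)
    # optional pre-existing inputs (TSV paths); when absent, simulation runs
    feature_table: str | None = None
    sample_table: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sections = {
            "simulation": SimConfig,
            "cascade": CascadeConfig,
            "modeling": ModelingConfig,
            "annotation": AnnotationConfig,
            "endpoints": EndpointsConfig,
        }
        kwargs: dict = {}
        seed = d.get("seed", 1)
        for key, section_cls in sections.items():
            if key in d:
                vals = dict(d.pop(key) or {})
                if key == "simulation":
                    vals.setdefault("seed", seed)
                kwargs[key] = _strict_init(section_cls, vals, key)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def resolved(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [conv(v) for v in obj]
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return conv(self)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, **counts) -> None:
        self.stages.append({"stage": stage, **counts})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"config_hash": self.config_hash, "version": self.version, "stages": self.stages},
                indent=1,
            )
        )


def validate_inputs(feature_path: str | Path, sample_path: str | Path) -> list[str]:
    """Schema check of the TSV contract; violations are listed, not raised."""
    report: list[str] = []
    for p in (feature_path, sample_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    wide = pd.read_csv(feature_path, sep="\t")
    required = ["feature_id", "mz", "rt_seconds", "assay"]
    for col in required:
        if col not in wide.columns:
            report.append(f"missing column {col!r} in feature table")
    if "feature_id" in wide.columns and wide["feature_id"].duplicated().any():
        report.append("duplicate feature_id values in feature table")
    samples = pd.read_csv(sample_path, sep="\t")
    if "sample_id" not in samples.columns:
        report.append("missing column 'sample_id' in sample table")
    elif samples["sample_id"].duplicated().any():
        report.append("duplicate sample_id values in sample table")
    sample_cols = [c for c in wide.columns if c not in required]
    for col in sample_cols:
        bad = pd.to_numeric(wide[col], errors="coerce").isna() & wide[col].notna()
        for idx in wide.index[bad]:
            report.append(f"non-numeric intensity in column {col!r}, row {idx}")
    return report


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Execute all stages in order; any stage error aborts with the stage name
    attached and the partial manifest written."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = config.resolved()
    cfg_text = yaml.safe_dump(resolved, sort_keys=True)
    (out / "resolved_config.yaml").write_text(cfg_text)
    manifest = RunManifest(hashlib.sha256(cfg_text.encode()).hexdigest()[:16], __version__)

    stage = "simulate"
    try:
        sim = config.simulation or SimConfig(seed=config.seed)
        if config.feature_table:
            if not Path(config.feature_table).exists():
                raise FileNotFoundError(f"input file not found: {config.feature_table}")
            table = FeatureTable.from_tsv(config.feature_table, config.sample_table)
            truth = None
        else:
            layout = make_plate_layout(sim.n_doses, sim.n_per_group, sim.n_neg, sim.n_pos,
                                       sim.nominal_doses)
            table, truth = simulate_feature_table(layout, sim)
            table.to_tsv(out / "features_raw.tsv", out / "samples.tsv")
            truth.to_json(out / "sim_truth.json")
        spectra = simulate_query_spectra(truth, table, sim.seed) if truth is not None else {}
        library = reference_spectrum_library(sim.seed)
        if spectra:
            write_mgf(list(spectra.values()), out / "query_spectra.mgf")
        write_mgf(library, out / "reference_library.mgf")
        manifest.add(stage, n_features=len(table.feature_ids), n_samples=len(table.sample_ids))

        stage = "preprocess"
        cascade = config.cascade
        if cascade.parent_mz is None:
            parent_mz = next(mz for r, a, mz in predicted_biotp_mzs(sim)
                             if r == "parent" and a == "[M+H]")
            cascade = dataclasses.replace(
                cascade, parent_mz=parent_mz, parent_rt=sim.parent_rt,
                predicted_biotp_masses=[mz for r, _, mz in predicted_biotp_mzs(sim)
                                        if r != "parent"],
            )
        is_ids = (truth.ids_with_label("internal_standard") if truth is not None else [])
        normed = normalize_to_is(table, is_ids) if is_ids else table
        filtered, audit = run_filter_cascade(normed, cascade)
        filtered.to_tsv(out / "features_filtered.tsv", out / "samples.tsv")
        filtered.audit_to_json(out / "filter_audit.jsonl")
        manifest.add(stage, n_features_in=len(table.feature_ids),
                     n_features_out=len(filtered.feature_ids))

        stage = "model"
        mc = config.modeling
        specs = default_model_specs(config.seed, rdcv=mc.rdcv())
        results = build_model_suite(filtered, specs, min_elected=mc.min_elected)
        if mc.n_permutations > 0:
            for spec in specs:
                res = results[spec.name]
                if res.error is None and spec.name in mc.permute_models:
                    X, yv = select_model_samples(filtered, spec)
                    perm = permutation_test(X, yv, spec, mc.n_permutations, observed=res)
                    res.permutation_p = perm.p_normal
                    res.permutation_p_empirical = perm.p_empirical
                    res.n_permutations = mc.n_permutations
        union = elected_union(results)
        model_report = {}
        for name, res in results.items():
            model_report[name] = {
                "mode": res.mode,
                "fitness": None if np.isnan(res.fitness) else res.fitness,
                "n_samples": res.n_samples,
                "elected_features": res.elected_features,
                "discarded": res.discarded,
                "permutation_p": res.permutation_p,
                "permutation_p_empirical": res.permutation_p_empirical,
                "error": res.error,
            }
            if res.mode == "classification" and res.error is None:
                pd.crosstab(
                    res.oof_predictions, res.y, rownames=["predicted"], colnames=["actual"]
                ).to_csv(out / f"confusion_{name}.tsv", sep="\t")
        (out / "model_results.json").write_text(json.dumps(
            {"models": model_report, "elected_union": union}, indent=1))
        if union:
            means = group_mean_matrix(filtered, union)
            rescale_rows(means).to_csv(out / "heatmap_matrix.tsv", sep="\t")
        manifest.add(stage, n_models=len(results),
                     n_retained=sum(1 for r in results.values()
                                    if r.error is None and not r.discarded),
                     n_elected_union=len(union))

        stage = "biotp"
        report = annotate_biotps(table, spectra, library, config.annotation)
        report.to_csv(out / "biotp_candidates.tsv", sep="\t", index=False)
        manifest.add(stage, n_matches=len(report),
                     n_cl1=int((report["confidence_level"] == 1).sum()) if len(report) else 0)

        stage = "endpoints"
        summaries = summarize_endpoints(table.samples)
        ep = {g: s.to_dict() for g, s in summaries.items()}
        pd.DataFrame(ep).T.to_csv(out / "endpoint_summaries.tsv", sep="\t", index=False)
        hatching = {}
        control = summaries.get("negative_control")
        if control is not None:
            for g, s in summaries.items():
                if g.startswith("dose_"):
                    hatching[g] = hatching_comparison(s, control)
        # dose confirmation from a synthetic IS-normalized calibration
        epc = config.endpoints
        rng = np.random.default_rng(config.seed + 7)
        cal_conc = np.array([1.0, 2.0, 5.0, 10.0, 20.0, 50.0])
        curve = CalibrationCurve.fit(cal_conc, 0.8 * cal_conc)
        replicate_responses = {}
        dilutions = {}
        for nominal, measured in zip(sorted(sim.nominal_doses), sorted(epc.measured_doses)):
            dilution = max(measured / 20.0, 1.0)  # dilute into calibration range
            base = 0.8 * measured / dilution
            reps = base * rng.normal(1.0, epc.replicate_cv, size=epc.n_replicates)
            replicate_responses[nominal] = list(reps)
            dilutions[nominal] = dilution
        checks = check_doses(curve, replicate_responses, dilutions)
        (out / "endpoints.json").write_text(json.dumps(
            {
                "groups": ep,
                "hatching_p_vs_control": hatching,
                "dose_checks": [dataclasses.asdict(c) for c in checks],
            },
            indent=1,
        ))
        manifest.add(stage, n_groups=len(ep), n_dose_checks=len(checks))
    except Exception as exc:
        manifest.add(stage, error=str(exc))
        manifest.to_json(out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.to_json(out / "manifest.json")
    return manifest
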