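"""End-to-end workflows: configuration, file formats, logging, run records.

Two workflows mirror the study design.  The metabolomics workflow takes (or
simulates) binned spectra with two class labels and runs: class-size
balancing -> OPLS-DA fit -> VIP ranking -> repeated-CV accuracy ensemble with
its permutation-null twin -> per-feature ROC/AUC -> univariate statistics on
the top discriminators.  The phenotype workflow fits PCA to a binary
clinico-radiologic matrix, writes scores/loadings/explained-variance tables,
and projects a predictive set of reference patients into the model.

All randomness flows from one top-level seed through named per-stage
substreams, so a rerun with the same config is numerically byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import substream_seed
from .binning import BinSpec, FeatureMatrix, build_feature_matrix, read_spectrum_csv
from .group_stats import compare_two_groups
from .oplsda import fit_oplsda, rank_vip, vip_scores
from .pca import BinaryPhenotypeMatrix, assign_clusters, fit_pca, loadings_table, project
from .synth import PhenotypeConfig, SpectraConfig, generate_binary_phenotypes, generate_feature_matrix
from .validation import (
    balance_classes,
    compare_ensembles,
    cv_ensemble,
    permutation_ensemble,
    roc_auc,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "RunRecord",
    "load_config",
    "save_config",
    "run_metabolomics_workflow",
    "run_phenotype_workflow",
]

log = logging.getLogger("chemoclass")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the offending input."""


@dataclass
class PathSettings:
    spectra_dir: str | None = None
    feature_matrix: str | None = None
    labels: str | None = None
    phenotype_matrix: str | None = None
    predictive_phenotype_matrix: str | None = None


@dataclass
class BinningSettings:
    regions: list = field(default_factory=lambda: [[0.80, 4.20], [5.20, 8.50]])
    bin_width: float = 0.02
    normalization: str = "unit_total"

    def binspec(self) -> BinSpec:
        return BinSpec(regions=tuple(tuple(r) for r in self.regions), bin_width=self.bin_width)


@dataclass
class OplsdaSettings:
    n_orthogonal: int = 1
    scaling: str = "unit_variance"
    vip_threshold: float = 1.75
    vip_variant: str = "total"


@dataclass
class ValidationSettings:
    k_folds: int = 10
    n_iterations: int = 100


@dataclass
class PcaSettings:
    n_components: int = 2
    scaling: str = "unit_variance"
    kmeans_k: int = 0  # 0 disables the optional k-means cluster surrogate


@dataclass
class PipelineConfig:
    paths: PathSettings = field(default_factory=PathSettings)
    binning: BinningSettings = field(default_factory=BinningSettings)
    oplsda: OplsdaSettings = field(default_factory=OplsdaSettings)
    validation: ValidationSettings = field(default_factory=ValidationSettings)
    pca: PcaSettings = field(default_factory=PcaSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.validation.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.validation.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.oplsda.n_orthogonal < 0:
            raise ValueError("n_orthogonal must be >= 0")
        if self.oplsda.vip_threshold < 0:
            raise ValueError("vip_threshold must be >= 0")
        if self.pca.n_components < 1:
            raise ValueError("pca n_components must be >= 1")
        self.binning.binspec()  # validates regions / width

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(dc_type, d: dict):
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(d) - names
            if unknown:
                raise ValueError(f"unknown config key(s) in {dc_type.__name__}: {sorted(unknown)}")
            return dc_type(**d)

        sections = {
            "paths": PathSettings,
            "binning": BinningSettings,
            "oplsda": OplsdaSettings,
            "validation": ValidationSettings,
            "pca": PcaSettings,
        }
        unknown = set(data) - set(sections) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {name: build(t, data.get(name, {})) for name, t in sections.items()}
        return cls(seed=int(data.get("seed", 0)), **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML or JSON pipeline config; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PipelineConfig.from_dict(data or {})


def save_config(config: PipelineConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))


@dataclass
class RunRecord:
    timestamp: str
    config: dict
    version: str
    seeds: dict
    output_digests: dict

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(config: PipelineConfig, seeds: dict, out_dir: Path, files: list[Path]) -> RunRecord:
    rec = RunRecord(
        timestamp=datetime.now(timezone.utc).isoformat(),
        config=config.to_dict(),
        version=__version__,
        seeds=seeds,
        output_digests={f.name: _digest(f) for f in files},
    )
    rec.write(out_dir / "run_record.json")
    return rec


def _load_metabolomics_inputs(config: PipelineConfig) -> FeatureMatrix:
    paths = config.paths
    if paths.feature_matrix:
        fm_path = Path(paths.feature_matrix)
        if not fm_path.exists():
            raise FileNotFoundError(f"feature matrix not found: {fm_path}")
        fm = FeatureMatrix.from_csv(fm_path)
        if paths.labels:
            lab_path = Path(paths.labels)
            if not lab_path.exists():
                raise FileNotFoundError(f"labels file not found: {lab_path}")
            fm.labels = pd.read_csv(lab_path).iloc[:, -1].to_numpy()
        if fm.labels is None:
            raise ValueError("no labels: supply a labels CSV or a label column")
        return fm
    if paths.spectra_dir:
        sdir = Path(paths.spectra_dir)
        manifest = sdir / "manifest.csv"
        if not manifest.exists():
            raise FileNotFoundError(f"spectra manifest not found: {manifest}")
        man = pd.read_csv(manifest)
        spectra = [read_spectrum_csv(sdir / f"{sid}.csv", sample_id=str(sid))
                   for sid in man["sample_id"]]
        return build_feature_matrix(
            spectra,
            binspec=config.binning.binspec(),
            normalization=config.binning.normalization,
            labels=man["class"].to_numpy(),
        )
    # no inputs: simulate the default study-structure cohort
    log.info("no input paths configured; simulating the default synthetic cohort")
    fm, _ = generate_feature_matrix(
        SpectraConfig(seed=substream_seed(config.seed, "synthetic-spectra")),
        binspec=config.binning.binspec(),
        normalization=config.binning.normalization,
    )
    return fm


def run_metabolomics_workflow(config: PipelineConfig, out_dir: str | Path) -> RunRecord:
    """bin -> OPLS-DA -> VIP -> CV ensembles (observed + null) -> AUC -> stats."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = {name: substream_seed(config.seed, name)
             for name in ("balance", "cv-observed", "cv-null", "auc-bootstrap")}
    files: list[Path] = []
    stage = "load-inputs"
    try:
        fm = _load_metabolomics_inputs(config)
        fm.to_csv(out_dir / "feature_matrix.csv")
        files += [out_dir / "feature_matrix.csv"]

        stage = "oplsda-fit"
        log.info("normalization=%s; y coded {0,1}, decision threshold 0.5; "
                 "VIP variant=%s", fm.normalization, config.oplsda.vip_variant)
        idx = balance_classes(fm.labels, seed=seeds["balance"])
        model = fit_oplsda(
            FeatureMatrix(fm.values[idx], fm.bin_centers,
                          [fm.sample_ids[i] for i in idx], fm.labels[idx],
                          fm.normalization),
            n_orthogonal=config.oplsda.n_orthogonal,
            scaling=config.oplsda.scaling,
        )
        vip = vip_scores(model, variant=config.oplsda.vip_variant)
        vip_df = pd.DataFrame(
            {
                "bin_center": fm.bin_centers[vip.ranking],
                "vip": vip.vip[vip.ranking],
                "rank": np.arange(1, vip.vip.size + 1),
            }
        )
        vip_df.to_csv(out_dir / "vip_table.csv", index=False)
        files += [out_dir / "vip_table.csv"]

        stage = "validation"
        obs = cv_ensemble(
            fm.values, fm.labels,
            k_folds=config.validation.k_folds,
            n_iterations=config.validation.n_iterations,
            model_config={"n_orthogonal": config.oplsda.n_orthogonal,
                          "scaling": config.oplsda.scaling},
            seed=seeds["cv-observed"],
        )
        null = permutation_ensemble(
            fm.values, fm.labels,
            k_folds=config.validation.k_folds,
            n_iterations=config.validation.n_iterations,
            model_config={"n_orthogonal": config.oplsda.n_orthogonal,
                          "scaling": config.oplsda.scaling},
            seed=seeds["cv-null"],
        )
        comparison = compare_ensembles(obs, null)
        log.info("ensemble comparison: Welch t-test plus distribution-free fraction")
        pd.DataFrame({"observed": obs.accuracies, "null": null.accuracies}).to_csv(
            out_dir / "ensemble_accuracies.csv", index=False
        )
        (out_dir / "ensemble_summary.json").write_text(
            json.dumps(dataclasses.asdict(comparison), indent=2)
        )
        files += [out_dir / "ensemble_accuracies.csv", out_dir / "ensemble_summary.json"]

        stage = "roc-auc"
        discriminators = rank_vip(vip, threshold=config.oplsda.vip_threshold)
        positive = model.classes[0]  # the minority/reference class
        auc_rows = []
        for feat_idx, bin_center, v in discriminators:
            roc = roc_auc(fm.values[:, feat_idx], fm.labels, positive_class=positive)
            auc_rows.append(
                {
                    "bin_center": bin_center,
                    "vip": v,
                    "auc": roc.auc,
                    "ci_low": roc.ci_low,
                    "ci_high": roc.ci_high,
                }
            )
        pd.DataFrame(auc_rows).to_csv(out_dir / "auc_table.csv", index=False)
        files += [out_dir / "auc_table.csv"]

        stage = "group-stats"
        stat_rows = []
        for feat_idx, bin_center, v in discriminators:
            cmp = compare_two_groups(fm.values[:, feat_idx], fm.labels, method="auto")
            stat_rows.append(
                {
                    "bin_center": bin_center,
                    "method": cmp.method,
                    "statistic": cmp.statistic,
                    "p_value": cmp.p_value,
                }
            )
        pd.DataFrame(stat_rows).to_csv(out_dir / "group_stats.csv", index=False)
        files += [out_dir / "group_stats.csv"]
    except (ValueError, FileNotFoundError) as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return _record(config, seeds, out_dir, files)


def run_phenotype_workflow(config: PipelineConfig, out_dir: str | Path) -> RunRecord:
    """fit PCA -> scores/loadings/explained variance -> project predictive set."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = {name: substream_seed(config.seed, name)
             for name in ("synthetic-phenotypes", "synthetic-predictive", "kmeans")}
    files: list[Path] = []
    stage = "load-phenotypes"
    try:
        if config.paths.phenotype_matrix:
            ppath = Path(config.paths.phenotype_matrix)
            if not ppath.exists():
                raise FileNotFoundError(f"phenotype matrix not found: {ppath}")
            matrix = BinaryPhenotypeMatrix.from_csv(ppath)
        else:
            matrix, _ = generate_binary_phenotypes(
                PhenotypeConfig(seed=seeds["synthetic-phenotypes"])
            )

        stage = "pca-fit"
        model = fit_pca(matrix, n_components=config.pca.n_components,
                        scaling=config.pca.scaling)
        pd.DataFrame(
            model.scores,
            index=pd.Index(matrix.patient_ids, name="patient_id"),
            columns=[f"PC{j + 1}" for j in range(model.n_components)],
        ).to_csv(out_dir / "pca_scores.csv")
        loadings_table(model).to_csv(out_dir / "pca_loadings.csv", index=False)
        pd.DataFrame(
            {
                "component": np.arange(1, model.n_components + 1),
                "explained_variance_fraction": model.explained_variance_fraction,
            }
        ).to_csv(out_dir / "pca_explained_variance.csv", index=False)
        files += [out_dir / "pca_scores.csv", out_dir / "pca_loadings.csv",
                  out_dir / "pca_explained_variance.csv"]

        stage = "project-predictive-set"
        if config.paths.predictive_phenotype_matrix:
            qpath = Path(config.paths.predictive_phenotype_matrix)
            if not qpath.exists():
                raise FileNotFoundError(f"predictive phenotype matrix not found: {qpath}")
            predictive = BinaryPhenotypeMatrix.from_csv(qpath)
        else:
            predictive, _ = generate_binary_phenotypes(
                PhenotypeConfig(cluster_sizes=(15, 15, 15),
                                seed=seeds["synthetic-predictive"])
            )
        proj = project(model, predictive)
        pd.DataFrame(
            proj,
            index=pd.Index(predictive.patient_ids, name="patient_id"),
            columns=[f"PC{j + 1}" for j in range(model.n_components)],
        ).to_csv(out_dir / "projected_scores.csv")
        files += [out_dir / "projected_scores.csv"]

        if config.pca.kmeans_k:
            stage = "assign-clusters"
            clusters = assign_clusters(model.scores, k=config.pca.kmeans_k,
                                       seed=seeds["kmeans"])
            pd.DataFrame(
                {"patient_id": matrix.patient_ids, "cluster": clusters}
            ).to_csv(out_dir / "clusters.csv", index=False)
            files += [out_dir / "clusters.csv"]
    except (ValueError, FileNotFoundError) as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return _record(config, seeds, out_dir, files)
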