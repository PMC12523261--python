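"""End-to-end experiment orchestration.

Runs the full factorial study design — feature sets {full spectra, SPA,
CARS, Grad-CAM++ at each threshold} x model families {PLSR, SVR, BPNN, CNN}
x analytes {prolamin, glutelin} — from a single config: generate or load
data, trim edge bands, screen outliers, split 4:1:1, select wavelengths,
fit, interpret, evaluate. Every artifact is written to the output directory
and a manifest records stage order, seeds, and content hashes; identical
configs reproduce identical manifests.

The Grad-CAM++ stage follows the study protocol: profiles are computed from
the full-spectra CNN on the *test* split's spectra. Selecting features from
test data is a leakage risk, so the split is configurable
(``gradcam_split: validation``) and the manifest flags the data flow either
way.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, feature_selection, interpretation, models, preprocessing
from ._nn import min_input_length
from .errors import ConfigError, SelectionError
from .synthetic import (ANALYTES, GeneratorConfig, generate_dataset,
                        load_generator_config, read_contents, read_spectra,
                        write_contents, write_spectra)

__all__ = ["ExperimentConfig", "run_experiment"]

VALID_MODELS = ("plsr", "svr", "bpnn", "cnn")


@dataclass
class ExperimentConfig:
    output_dir: str = "experiment_out"
    seed: int = 0
    # data source: either a synthetic generator config or file paths
    synthetic: GeneratorConfig | None = field(default_factory=GeneratorConfig)
    spectra_path: str | None = None
    contents_path: str | None = None
    # preprocessing
    trim_head: int = 0
    trim_tail: int = 0
    outlier_k_sd: float = 3.0
    outlier_components: int = 10
    split_ratio: tuple = (4, 1, 1)
    # factorial
    analytes: tuple = ANALYTES
    selections: tuple = ("full", "spa", "cars", "gradcampp@0.6", "gradcampp@0.7")
    model_families: tuple = ("plsr", "svr", "bpnn", "cnn")
    gradcam_split: str = "test"
    # per-stage parameter overrides
    spa_params: dict = field(default_factory=dict)
    cars_params: dict = field(default_factory=dict)
    plsr_params: dict = field(default_factory=dict)
    svr_params: dict = field(default_factory=dict)
    bpnn_params: dict = field(default_factory=dict)
    cnn_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.synthetic is None and not (self.spectra_path and self.contents_path):
            raise ConfigError("either a synthetic generator config or both "
                              "spectra_path and contents_path are required")
        for fam in self.model_families:
            if fam not in VALID_MODELS:
                raise ConfigError(f"unknown model family {fam!r}")
        for a in self.analytes:
            if a not in ANALYTES:
                raise ConfigError(f"unknown analyte {a!r}")
        if self.gradcam_split not in ("test", "validation"):
            raise ConfigError("gradcam_split must be 'test' or 'validation'")
        needs_cnn = any(s.startswith("gradcampp") for s in self.selections)
        if needs_cnn and "cnn" not in self.model_families:
            raise ConfigError(
                "Grad-CAM++ selections require the CNN model family"
            )
        for s in self.selections:
            base = s.split("@")[0]
            if base not in ("full", "spa", "cars", "gradcampp"):
                raise ConfigError(f"unknown selection method {s!r}")
            if base == "gradcampp":
                try:
                    float(s.split("@")[1])
                except (IndexError, ValueError):
                    raise ConfigError(
                        f"gradcampp selection needs a threshold, e.g. "
                        f"'gradcampp@0.6' (got {s!r})"
                    ) from None

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "synthetic" in doc and isinstance(doc["synthetic"], dict):
            from .synthetic import Band, ContentParams
            syn = dict(doc["synthetic"])
            if "content_params" in syn:
                syn["content_params"] = {
                    k: ContentParams(**v) if isinstance(v, dict) else v
                    for k, v in syn["content_params"].items()}
            if "band_library" in syn:
                syn["band_library"] = tuple(
                    Band(**b) if isinstance(b, dict) else b
                    for b in syn["band_library"])
            doc["synthetic"] = GeneratorConfig(**syn)
        for key in ("split_ratio", "analytes", "selections", "model_families"):
            if key in doc:
                doc[key] = tuple(doc[key])
        try:
            config = cls(**doc)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
        config.validate()
        return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def _fit_model(family, X_tr, y_tr, X_va, y_va, config, seed):
    if family == "plsr":
        return models.fit_plsr(X_tr, y_tr, **config.plsr_params)
    if family == "svr":
        return models.fit_svr(X_tr, y_tr, **config.svr_params)
    if family == "bpnn":
        return models.fit_bpnn(X_tr, y_tr, X_va, y_va, seed=seed,
                               **config.bpnn_params)
    if family == "cnn":
        params = dict(config.cnn_params)
        # shrink kernels when a small wavelength selection is below the
        # receptive field of the configured conv stack
        kernels = tuple(params.get("kernels", (7, 5)))
        for candidate in (kernels, (5, 3), (3, 3), (2, 2)):
            if X_tr.shape[1] >= min_input_length(candidate):
                params["kernels"] = candidate
                break
        else:
            raise ConfigError(
                f"{X_tr.shape[1]} selected bands are too few for any conv stack"
            )
        return models.fit_cnn(X_tr, y_tr, X_va, y_va, seed=seed, **params)
    raise ConfigError(f"unknown model family {family!r}")


def run_experiment(config: ExperimentConfig) -> dict:
    """Run all stages; return the manifest (also written to the output dir)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest = {"stages": [], "seed": config.seed, "artifacts": {},
                "reports": {}, "data_flow": []}

    def stage(name, **info):
        manifest["stages"].append({"name": name, **info})

    def artifact(name, path: Path):
        manifest["artifacts"][name] = _sha256(path)

    # --- data ---------------------------------------------------------------
    if config.synthetic is not None:
        spectra, contents = generate_dataset(config.synthetic)
        stage("generate", n_samples=config.synthetic.n_samples,
              seed=config.synthetic.seed)
    else:
        spectra = read_spectra(config.spectra_path)
        contents = read_contents(config.contents_path)
        if spectra.sample_ids != contents.sample_ids:
            raise ConfigError("spectra and contents sample ids do not align")
        stage("ingest", spectra=str(config.spectra_path),
              contents=str(config.contents_path))
    write_spectra(spectra, out / "spectra.csv")
    write_contents(contents, out / "contents.csv")
    artifact("spectra.csv", out / "spectra.csv")
    artifact("contents.csv", out / "contents.csv")

    # --- trim ---------------------------------------------------------------
    if config.trim_head or config.trim_tail:
        spectra = preprocessing.trim_bands(spectra, config.trim_head,
                                           config.trim_tail)
        write_spectra(spectra, out / "spectra_trimmed.csv")
        artifact("spectra_trimmed.csv", out / "spectra_trimmed.csv")
        stage("trim_bands", n_head=config.trim_head, n_tail=config.trim_tail,
              n_bands=spectra.n_bands)

    # --- outlier screen (one retained set for both analytes) ----------------
    reports = []
    for analyte in config.analytes:
        rep = preprocessing.remove_outliers_plsr(
            spectra, contents, analyte,
            n_components=config.outlier_components, k_sd=config.outlier_k_sd)
        _write_json(rep.to_dict(), out / f"outliers_{analyte}.json")
        artifact(f"outliers_{analyte}.json", out / f"outliers_{analyte}.json")
        reports.append(rep)
    retained = preprocessing.combined_retained(reports)
    spectra = spectra.take_samples(retained)
    contents = contents.take(retained)
    stage("remove_outliers", k_sd=config.outlier_k_sd,
          n_retained=len(retained))

    # --- split --------------------------------------------------------------
    split = preprocessing.split_dataset(spectra.n_samples, config.split_ratio,
                                        seed=config.seed)
    split.to_json(out / "split.json")
    artifact("split.json", out / "split.json")
    stage("split_dataset", ratio=list(config.split_ratio), sizes=list(split.sizes))

    wl = spectra.grid.wavelengths
    n_full = spectra.n_bands
    gradcam_idx = (split.test_idx if config.gradcam_split == "test"
                   else split.val_idx)

    for analyte in config.analytes:
        y = contents.values(analyte)
        X_tr, y_tr = spectra.values[split.train_idx], y[split.train_idx]
        X_va, y_va = spectra.values[split.val_idx], y[split.val_idx]

        # full-spectra CNN first: Grad-CAM++ selections depend on it
        full_models = {}
        needs_cnn = ("cnn" in config.model_families)
        if needs_cnn:
            full_models["cnn"] = _fit_model("cnn", X_tr, y_tr, X_va, y_va,
                                            config, seed=config.seed + 1)
            stage("fit_full_cnn", analyte=analyte, seed=config.seed + 1)

        selections = {}
        for sel_name in config.selections:
            base = sel_name.split("@")[0]
            if base == "full":
                selections[sel_name] = None
            elif base == "spa":
                selections[sel_name] = feature_selection.spa_select(
                    X_tr, y_tr, X_va, y_va, wavelengths=wl,
                    **config.spa_params)
            elif base == "cars":
                params = dict(config.cars_params)
                params.setdefault("seed", config.seed + 2)
                selections[sel_name] = feature_selection.cars_select(
                    X_tr, y_tr, wavelengths=wl, **params)
            else:  # gradcampp@<threshold>
                threshold = float(sel_name.split("@")[1])
                profile = interpretation.gradcampp_profile(
                    full_models["cnn"], spectra.take_samples(gradcam_idx))
                profile.to_json(out / f"profile_{analyte}.json")
                artifact(f"profile_{analyte}.json",
                         out / f"profile_{analyte}.json")
                manifest["data_flow"].append({
                    "stage": f"gradcampp@{threshold}:{analyte}",
                    "uses_split_spectra": config.gradcam_split,
                    "uses_targets": False,
                    "leakage_flag": config.gradcam_split == "test",
                })
                sel = feature_selection.threshold_select(
                    profile.mean, threshold, wavelengths=wl)
                if len(sel) == 0:
                    raise SelectionError(
                        f"gradcampp@{threshold} selected no wavelengths for "
                        f"{analyte}"
                    )
                selections[sel_name] = sel
            if selections[sel_name] is not None:
                p = out / "selections" / f"{analyte}_{base}"
                p.parent.mkdir(parents=True, exist_ok=True)
                selections[sel_name].to_json(p.with_suffix(".json"))
                artifact(f"selections/{analyte}_{sel_name}.json",
                         p.with_suffix(".json"))
            stage("select", analyte=analyte, method=sel_name,
                  n_selected=n_full if selections[sel_name] is None
                  else len(selections[sel_name]))

        for sel_name, sel in selections.items():
            sub = spectra if sel is None else spectra.take_bands(sel.indices)
            Xs_tr, Xs_va = sub.values[split.train_idx], sub.values[split.val_idx]
            for k, family in enumerate(config.model_families):
                if sel is None and family == "cnn" and "cnn" in full_models:
                    model = full_models["cnn"]
                else:
                    model = _fit_model(family, Xs_tr, y_tr, Xs_va, y_va,
                                       config, seed=config.seed + 10 + k)
                report = evaluation.evaluate(model, sub, contents, analyte,
                                             split, selection=sel,
                                             n_full=n_full)
                key = f"{analyte}/{sel_name}/{family}"
                path = out / "reports" / f"{analyte}_{sel_name.replace('@', '_')}_{family}.json"
                _write_json(report.to_dict(), path)
                artifact(f"reports/{key}", path)
                manifest["reports"][key] = report.to_dict()
                stage("fit_evaluate", analyte=analyte, selection=sel_name,
                      family=family)

    table = evaluation.render_table(
        [evaluation.EvaluationReport(**{
            "model_family": r["model_family"], "analyte": r["analyte"],
            "metrics": r["metrics"], "selection_method": r["selection_method"],
            "n_selected": r["n_selected"], "n_full": r["n_full"]})
         for r in manifest["reports"].values()])
    (out / "summary_table.txt").write_text(table + "\n")
    artifact("summary_table.txt", out / "summary_table.txt")

    manifest["config"] = _config_to_jsonable(config)
    _write_json(manifest, out / "manifest.json")
    # wall time recorded outside the manifest so reruns hash identically
    (out / "timing.txt").write_text(f"{time.time() - t0:.1f} s\n")
    return manifest


def _config_to_jsonable(config: ExperimentConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple, range)):
            return [convert(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return convert(config)
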