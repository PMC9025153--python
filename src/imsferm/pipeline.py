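"""End-to-end orchestration: simulate -> preprocess -> decompose -> classify
-> quantify, with a machine-readable run manifest.

The run mirrors the study design: duplicate raw measurements are generated
per sample, preprocessed into a RIP-relative cube, split stratified 80:20
into training and held-out samples; PCA and NNMF are fitted on the training
matrix only and held-out samples are projected onto the fitted models;
classifiers are scored by stratified cross-validation on the training scores
and by prediction accuracy on the held-out scores; NNMF components are
back-projected, matched to classes, integrated, and screened against the
microbial ground truth.

Every random operation references an explicit seed from the configuration,
so a rerun with the same configuration reproduces all numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify as cls
from . import decompose as dec
from . import io as fio
from . import preprocess as pre
from . import quantify as qnt
from . import simulate as sim

__all__ = ["RunConfig", "run_pipeline", "fold_change_summary"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat, YAML-serializable configuration of one full run."""

    # generator
    samples_per_class: int = 16
    duplicates_per_sample: int = 2
    noise_sd: float = 2.0
    drift_jitter_sd: float = 0.02
    amplitude_cv: float = 0.10
    depletion_fraction: float = 0.3
    baseline_drift_amplitude: float = 15.0
    saturation_ceiling: float = 350.0
    generator_seed: int = 0
    # preprocessing
    bin_factor: int = 5
    drift_lo: float = 1.03
    drift_hi: float = 2.0
    retention_lo: float = 150.0
    retention_hi: float = 600.0
    n_drift_points: int = 531
    # decomposition
    pca_components: int = 4
    nnmf_k: int = 4
    decompose_seed: int = 1
    nnmf_restarts: int = 5
    # classification
    classifiers: list = field(default_factory=lambda: ["lda", "knn5", "svm"])
    pls_components: int = 4
    cv_folds: int = 10
    split_fraction: float = 0.8
    split_seed: int = 1
    merge_mild_labels: bool = True
    # quantification
    library_csv: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls_, d: dict) -> "RunConfig":
        return cls_(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls_, path) -> "RunConfig":
        return cls_.from_dict(yaml.safe_load(Path(path).read_text()))

    def generator_config(self) -> sim.GeneratorConfig:
        return sim.GeneratorConfig(
            samples_per_class=self.samples_per_class,
            duplicates_per_sample=self.duplicates_per_sample,
            noise_sd=self.noise_sd,
            drift_jitter_sd=self.drift_jitter_sd,
            amplitude_cv=self.amplitude_cv,
            depletion_fraction=self.depletion_fraction,
            baseline_drift_amplitude=self.baseline_drift_amplitude,
            saturation_ceiling=self.saturation_ceiling,
            seed=self.generator_seed,
        )

    def preprocess_config(self) -> pre.PreprocessConfig:
        return pre.PreprocessConfig(
            bin_factor=self.bin_factor,
            drift_bounds=(self.drift_lo, self.drift_hi),
            retention_bounds=(self.retention_lo, self.retention_hi),
            n_drift_points=self.n_drift_points,
        )


def _merged_truth_patterns(
    truth: sim.GroundTruth,
    gen_config: sim.GeneratorConfig,
    pre_config: pre.PreprocessConfig,
) -> tuple[list[str], np.ndarray]:
    """Noise-free class patterns in the preprocessed data space.

    One spectrum per class panel is rendered without noise, jitter or
    amplitude variation and pushed through the same preprocessing chain as
    the data, so a recovered component is compared against the pattern as it
    actually appears to the factorization (baseline correction reshapes the
    saturated ethanol band, cropping removes the RIP).  The two mild
    sub-varieties are merged.
    """
    clean_config = dataclasses.replace(
        gen_config, noise_sd=0.0, drift_jitter_sd=0.0, amplitude_cv=0.0
    )
    rng = np.random.default_rng(0)
    clean = [
        sim.render_spectrum(panel, clean_config, rng, sample_id=label)
        for label, panel in truth.panels.items()
    ]
    _, unfolded = pre.preprocess_pipeline(clean, pre_config)
    ref = {
        label: unfolded.values[i] for i, label in enumerate(truth.panels)
    }
    merged = {
        "yogurt": ref["yogurt"],
        "commercial_kefir": ref["commercial_kefir"],
        "mild": 0.5 * (ref["mild_LS"] + ref["mild_FN"]),
        "tangy": ref["tangy"],
    }
    names = sorted(merged)
    patterns = np.stack([merged[n] for n in names])
    return names, patterns


def fold_change_summary(
    class_volumes: "dict[str, dict]",
) -> dict[str, float]:
    """The study's headline compound ratios from per-class volume rows.

    Expects rows keyed by the merged class labels; returns acetoin and
    diacetyl ratios between commercial kefir and yogurt and the ester /
    aldehyde / alcohol ratios between tangy and mild kefir.
    """

    def ratio(compound, a, b):
        fc = qnt.fold_change(
            class_volumes[a], class_volumes[b], compound
        )
        return fc if isinstance(fc, float) else float("nan")

    alcohol = np.mean(
        [
            ratio(name, "tangy", "mild")
            for name in ("2-methyl-1-propanol", "methyl-1-butanol")
        ]
    )
    return {
        "acetoin_commercial_vs_yogurt": ratio(
            "acetoin", "commercial_kefir", "yogurt"
        ),
        "diacetyl_yogurt_vs_commercial": ratio(
            "diacetyl", "yogurt", "commercial_kefir"
        ),
        "ethyl_acetate_tangy_vs_mild": ratio(
            "ethyl acetate", "tangy", "mild"
        ),
        "methylbutanal_tangy_vs_mild": ratio(
            "3-methylbutanal", "tangy", "mild"
        ),
        "alcohols_tangy_vs_mild": float(alcohol),
    }


def run_pipeline(
    config: RunConfig, outdir: str | Path | None = None
) -> tuple[dict, dict]:
    """Execute all five stages; returns (manifest, artifacts).

    The manifest is JSON-serializable; artifacts holds the in-memory objects
    (cube, unfolded matrix, models, ground truth, volume tables) for further
    analysis.  If ``outdir`` is given, the cube, models, volume tables,
    dendrograms and manifest are written there.
    """
    manifest: dict = {"config": config.to_dict(), "stages": []}
    artifacts: dict = {}

    def stage(name: str, **info) -> None:
        manifest["stages"].append(
            {"name": name, "seconds": round(time.perf_counter() - t0, 3),
             **info}
        )
        logger.info("stage %s done: %s", name, info)

    # 1. simulate ----------------------------------------------------------
    t0 = time.perf_counter()
    spectra, truth = sim.generate_dataset(config.generator_config())
    artifacts["truth"] = truth
    stage(
        "simulate",
        n_raw_spectra=len(spectra),
        grid=list(spectra[0].shape),
    )

    # 2. preprocess --------------------------------------------------------
    t0 = time.perf_counter()
    cube, unfolded = pre.preprocess_pipeline(
        spectra, config.preprocess_config()
    )
    artifacts["cube"] = cube
    artifacts["unfolded"] = unfolded
    stage("preprocess", cube_shape=list(cube.shape))

    labels = [str(lab) for lab in unfolded.class_labels]
    if config.merge_mild_labels:
        labels = sim.merge_mild(labels)

    # 3. decompose (fit on the training samples only) ----------------------
    t0 = time.perf_counter()
    split = cls.stratified_split(
        labels, fraction=config.split_fraction, seed=config.split_seed
    )
    train_X = unfolded.values[split.train_indices]
    test_X = unfolded.values[split.test_indices]
    train_labels = [labels[i] for i in split.train_indices]
    test_labels = [labels[i] for i in split.test_indices]
    pca = dec.pca_fit(train_X, config.pca_components)
    nnmf = dec.nnmf_fit(
        train_X,
        config.nnmf_k,
        seed=config.decompose_seed,
        n_restarts=config.nnmf_restarts,
    )
    artifacts.update(
        pca=pca, nnmf=nnmf, split=split,
        train_labels=train_labels, test_labels=test_labels,
    )
    pattern_names, patterns = _merged_truth_patterns(
        truth, config.generator_config(), config.preprocess_config()
    )
    matched, cosines = dec.match_components(nnmf.H, patterns)
    component_to_class = {
        pattern_names[p]: int(j) for j, p in enumerate(matched)
    }
    artifacts["component_to_class"] = component_to_class
    artifacts["component_cosines"] = {
        pattern_names[p]: float(c) for p, c in zip(matched, cosines)
    }
    manifest["split"] = {
        "train_total": int(split.train_indices.size),
        "test_total": int(split.test_indices.size),
        "per_class_train": split.per_class_train,
    }
    manifest["pca"] = {
        "explained_variance_pct": [
            round(float(v), 3) for v in pca.explained_variance_pct
        ]
    }
    manifest["nnmf"] = {
        "k": nnmf.k,
        "residual": float(nnmf.residual),
        "n_iterations": nnmf.n_iterations,
        "component_truth_cosines": artifacts["component_cosines"],
    }
    stage("decompose", pca_components=config.pca_components, nnmf_k=nnmf.k)

    # 4. classify ----------------------------------------------------------
    t0 = time.perf_counter()
    score_sets = {
        "pca": (pca.scores, dec.pca_project(pca, test_X)),
        "nnmf": (nnmf.W, dec.nnmf_project(nnmf, test_X)),
    }
    reports: dict[str, dict] = {}
    for source, (train_scores, test_scores) in score_sets.items():
        for kind in config.classifiers:
            _, cv_fields = cls.cross_validate(
                kind, train_scores, train_labels,
                folds=config.cv_folds, seed=config.split_seed,
            )
            model = cls.train_classifier(kind, train_scores, train_labels)
            test_fields = cls.evaluate_test(model, test_scores, test_labels)
            report = cls.ClassifierReport(
                method=kind,
                feature_source=source,
                n_components=train_scores.shape[1],
                **cv_fields,
                **test_fields,
            )
            reports[f"{source}_{kind}"] = report.to_dict()
    _, cv_fields = cls.cross_validate(
        "plsda", train_X, train_labels,
        folds=config.cv_folds, seed=config.split_seed,
        n_components=config.pls_components,
    )
    pls_model = cls.train_classifier(
        "plsda", train_X, train_labels, n_components=config.pls_components
    )
    test_fields = cls.evaluate_test(pls_model, test_X, test_labels)
    reports["pls_da"] = cls.ClassifierReport(
        method="plsda",
        feature_source="pls",
        n_components=config.pls_components,
        **cv_fields,
        **test_fields,
    ).to_dict()
    manifest["classification"] = reports
    dendrograms = {
        source: cls.hca(train_scores, labels=train_labels)
        for source, (train_scores, _) in score_sets.items()
    }
    artifacts["dendrograms"] = dendrograms
    stage("classify", n_reports=len(reports))

    # 5. quantify ----------------------------------------------------------
    t0 = time.perf_counter()
    library = (
        qnt.CompoundLibrary.from_csv(config.library_csv)
        if config.library_csv
        else qnt.default_library()
    )
    component_spectra = {
        f"component_{cls_name}": dec.backproject_component(
            nnmf, j, unfolded.axis_map
        )
        for cls_name, j in component_to_class.items()
    }
    component_volumes = qnt.volume_table(
        component_spectra, cube.retention_axis, cube.drift_axis, library,
        drop_empty=False,
    )
    mean_spectra = qnt.class_mean_spectra(
        pre.SpectrumCube(
            intensity=cube.intensity,
            retention_axis=cube.retention_axis,
            drift_axis=cube.drift_axis,
            sample_ids=cube.sample_ids,
            class_labels=labels,
        )
    )
    class_volumes = qnt.volume_table(
        mean_spectra, cube.retention_axis, cube.drift_axis, library,
        drop_empty=False,
    )
    fold_changes = fold_change_summary(
        {row: class_volumes.loc[row].to_dict() for row in class_volumes.index}
    )
    sample_volumes = qnt.sample_volume_table(cube, library)
    microbe_table = truth.microbe_table()
    corr, flagged = qnt.correlate_microbes(sample_volumes, microbe_table)
    artifacts.update(
        library=library,
        component_volumes=component_volumes,
        class_volumes=class_volumes,
        sample_volumes=sample_volumes,
        correlations=corr,
        flagged_pairs=flagged,
    )
    acetic = {
        cls_name: float(
            component_volumes.loc[f"component_{cls_name}", "acetic acid"]
        )
        for cls_name in ("commercial_kefir", "yogurt")
    }
    hexanal_row = corr.loc["hexanal"] if "hexanal" in corr.index else None
    isoamyl_row = (
        corr.loc["3-methylbutyl acetate"]
        if "3-methylbutyl acetate" in corr.index
        else None
    )
    manifest["quantification"] = {
        "fold_changes": {k: round(v, 4) for k, v in fold_changes.items()},
        "acetic_acid_component_volume": acetic,
        "flagged_correlations": [
            [compound, microbe, round(r, 4)] for compound, microbe, r in flagged
        ],
        "hexanal_d_anomalous_r": (
            round(float(hexanal_row["D. anomalous"]), 4)
            if hexanal_row is not None
            else None
        ),
        "isoamyl_acetate_top_correlate": (
            str(isoamyl_row.astype(float).idxmax())
            if isoamyl_row is not None
            else None
        ),
    }
    stage("quantify", n_compounds=int(sample_volumes.shape[1]))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fio.save_cube(cube, outdir / "cube.h5")
        fio.save_models(
            outdir / "models.h5",
            unfolded.axis_map,
            cube.retention_axis,
            cube.drift_axis,
            unfolded.sample_ids,
            labels,
            pca=pca,
            nnmf=nnmf,
        )
        component_volumes.to_csv(outdir / "component_volumes.csv")
        sample_volumes.to_csv(outdir / "sample_volumes.csv")
        corr.to_csv(outdir / "microbe_correlations.csv")
        for source, dg in dendrograms.items():
            (outdir / f"hca_{source}.nwk").write_text(dg.to_newick())
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=float)
        )
    return manifest, artifacts
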