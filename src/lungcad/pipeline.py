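"""Pipeline orchestration: configuration, labels, feature assembly, experiments.

The default configuration carries the operating points at which the descriptor
suite performs best: HOG with 5x5x5 blocks / 3x3x3 cells / dodecahedron full
binning; ALBP with 5 views / 3 levels / average-N resampling; PSCSS with a
15-pixel gap and 5 views; MGRF with 1000 histogram bins; SPHARM with 70
harmonic orders.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import classify
from .classify import (
    EvalReport,
    FusionClassifier,
    StackedAutoencoderClassifier,
    build_stacked_sae,
    evaluate,
    split_train_test,
    train_descriptor_classifier,
)
from .descriptors import (
    ALBPExtractor,
    GeometricExtractor,
    HOG3DExtractor,
    MGRFEnergyExtractor,
    PSCSSExtractor,
    SphericalHarmonicsExtractor,
)

logger = logging.getLogger("lungcad")

__all__ = [
    "PipelineConfig",
    "label_from_grades",
    "build_extractors",
    "extract_all_features",
    "extract_feature_tables",
    "run_experiment",
    "ExperimentResult",
]

DESCRIPTOR_ORDER = ("albp", "hog3d", "mgrf", "pscss", "spharm", "geometric")


@dataclass
class PipelineConfig:
    """Full pipeline configuration; defaults are the recommended optima."""

    voi_side_mm: float = 40.0
    isotropic_mm: float = 1.0
    seed: int = 0
    albp: dict = field(default_factory=lambda: {
        "n_views": 5, "r_max": 3, "scheme": "average_n"})
    hog3d: dict = field(default_factory=lambda: {
        "n_blocks": 5, "cell_size": 3, "solid": "dodecahedron", "binning_style": "full"})
    mgrf: dict = field(default_factory=lambda: {
        "q_levels": 32, "n_bins": 1000, "include_star": True})
    pscss: dict = field(default_factory=lambda: {
        "n_views": 5, "gap": 15, "sigmas": [8.0, 12.0, 16.0, 24.0, 32.0],
        "in_plane_spacing": 0.25, "presmooth_px": 0.0})
    spharm: dict = field(default_factory=lambda: {
        "max_order": 70, "step_size": 1, "max_vertices": 1200,
        "ar_step": 0.1, "ar_iters": 100, "ar_repulsion": 0.01, "smooth_vox": 0.0})
    geometric: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=lambda: {
        "pretrain_epochs": 200, "finetune_epochs": 200, "learning_rate": 0.005,
        "rule": "two_thirds", "fusion_hidden_width": 4,
        "fusion_learning_rate": 0.01, "threshold": 0.5})
    train_frac: float = 0.70
    enabled: tuple = DESCRIPTOR_ORDER

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["enabled"] = list(self.enabled)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        base = cls()
        kw = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                val = d[f.name]
                if isinstance(getattr(base, f.name), dict):
                    merged = dict(getattr(base, f.name))
                    merged.update(val)
                    val = merged
                kw[f.name] = tuple(val) if f.name == "enabled" else val
        return cls(**kw)

    def save(self, path: str) -> None:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def load(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            if str(path).endswith((".yml", ".yaml")):
                import yaml

                return cls.from_dict(yaml.safe_load(fh))
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self) -> dict:
        from . import __version__

        return {"config_hash": self.config_hash(), "seed": self.seed,
                "package_version": __version__}


def label_from_grades(grades) -> str:
    """Consensus malignancy label from radiologist grades (integers 1-5).

    Mean grade >= 3.5 -> "malignant"; <= 1.5 -> "benign"; otherwise
    "excluded" (insufficient reader agreement).
    """
    grades = list(grades)
    if not grades:
        raise ValueError("empty grade list")
    if any(not 1 <= g <= 5 for g in grades):
        raise ValueError("grades must lie in 1..5")
    mean = float(np.mean(grades))
    if mean >= 3.5:
        return "malignant"
    if mean <= 1.5:
        return "benign"
    return "excluded"


def build_extractors(config: PipelineConfig) -> dict:
    """Instantiate the enabled descriptor transformers from the config."""
    factory = {
        "albp": lambda: ALBPExtractor(**config.albp),
        "hog3d": lambda: HOG3DExtractor(**config.hog3d),
        "mgrf": lambda: MGRFEnergyExtractor(**{k: v for k, v in config.mgrf.items()}),
        "pscss": lambda: PSCSSExtractor(**{**config.pscss,
                                           "sigmas": tuple(config.pscss["sigmas"])}),
        "spharm": lambda: SphericalHarmonicsExtractor(**config.spharm),
        "geometric": lambda: GeometricExtractor(**config.geometric),
    }
    return {tag: factory[tag]() for tag in DESCRIPTOR_ORDER if tag in config.enabled}


def extract_all_features(record, config: PipelineConfig, mgrf_model=None) -> dict:
    """All enabled descriptor vectors for one record.

    Returns ``{tag: DescriptorVector | None}``; a failed stage maps to None
    (logged) and the remaining stages still run.  ``mgrf_model`` must be a
    trained :class:`~lungcad.descriptors.mgrf.MGRFModel` for the MGRF stage.
    """
    extractors = build_extractors(config)
    if "mgrf" in extractors:
        if mgrf_model is None:
            extractors.pop("mgrf")
            logger.warning("no trained MGRF model supplied; skipping mgrf stage")
        else:
            extractors["mgrf"].model_ = mgrf_model
    out = {}
    for tag, ext in extractors.items():
        t0 = time.perf_counter()
        try:
            out[tag] = ext.describe(record)
        except Exception as exc:  # pragma: no cover - defensive path
            logger.warning("descriptor %s failed on %s: %s", tag, getattr(record, "record_id", "?"), exc)
            out[tag] = None
        logger.debug("%s: %.3f s", tag, time.perf_counter() - t0)
    return out


def _safe_transform(extractor, records) -> np.ndarray:
    """Row-wise transform; a failing record yields a zero row (logged)."""
    rows, width = [], None
    for rec in records:
        try:
            v = extractor.describe(rec).values
            width = v.size
            rows.append(v)
        except Exception as exc:  # pragma: no cover - defensive path
            logger.warning("descriptor %s failed on %s: %s", extractor.tag,
                           getattr(rec, "record_id", "?"), exc)
            rows.append(None)
    width = width or 1
    return np.vstack([r if r is not None else np.zeros(width) for r in rows])


def extract_feature_tables(records, config: PipelineConfig, extractors: dict) -> dict:
    """{tag: (n_records, d_tag) matrix} using already-fitted extractors."""
    return {tag: _safe_transform(ext, records) for tag, ext in extractors.items()}


@dataclass
class ExperimentResult:
    """Per-descriptor and fused test-set reports plus models and provenance."""

    reports: dict                  # tag -> EvalReport, plus "fused"
    train_probabilities: dict
    test_probabilities: dict
    stage1_models: dict
    fusion_model: FusionClassifier
    test_labels: list
    provenance: dict
    extractors: dict = field(default_factory=dict)

    def summary_rows(self) -> list:
        rows = []
        for tag in list(DESCRIPTOR_ORDER) + ["fused"]:
            if tag in self.reports:
                r = self.reports[tag]
                rows.append({"descriptor": tag, **r.as_dict()})
        return rows


def run_experiment(cohort: list, config: PipelineConfig | None = None) -> ExperimentResult:
    """Split -> stage-1 training per descriptor -> fusion -> evaluation.

    The MGRF model is trained only on the benign nodules of the training
    split.  Stage-1 classifier seeds are derived from ``config.seed``.
    """
    config = config or PipelineConfig()
    labels = [r.label for r in cohort]
    if len(set(labels)) < 2:
        raise ValueError("cohort must contain both classes")
    train, test = split_train_test(cohort, train_frac=config.train_frac, seed=config.seed)
    extractors = build_extractors(config)
    if "mgrf" in extractors:
        extractors["mgrf"].fit(train)
    logger.info("extracting features for %d train / %d test records", len(train), len(test))
    X_train = extract_feature_tables(train, config, extractors)
    X_test = extract_feature_tables(test, config, extractors)
    y_train = [r.label for r in train]
    y_test = [r.label for r in test]
    cc = config.classifier
    reports, p_train, p_test, models = {}, {}, {}, {}
    for i, tag in enumerate(t for t in DESCRIPTOR_ORDER if t in extractors):
        cfg = build_stacked_sae(
            X_train[tag].shape[1], seed=config.seed + 1 + i, rule=cc["rule"],
            pretrain_epochs=cc["pretrain_epochs"], finetune_epochs=cc["finetune_epochs"],
            learning_rate=cc["learning_rate"],
        )
        t0 = time.perf_counter()
        model, prob_tr = train_descriptor_classifier(X_train[tag], y_train, cfg)
        logger.info("stage-1 %s trained in %.1f s", tag, time.perf_counter() - t0)
        models[tag] = model
        p_train[tag] = prob_tr
        p_test[tag] = model.malignancy_probability(X_test[tag])
        reports[tag] = evaluate(p_test[tag], y_test, threshold=cc["threshold"])
    tags = [t for t in DESCRIPTOR_ORDER if t in extractors]
    P_tr = np.column_stack([p_train[t] for t in tags])
    P_te = np.column_stack([p_test[t] for t in tags])
    fusion = FusionClassifier(
        hidden_width=cc["fusion_hidden_width"], n_expected_inputs=len(tags),
        learning_rate=cc["fusion_learning_rate"], random_state=config.seed + 100,
        pretrain_epochs=cc["pretrain_epochs"], finetune_epochs=cc["finetune_epochs"],
    ).fit(P_tr, y_train)
    fused_tr = fusion.malignancy_probability(P_tr)
    fused_te = fusion.malignancy_probability(P_te)
    reports["fused"] = evaluate(fused_te, y_test, threshold=cc["threshold"])
    p_train["fused"], p_test["fused"] = fused_tr, fused_te
    return ExperimentResult(
        reports=reports, train_probabilities=p_train, test_probabilities=p_test,
        stage1_models=models, fusion_model=fusion, test_labels=y_test,
        provenance=config.provenance(), extractors=extractors,
    )
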