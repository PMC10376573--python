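"""End-to-end pipeline: scale adaptation -> pyramid features -> classifier.

:class:`OCTPyramidPipeline` chains the unsupervised scale-adaptation
autoencoder, the frozen multi-scale dense backbones and a cascade (or
all-at-once) classifier head into a single scikit-learn classifier over raw
images, so the whole system can sit inside ``cross_validate`` with every
fitted component trained on the training fold only.

:func:`run_synthetic_benchmark` is the package's desk-scale study: a
balanced synthetic four-class OCT set, stratified k-fold cross-validation,
and accuracy for the cascade, the all-at-once head, the fused feature and
each single scale. It is the experiment the test suite uses to show the
pipeline learns (accuracy above the 0.25 chance level) and that fusion does
not hurt relative to the best single scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .backbone import BackboneConfig
from .cascade import CascadeClassifier, ClassifierSpec, train_all_at_once
from .evaluation import make_folds
from .pyramid import PyramidFeatureExtractor
from .scale_adaptation import AEConfig, ScaleAdaptationAE
from .synthetic import SyntheticSpec, generate_dataset

__all__ = ["OCTPyramidPipeline", "run_synthetic_benchmark", "TINY_BACKBONE"]

# Desk-scale backbone: same arithmetic as the reference topology, tiny widths.
TINY_BACKBONE = BackboneConfig(growth_rate=8, stem_channels=16,
                               block_layers=(2, 2), compression=0.5)


class OCTPyramidPipeline(BaseEstimator, ClassifierMixin):
    """Image-in, diagnosis-out classifier.

    Parameters mirror the stage configs; ``ae_train_max_images`` caps how
    many training images the autoencoder sees (it learns low-level image
    statistics, for which a subsample suffices and keeps fitting cheap).
    """

    def __init__(self, ae_config: AEConfig | None = None,
                 backbone_config: BackboneConfig | None = None,
                 classifier_kind: str = "MLP", mode: str = "cascade",
                 share_weights: bool = False,
                 ae_train_max_images: int | None = None,
                 random_state: int = 0):
        self.ae_config = ae_config
        self.backbone_config = backbone_config
        self.classifier_kind = classifier_kind
        self.mode = mode
        self.share_weights = share_weights
        self.ae_train_max_images = ae_train_max_images
        self.random_state = random_state

    def _build_transformers(self):
        cfg = self.ae_config or AEConfig(seed=self.random_state)
        self.ae_ = ScaleAdaptationAE(cfg)
        self.pyramid_ = PyramidFeatureExtractor(
            self.backbone_config or TINY_BACKBONE,
            n_scales=len(cfg.target_scales),
            share_weights=self.share_weights,
            random_state=self.random_state).fit()

    def transform(self, images) -> np.ndarray:
        """Images -> fused feature matrix (requires a fitted/built AE)."""
        return self.pyramid_.transform(self.ae_.transform(images))

    def fit(self, images, y) -> "OCTPyramidPipeline":
        if self.mode not in ("cascade", "four"):
            raise ValueError("mode must be 'cascade' or 'four'")
        y = np.asarray(y)
        self._build_transformers()
        train_imgs = list(images)
        cap = self.ae_train_max_images
        if cap is not None and len(train_imgs) > cap:
            rng = np.random.default_rng(self.random_state)
            idx = rng.choice(len(train_imgs), size=cap, replace=False)
            ae_imgs = [train_imgs[i] for i in idx]
        else:
            ae_imgs = train_imgs
        self.ae_.fit(ae_imgs)
        X = self.transform(train_imgs)
        if self.mode == "cascade":
            self.head_ = CascadeClassifier(self.classifier_kind,
                                           random_state=self.random_state)
            self.head_.fit(X, y)
            self.classes_ = self.head_.classes_
        else:
            self.head_ = train_all_at_once(
                X, y, ClassifierSpec(self.classifier_kind, seed=self.random_state))
            self.classes_ = self.head_.classes_
        return self

    def predict(self, images) -> np.ndarray:
        return self.head_.predict(self.transform(images))

    def predict_proba(self, images) -> np.ndarray:
        X = self.transform(images)
        if hasattr(self.head_, "predict_proba"):
            return self.head_.predict_proba(X)
        return self.head_.scores(X)


def run_synthetic_benchmark(n_per_class: int = 50,
                            image_size: tuple[int, int] = (96, 128),
                            k: int = 5, seed: int = 0,
                            classifier_kind: str = "LR",
                            backbone_config: BackboneConfig | None = None,
                            ae_epochs: int = 1, ae_base_channels: int = 4,
                            ae_train_subset: int = 40) -> dict:
    """Cross-validated synthetic study of the full pipeline.

    Per fold: the autoencoder is fitted on (a subsample of) the training
    images, the frozen pyramid features of every image are extracted through
    it, and four classifiers are trained on the training fold — the
    two-stage cascade and the all-at-once head on the fused feature, plus
    one head per single scale for the fusion comparison. Returns pooled
    held-out accuracies and per-fold breakdowns.
    """
    spec = SyntheticSpec(n_per_class=n_per_class, image_height=image_size[0],
                         image_width=image_size[1], seed=seed)
    data = generate_dataset(spec)
    y = np.asarray(data.labels)
    plan = make_folds(y, k=k, seed=seed, stratified=True)

    ae_cfg = AEConfig(epochs=ae_epochs, base_channels=ae_base_channels,
                      seed=seed)
    pyramid = PyramidFeatureExtractor(backbone_config or TINY_BACKBONE,
                                      n_scales=len(ae_cfg.target_scales),
                                      random_state=seed).fit()
    n_scales = len(ae_cfg.target_scales)
    widths = [b.terminal_channels_ for b in pyramid.backbones_]
    edges = np.concatenate([[0], np.cumsum(widths)])

    correct = {"cascade": 0, "four": 0, "fused": 0}
    correct.update({f"scale{i}": 0 for i in range(n_scales)})
    per_fold: dict[str, list[float]] = {k2: [] for k2 in correct}
    n_test_total = 0
    rng = np.random.default_rng(seed)
    cls_spec = ClassifierSpec(classifier_kind, seed=seed)

    for f in range(1, plan.k + 1):
        tr, te = plan.train_indices(f), plan.test_indices(f)
        ae_pool = [data.images[i] for i in tr]
        if len(ae_pool) > ae_train_subset:
            pick = rng.choice(len(ae_pool), size=ae_train_subset, replace=False)
            ae_pool = [ae_pool[i] for i in pick]
        ae = ScaleAdaptationAE(ae_cfg).fit(ae_pool)
        fused = pyramid.transform(ae.transform(data.images))

        models = {}
        models["cascade"] = CascadeClassifier(classifier_kind, random_state=seed
                                              ).fit(fused[tr], y[tr])
        models["four"] = train_all_at_once(fused[tr], y[tr], cls_spec)
        models["fused"] = train_all_at_once(fused[tr], y[tr], cls_spec)
        for i in range(n_scales):
            cols = slice(int(edges[i]), int(edges[i + 1]))
            models[f"scale{i}"] = (train_all_at_once(fused[tr, cols], y[tr],
                                                     cls_spec), cols)
        for name, model in models.items():
            if isinstance(model, tuple):
                model, cols = model
                pred = model.predict(fused[te, cols])
            else:
                pred = model.predict(fused[te])
            n_ok = int((np.asarray(pred) == y[te]).sum())
            correct[name] += n_ok
            per_fold[name].append(n_ok / len(te))
        n_test_total += len(te)

    out = {"n": int(len(y)), "n_test": int(n_test_total), "k": k, "seed": seed,
           "classifier": cls_spec.kind,
           "accuracy": {name: correct[name] / n_test_total for name in correct},
           "correct": dict(correct), "per_fold": per_fold,
           "scale_tags": [f"{h}x{w}" for h, w, _ in ae_cfg.target_scales]}
    single = [out["accuracy"][f"scale{i}"] for i in range(n_scales)]
    out["best_single_scale_accuracy"] = max(single)
    return out
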