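"""End-to-end vitals estimation: wide-band analysis -> respiration-class
model -> band-specific re-analysis -> regression model.

The two-stage design follows from the spread of ovine respiration rates
(12-192 BrPM) being far wider than heart rates (63-132 BPM): a single
wide band cannot resolve the respiratory peak reliably (slow breathing
falls below the 0.33 Hz edge, and the cardiac component leaking into
the a* channel can dominate it), so a pattern-recognition network
(Model 1) first assigns each recording to a low/medium/high respiration
class from its wide-band features, the a* signal is re-analyzed in the
class-specific band, and a regression network (Model 2) maps the 16
cardiac + respiratory features to calibrated HR/RR values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ann, features as ft, spectral, synthetic
from .ann import BRNetClassifier, BRNetRegressor, FFNet
from .evaluation import classification_report, regress_through_origin
from .features import MinMaxNormalizer, SignalFeatures
from .signals import ChannelSignal, extract_series
from .spectral import RR_BAND_FOR_CLASS, SpectralEstimate, analyze_band
from .video import FrameStack, TrackedROI, crop_stack

__all__ = [
    "BandClass",
    "VitalsEstimate",
    "VitalsModel",
    "signal_features",
    "classify_band",
    "reanalyze",
    "estimate_vitals",
    "train_models",
]

BAND_LABELS = ("low", "medium", "high")


@dataclass
class BandClass:
    """Respiration-class decision with its softmax scores."""

    label: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float).ravel()
        if BAND_LABELS[int(np.argmax(self.scores))] != self.label:
            raise ValueError("label must be the argmax of the scores")


@dataclass
class VitalsEstimate:
    """Calibrated and raw spectral vitals for one recording."""

    hr_bpm: float
    rr_brpm: float
    band: BandClass
    raw_hr_bpm: float
    raw_rr_bpm: float       # band-specific re-analysis peak x 60
    raw_rr_wide_bpm: float  # single wide-band peak x 60
    edge_peaks: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def signal_features(sig: ChannelSignal, band) -> tuple[SignalFeatures, SpectralEstimate]:
    """Band-filter a series, estimate its dominant frequency and build
    the 8-parameter feature vector (the RVA/RVAm analysis step)."""
    filtered, est = analyze_band(sig, band)
    return ft.compute_features(sig, filtered, est), est


def true_band(rr_hz: float) -> str:
    """Class of a respiration frequency; a boundary frequency (1.2 or
    2.2 Hz) belongs to the lower class (half-open convention)."""
    if rr_hz <= synthetic.RR_CLASS_RANGES["low"][1]:
        return "low"
    if rr_hz <= synthetic.RR_CLASS_RANGES["medium"][1]:
        return "medium"
    return "high"


class VitalsModel:
    """Trained Model 1 + Model 2 bundle with their feature normalizers."""

    def __init__(self, classifier: BRNetClassifier, regressor: BRNetRegressor,
                 norm1: MinMaxNormalizer, norm2: MinMaxNormalizer,
                 config: dict = None):
        self.classifier = classifier
        self.regressor = regressor
        self.norm1 = norm1
        self.norm2 = norm2
        self.config = config or {}

    # -- persistence ----------------------------------------------------
    def save(self, path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        clf, reg = self.classifier, self.regressor
        (path / "model1.json").write_text(json.dumps({
            **clf.net_.to_dict(), "classes": clf.classes_.tolist(),
        }))
        (path / "model2.json").write_text(json.dumps({
            **reg.net_.to_dict(),
            "y_mean": reg.y_mean_.tolist(), "y_sd": reg.y_sd_.tolist(),
        }))
        (path / "norm1.json").write_text(json.dumps(self.norm1.to_dict()))
        (path / "norm2.json").write_text(json.dumps(self.norm2.to_dict()))
        (path / "config.json").write_text(json.dumps(self.config))
        return path

    @classmethod
    def load(cls, path) -> "VitalsModel":
        path = Path(path)
        if not (path / "model1.json").exists():
            raise FileNotFoundError(
                f"no trained models in {path}; run training first "
                f"(`sheepvitals pipeline train`)")
        d1 = json.loads((path / "model1.json").read_text())
        clf = BRNetClassifier()
        clf.net_ = FFNet.from_dict(d1)
        clf.classes_ = np.asarray(d1["classes"])
        clf.n_features_in_ = clf.net_.n_in
        d2 = json.loads((path / "model2.json").read_text())
        reg = BRNetRegressor()
        reg.net_ = FFNet.from_dict(d2)
        reg.y_mean_ = np.asarray(d2["y_mean"], float)
        reg.y_sd_ = np.asarray(d2["y_sd"], float)
        reg._single_output = False
        reg.n_features_in_ = reg.net_.n_in
        norm1 = MinMaxNormalizer.from_dict(
            json.loads((path / "norm1.json").read_text()))
        norm2 = MinMaxNormalizer.from_dict(
            json.loads((path / "norm2.json").read_text()))
        config = json.loads((path / "config.json").read_text())
        return cls(clf, reg, norm1, norm2, config)


def classify_band(model: VitalsModel, rr_wide_features: SignalFeatures) -> BandClass:
    """Model-1 respiration-class decision from wide-band features."""
    x = ft.assemble_model1_matrix([rr_wide_features])
    z = model.norm1.transform(x)
    scores = model.classifier.predict_proba(z.to_numpy())[0]
    label = str(model.classifier.classes_[int(np.argmax(scores))])
    # scores ordered as the canonical low/medium/high labels
    order = [list(model.classifier.classes_).index(b) for b in BAND_LABELS]
    return BandClass(label=label, scores=scores[order])


def reanalyze(a_signal: ChannelSignal, band: "BandClass | str"):
    """Re-run the respiration analysis in the class-specific band."""
    label = band.label if isinstance(band, BandClass) else str(band)
    if label not in RR_BAND_FOR_CLASS:
        raise ValueError(f"unknown respiration class {label!r}")
    return signal_features(a_signal, RR_BAND_FOR_CLASS[label])


def estimate_vitals(g_signal: ChannelSignal, a_signal: ChannelSignal,
                    model: VitalsModel) -> VitalsEstimate:
    """Full two-stage estimate for one recording."""
    hr_feats, hr_est = signal_features(g_signal, "HR")
    wide_feats, wide_est = signal_features(a_signal, "RR-wide")
    band = classify_band(model, wide_feats)
    rr_feats, rr_est = reanalyze(a_signal, band)
    x2 = ft.assemble_model2_matrix([hr_feats], [rr_feats])
    z2 = model.norm2.transform(x2)
    hr_bpm, rr_brpm = model.regressor.predict(z2.to_numpy())[0]
    return VitalsEstimate(
        hr_bpm=float(hr_bpm), rr_brpm=float(rr_brpm), band=band,
        raw_hr_bpm=spectral.to_bpm(hr_est),
        raw_rr_bpm=spectral.to_bpm(rr_est),
        raw_rr_wide_bpm=spectral.to_bpm(wide_est),
        edge_peaks={"hr": hr_est.edge_peak, "rr": rr_est.edge_peak,
                    "rr_wide": wide_est.edge_peak},
        provenance={"bands": dict(RR_BAND_FOR_CLASS)},
    )


# ---------------------------------------------------------------------------
# training

def scene_signals(sample: synthetic.CohortSample) -> tuple[ChannelSignal, ChannelSignal]:
    """Render one cohort scene and extract its G and a* series from the
    reference ROI."""
    stack = getattr(sample, "_stack", None)
    if stack is None:
        stack, _ = synthetic.generate_rgb_scene(sample.spec)
    track = TrackedROI.static(sample.spec.roi_true, stack.n_frames,
                              source="label-file")
    crop = crop_stack(stack, track)
    return extract_series(crop, "G"), extract_series(crop, "a")


def _pooled_regression(pred: np.ndarray, truth: np.ndarray) -> dict:
    rep = regress_through_origin(truth.ravel(), pred.ravel())
    return {"n": rep.n, "r": rep.r, "slope": rep.slope,
            "mse": float(np.mean((pred - truth) ** 2)),
            "outlier_count": rep.outlier_count,
            "outlier_pct": rep.outlier_pct}


def train_models(cohort, seed: int = 1, n_hidden: int = 10,
                 max_epochs: int = 300, verbose: bool = False):
    """Train Model 1 and Model 2 on a labelled cohort.

    ``cohort`` is a list of :class:`synthetic.CohortSample` (rendered on
    demand).  Samples are split 70/30; Model 1 learns the respiration
    class from wide-band a* features, every recording is re-analyzed in
    its *predicted* class band, and Model 2 learns reference HR/RR from
    the 16 joint features.  Returns ``(VitalsModel, report)`` where the
    report carries a classification block (accuracy/error/MSE per
    stage), a regression block (R/slope/MSE per stage, predictions
    pooled over HR and RR), and the raw spectral estimates.
    """
    n = len(cohort)
    if n < 10:
        raise ValueError(f"cohort too small to train on: n={n}")
    hr_feats, wide_feats, wide_ests, hr_ests, g_sigs, a_sigs = [], [], [], [], [], []
    for i, sample in enumerate(cohort):
        g, a = scene_signals(sample)
        g_sigs.append(g)
        a_sigs.append(a)
        hf, he = signal_features(g, "HR")
        wf, we = signal_features(a, "RR-wide")
        hr_feats.append(hf)
        wide_feats.append(wf)
        hr_ests.append(he)
        wide_ests.append(we)
        if verbose and (i + 1) % 20 == 0:
            print(f"  analyzed {i + 1}/{n} scenes")

    labels = np.asarray([s.band for s in cohort])
    ds = ann.split(n, seed)
    train_mask = np.zeros(n, bool)
    train_mask[ds.train_idx] = True

    x1 = ft.assemble_model1_matrix(wide_feats)
    norm1 = MinMaxNormalizer().fit(x1.iloc[ds.train_idx])
    z1 = norm1.transform(x1).to_numpy()
    clf = BRNetClassifier(n_hidden=n_hidden, max_epochs=max_epochs,
                          random_state=seed)
    clf.fit(z1[ds.train_idx], labels[ds.train_idx])
    pred_labels = clf.predict(z1)
    scores = clf.predict_proba(z1)

    # re-analysis in the predicted class band
    rr_feats, rr_ests = [], []
    for a, lab in zip(a_sigs, pred_labels):
        f, e = reanalyze(a, str(lab))
        rr_feats.append(f)
        rr_ests.append(e)

    x2 = ft.assemble_model2_matrix(hr_feats, rr_feats)
    norm2 = MinMaxNormalizer().fit(x2.iloc[ds.train_idx])
    z2 = norm2.transform(x2).to_numpy()
    targets = np.column_stack([[s.hr_bpm for s in cohort],
                               [s.rr_brpm for s in cohort]])
    reg = BRNetRegressor(n_hidden=n_hidden, max_epochs=max_epochs,
                         random_state=seed)
    reg.fit(z2[ds.train_idx], targets[ds.train_idx])
    pred = reg.predict(z2)

    raw_hr = np.asarray([spectral.to_bpm(e) for e in hr_ests])
    raw_rr_wide = np.asarray([spectral.to_bpm(e) for e in wide_ests])
    raw_rr_band = np.asarray([spectral.to_bpm(e) for e in rr_ests])

    class_order = clf.classes_
    cls_block = classification_report(
        labels, pred_labels, scores, classes=class_order,
        stage_masks={"training": train_mask, "testing": ~train_mask})
    reg_block = {
        "training": _pooled_regression(pred[train_mask], targets[train_mask]),
        "testing": _pooled_regression(pred[~train_mask], targets[~train_mask]),
        "overall": _pooled_regression(pred, targets),
    }
    raw_block = {
        "single_band": _pooled_regression(
            np.column_stack([raw_hr, raw_rr_wide]), targets),
        "band_specific": _pooled_regression(
            np.column_stack([raw_hr, raw_rr_band]), targets),
    }
    report = {
        "n": n,
        "seed": seed,
        "split": {"n_train": int(train_mask.sum()),
                  "n_test": int((~train_mask).sum()),
                  "observations_train": int(train_mask.sum() * 2),
                  "observations_test": int((~train_mask).sum() * 2)},
        "model1": cls_block,
        "model2": reg_block,
        "raw": raw_block,
        "predictions": pd.DataFrame({
            "scene_id": [s.scene_id for s in cohort],
            "band_true": labels, "band_pred": pred_labels,
            "hr_true": targets[:, 0], "rr_true": targets[:, 1],
            "hr_pred": pred[:, 0], "rr_pred": pred[:, 1],
            "raw_hr_bpm": raw_hr, "raw_rr_wide_bpm": raw_rr_wide,
            "raw_rr_band_bpm": raw_rr_band,
            "is_train": train_mask,
        }),
    }
    model = VitalsModel(clf, reg, norm1, norm2, config={
        "seed": seed, "n_hidden": n_hidden,
        "classes": class_order.tolist(),
        "targets": ["hr_bpm", "rr_brpm"],
    })
    return model, report
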