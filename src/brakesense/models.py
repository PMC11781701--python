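"""Assembly of full decoding models from the pipeline stages.

A :class:`BinaryStack` is one binary subproblem's chain CSP -> features ->
DCC selection -> RLDA, per modality, with optional feature-level or
classifier-level fusion across EEG and EMG. A :class:`MulticlassModel`
wires binary stacks into either the one-vs-rest or decision-tree strategy;
sequential hybrids (SE1/SE2) assign whole stacks to one modality each
(SE1 gives the hard-vs-rest task to EEG, everything else to EMG; SE2
swaps). All stages are fitted on training epochs only and reapplied frozen
to test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import csp, features, fusion, rlda
from .data import CLASSES, Epoch, labels_of, stack_epochs

MODEL_KEYS = (
    "eeg", "emg", "hbci_fl", "hbci_cl1", "hbci_cl2", "hbci_cl3",
    "hbci_se1", "hbci_se2",
)


@dataclass
class ModelSpec:
    """A point in the model grid: modality/fusion x multiclass x features."""

    model: str = "hbci_fl"
    strategy: str = "tree"  # "ovr" | "tree"
    feature_kind: str = "spectral"  # "temporal" | "spectral"
    eeg_band: str = "full"  # key into features.BANDS
    m: int = 6  # EEG virtual channels
    M: int = 4  # EMG virtual channels
    W: int = 30  # selected features per modality
    lambda_grid: tuple = rlda.LAMBDA_GRID
    tree_k1: float = 0.5  # probability-scale cascade thresholds
    tree_k2: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.model not in MODEL_KEYS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.strategy not in ("ovr", "tree"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.feature_kind not in ("temporal", "spectral"):
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.eeg_band not in features.BANDS:
            raise ValueError(f"unknown EEG band {self.eeg_band!r}")

    def key(self) -> str:
        return f"{self.model}-{self.strategy}-{self.feature_kind}"


def _featurize(projected: np.ndarray, modality: str, spec: ModelSpec, fs: float) -> np.ndarray:
    """Batched feature values for (n, m, L) projected epochs."""
    if spec.feature_kind == "temporal":
        if modality == "eeg":
            return features.temporal_features_eeg(projected).values
        return features.temporal_features_emg(projected, fs).values
    band = features.BANDS[spec.eeg_band] if modality == "eeg" else features.EMG_SPECTRAL_BAND
    return features.spectral_features(projected, fs, band).values


def _plan(model: str, task: str) -> tuple:
    """(modalities, fusion_mode) for one binary task of a model key.

    ``task`` is the positive class of the subproblem ("hard", "soft",
    "normal", or "soft_vs_normal" for the tree's second stage).
    """
    if model in ("eeg", "emg"):
        return (model,), None
    if model == "hbci_fl":
        return ("eeg", "emg"), "fl"
    if model in ("hbci_cl1", "hbci_cl2", "hbci_cl3"):
        return ("eeg", "emg"), model.removeprefix("hbci_")
    hard_first, rest = ("eeg", "emg") if model == "hbci_se1" else ("emg", "eeg")
    return ((hard_first,) if task == "hard" else (rest,)), None


@dataclass
class BinaryStack:
    """One fitted binary subproblem: per-modality CSP+DCC+RLDA (+fusion)."""

    spec: ModelSpec
    task: str
    modalities: tuple
    fusion_mode: str | None
    csp_models: dict = field(default_factory=dict)
    selectors: dict = field(default_factory=dict)
    classifiers: dict = field(default_factory=dict)
    feature_fusion: fusion.FeatureFusion | None = None
    fs: float = 200.0

    def _modality_features(self, modality: str, x: np.ndarray) -> np.ndarray:
        proj = csp.project(self.csp_models[modality], x)
        feats = _featurize(proj, modality, self.spec, self.fs)
        return features.select_features(self.selectors[modality], feats)

    def predict_proba(self, eeg: np.ndarray | None, emg: np.ndarray | None) -> np.ndarray:
        """P(target) per epoch from batched (n, C, L) arrays."""
        data = {"eeg": eeg, "emg": emg}
        sel = {mod: self._modality_features(mod, data[mod]) for mod in self.modalities}
        if self.fusion_mode == "fl":
            fused = self.feature_fusion.transform(sel["eeg"], sel["emg"])
            return rlda.predict_proba(self.classifiers["fused"], fused)
        if self.fusion_mode in ("cl1", "cl2", "cl3"):
            p1 = rlda.predict_proba(self.classifiers["eeg"], sel["eeg"])
            p2 = rlda.predict_proba(self.classifiers["emg"], sel["emg"])
            return fusion.fused_score(self.fusion_mode, p1, p2)
        (mod,) = self.modalities
        return rlda.predict_proba(self.classifiers[mod], sel[mod])

    def predict_decision(self, eeg, emg) -> np.ndarray:
        """+1/-1 decisions; classifier-level fusion uses its exact rule."""
        if self.fusion_mode in ("cl1", "cl2", "cl3"):
            data = {"eeg": eeg, "emg": emg}
            sel = {m: self._modality_features(m, data[m]) for m in self.modalities}
            p1 = rlda.predict_proba(self.classifiers["eeg"], sel["eeg"])
            p2 = rlda.predict_proba(self.classifiers["emg"], sel["emg"])
            d1 = np.where(p1 >= 0.5, 1, -1)
            d2 = np.where(p2 >= 0.5, 1, -1)
            if self.fusion_mode == "cl1":
                return np.array([fusion.fuse_and(a, b) for a, b in zip(d1, d2)])
            if self.fusion_mode == "cl2":
                return np.array([fusion.fuse_or(a, b) for a, b in zip(d1, d2)])
            return np.array([fusion.fuse_bayes(a, b).g_out for a, b in zip(p1, p2)])
        return np.where(self.predict_proba(eeg, emg) >= 0.5, 1, -1)


def fit_binary_stack(
    epochs: list,
    y: np.ndarray,
    spec: ModelSpec,
    task: str,
    seed: int | None = None,
) -> BinaryStack:
    """Fit one binary subproblem on labelled epochs (y in {+1, -1})."""
    spec.validate()
    modalities, fusion_mode = _plan(spec.model, task)
    seed = spec.seed if seed is None else seed
    fs = epochs[0].fs
    stack = BinaryStack(spec=spec, task=task, modalities=modalities,
                        fusion_mode=fusion_mode, fs=fs)
    y = np.asarray(y)
    selected = {}
    for mod in modalities:
        data = stack_epochs(epochs, mod)
        n_virtual = spec.m if mod == "eeg" else spec.M
        model = csp.fit_csp(
            [e for e, lab in zip(data, y) if lab == 1],
            [e for e, lab in zip(data, y) if lab == -1],
            m=n_virtual,
        )
        stack.csp_models[mod] = model
        feats = _featurize(csp.project(model, data), mod, spec, fs)
        stack.selectors[mod] = features.dcc_scores(feats, y, W=spec.W)
        selected[mod] = features.select_features(stack.selectors[mod], feats)

    if fusion_mode == "fl":
        stack.feature_fusion = fusion.FeatureFusion.fit(selected["eeg"], selected["emg"])
        fused = stack.feature_fusion.transform(selected["eeg"], selected["emg"])
        stack.classifiers["fused"] = rlda.fit_rlda(fused, y, spec.lambda_grid, seed=seed)
    elif fusion_mode in ("cl1", "cl2", "cl3"):
        for mod in modalities:
            stack.classifiers[mod] = rlda.fit_rlda(selected[mod], y, spec.lambda_grid, seed=seed)
    else:
        (mod,) = modalities
        stack.classifiers[mod] = rlda.fit_rlda(selected[mod], y, spec.lambda_grid, seed=seed)
    return stack


@dataclass
class MulticlassModel:
    """Fitted three-class decoder: binary stacks + a multiclass strategy."""

    spec: ModelSpec
    stacks: dict  # ovr: class -> stack; tree: {"hard", "soft_vs_normal"}

    def predict(self, eeg: np.ndarray, emg: np.ndarray) -> np.ndarray:
        """Class labels for batched (n, C, L) preprocessed windows."""
        from .multiclass import decide_ovr_batch, decide_tree_batch

        if self.spec.strategy == "ovr":
            scores = np.column_stack(
                [self.stacks[cls].predict_proba(eeg, emg) for cls in CLASSES]
            )
            return decide_ovr_batch(scores)
        y1 = self.stacks["hard"].predict_proba(eeg, emg)
        y2 = self.stacks["soft_vs_normal"].predict_proba(eeg, emg)
        return decide_tree_batch(y1, y2, self.spec.tree_k1, self.spec.tree_k2)

    def predict_epochs(self, epochs: list) -> np.ndarray:
        return self.predict(stack_epochs(epochs, "eeg"), stack_epochs(epochs, "emg"))


def fit_multiclass(epochs: list, spec: ModelSpec, seed: int | None = None) -> MulticlassModel:
    """Fit the full three-class decoder on labelled, preprocessed epochs."""
    spec.validate()
    seed = spec.seed if seed is None else seed
    labels = labels_of(epochs)
    stacks = {}
    if spec.strategy == "ovr":
        for i, cls in enumerate(CLASSES):
            y = np.where(labels == cls, 1, -1)
            stacks[cls] = fit_binary_stack(epochs, y, spec, task=cls, seed=seed + i)
    else:
        y_hard = np.where(labels == "hard", 1, -1)
        stacks["hard"] = fit_binary_stack(epochs, y_hard, spec, task="hard", seed=seed)
        sub = [e for e in epochs if e.label in ("soft", "normal")]
        y_soft = np.where(labels_of(sub) == "soft", 1, -1)
        stacks["soft_vs_normal"] = fit_binary_stack(
            sub, y_soft, spec, task="soft_vs_normal", seed=seed + 1
        )
    return MulticlassModel(spec=spec, stacks=stacks)


def sequential_decide(model: MulticlassModel, epoch: Epoch) -> str:
    """Classify one epoch with a fitted sequential (SE1/SE2) model."""
    if model.spec.model not in ("hbci_se1", "hbci_se2"):
        raise ValueError("sequential_decide requires an SE1/SE2 model")
    if not model.stacks:
        raise RuntimeError("constituent binary stacks are missing")
    return str(model.predict(epoch.eeg[None], epoch.emg[None])[0])
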