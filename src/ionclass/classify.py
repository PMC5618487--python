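"""RBF-SVM training, grid search, jackknife evaluation and the hierarchical
ion-channel prediction flow.

The classifier is a support vector machine with RBF kernel
exp(-gamma * ||x - y||^2) and one-vs-one decomposition for multiclass
problems (sklearn's libsvm backend). Hyperparameters (C, gamma) are tuned by
exhaustive grid search over exponent ladders, default C in {2^-5, 2^-3, ...,
2^15} and gamma in {2^5, 2^4, ..., 2^-15} (231 pairs), scored by jackknife
(leave-one-out) overall accuracy.

Two tuning protocols are provided. The default, "pooled", tunes
(C, gamma) once on the full dataset and then jackknifes with them fixed —
mildly optimistic, since every held-out sample participated in tuning. The
"nested" alternative re-tunes inside each leave-one-out fold and is the
unbiased (and far costlier) protocol. The default logs a warning noting the
optimism.

Evaluation metrics follow the usual multi-class definitions: per-class
sensitivity Sn(i) = TP_i / (TP_i + FN_i), overall accuracy OA = sum TP_i / N,
and average accuracy AA = mean_i Sn(i).

The hierarchy mirrors a three-stage decision flow for ion-channel annotation:
stage 1 separates ion channels (IC) from non-ion channels (NIC); stage 2
splits ICs into voltage-gated (VGIC) vs ligand-gated (LGIC); stage 3 assigns
VGICs to one of the four types (K+, Ca2+, Na+, anion). Each stage carries
its own encoder parameters, so a record too short for one stage's lag depth
gets an explicit "unencodable" verdict rather than a silent failure.
"""

from __future__ import annotations

import datetime
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .encoder import EncoderParams, EncodingError, encode
from .selection import LabeledDataset
from .seqio import ProteinRecord

PathLike = Union[str, Path]
logger = logging.getLogger(__name__)

DEFAULT_SEED = 0


@dataclass(frozen=True)
class SvmConfig:
    """One (C, gamma) pair for the RBF SVM."""

    C: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


def default_grid() -> list[tuple[float, float]]:
    """The exhaustive (C, gamma) search grid.

    C exponents -5, -3, ..., 15 (step 2; 11 values); gamma exponents
    5, 4, ..., -15 (step -1; 21 values); 231 pairs in total.
    """
    cs = [2.0**e for e in range(-5, 16, 2)]
    gammas = [2.0**e for e in range(5, -16, -1)]
    return [(c, g) for c in cs for g in gammas]


def reduced_grid() -> list[tuple[float, float]]:
    """A coarse 4 x 4 sub-grid of :func:`default_grid` for cheap searches."""
    cs = [2.0**e for e in (-1, 3, 7, 11)]
    gammas = [2.0**e for e in (3, 0, -3, -7)]
    return [(c, g) for c in cs for g in gammas]


def _make_svc(C: float, gamma: float, seed: int = DEFAULT_SEED) -> SVC:
    return SVC(
        kernel="rbf",
        C=C,
        gamma=gamma,
        decision_function_shape="ovo",
        random_state=seed,
        cache_size=200,
    )


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix (rows = true, columns = predicted) with Sn/OA/AA."""

    classes: tuple[str, ...]
    confusion_matrix: np.ndarray
    sensitivity: dict[str, float]
    overall_accuracy: float
    average_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion_matrix, index=list(self.classes), columns=list(self.classes)
        )

    def to_tsv(self) -> str:
        """Deterministic TSV serialization (confusion matrix then metrics)."""
        lines = ["true\\pred\t" + "\t".join(self.classes)]
        for cls, row in zip(self.classes, self.confusion_matrix):
            lines.append(cls + "\t" + "\t".join(str(int(v)) for v in row))
        for cls in self.classes:
            lines.append(f"Sn({cls})\t{self.sensitivity[cls]:.10f}")
        lines.append(f"OA\t{self.overall_accuracy:.10f}")
        lines.append(f"AA\t{self.average_accuracy:.10f}")
        return "\n".join(lines) + "\n"

    def save(self, path: PathLike) -> None:
        Path(path).write_text(self.to_tsv())


def metrics_from_confusion(
    confusion: np.ndarray, classes: Sequence[str] | None = None
) -> EvalReport:
    """Compute Sn per class, OA and AA from a K x K confusion matrix.

    Rows are true classes, columns predicted. An empty row (class with no
    samples) makes its sensitivity undefined and raises.
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion counts must be non-negative")
    n = cm.sum()
    if n == 0:
        raise ValueError("confusion matrix has no samples")
    row_sums = cm.sum(axis=1)
    if (row_sums == 0).any():
        empty = int(np.flatnonzero(row_sums == 0)[0])
        raise ValueError(f"class row {empty} is empty; sensitivity undefined")
    if classes is None:
        classes = [str(i) for i in range(cm.shape[0])]
    tp = np.diag(cm)
    sn = tp / row_sums
    oa = tp.sum() / n
    aa = sn.mean()
    return EvalReport(
        classes=tuple(str(c) for c in classes),
        confusion_matrix=cm,
        sensitivity={str(c): float(s) for c, s in zip(classes, sn)},
        overall_accuracy=float(oa),
        average_accuracy=float(aa),
    )


TrainPredict = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def svm_train_predict(
    config: SvmConfig, seed: int = DEFAULT_SEED
) -> TrainPredict:
    """A train-and-predict procedure with fixed hyperparameters, for jackknifing."""

    def _fit_predict(
        x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray
    ) -> np.ndarray:
        model = _make_svc(config.C, config.gamma, seed)
        model.fit(x_train, y_train)
        return model.predict(x_test)

    return _fit_predict


def jackknife_evaluate(
    dataset: LabeledDataset, train_predict: TrainPredict
) -> EvalReport:
    """Leave-one-out evaluation: each sample predicted by a model trained on
    the other N-1, confusion matrix assembled from the N held-out predictions.

    Deterministic given a deterministic ``train_predict``. Requires every
    class to have at least 2 samples so no training fold loses a class
    (enforced by :class:`LabeledDataset`).
    """
    x = dataset.matrix.to_numpy(dtype=float)
    y = dataset.labels
    classes = [str(c) for c in dataset.classes]
    class_index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    mask = np.ones(len(y), dtype=bool)
    for i in range(len(y)):
        mask[i] = False
        predicted = train_predict(x[mask], y[mask], x[i : i + 1])[0]
        mask[i] = True
        cm[class_index[str(y[i])], class_index[str(predicted)]] += 1
    return metrics_from_confusion(cm, classes)


def jackknife_oa(
    dataset: LabeledDataset, config: SvmConfig, seed: int = DEFAULT_SEED
) -> float:
    """Jackknife overall accuracy of the RBF SVM at fixed (C, gamma)."""
    return jackknife_evaluate(
        dataset, svm_train_predict(config, seed)
    ).overall_accuracy


Scorer = Callable[[LabeledDataset, SvmConfig], float]


def grid_search(
    dataset: LabeledDataset,
    grid: Sequence[tuple[float, float]] | None = None,
    scorer: Scorer | None = None,
    seed: int = DEFAULT_SEED,
) -> tuple[SvmConfig, float]:
    """Exhaustive search of the (C, gamma) grid, maximizing the scorer.

    The default scorer is jackknife overall accuracy. Ties break by smaller
    C, then smaller gamma, independent of the grid's enumeration order.
    Returns the winning config and its score.
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if scorer is None:
        scorer = lambda ds, cfg: jackknife_oa(ds, cfg, seed)  # noqa: E731
    best: tuple[float, float, float] | None = None  # (-score, C, gamma)
    for c, g in sorted(set(grid)):
        config = SvmConfig(C=c, gamma=g)
        try:
            score = float(scorer(dataset, config))
        except Exception as err:
            raise RuntimeError(
                f"grid search scorer failed at (C={c}, gamma={g}): {err}"
            ) from err
        key = (-score, c, g)
        if best is None or key < best:
            best = key
    assert best is not None
    return SvmConfig(C=best[1], gamma=best[2]), -best[0]


@dataclass
class ModelBundle:
    """A trained classifier with everything needed to reproduce predictions:
    the fitted SVM, the ordered selected-feature names, the encoder
    parameters it expects, the chosen (C, gamma), class labels and training
    metadata."""

    model: SVC
    selected_features: tuple[str, ...]
    encoder_params: EncoderParams
    svm_config: SvmConfig
    classes: tuple[str, ...]
    seed: int = DEFAULT_SEED
    metadata: dict = field(default_factory=dict)

    def predict_matrix(self, matrix: pd.DataFrame) -> np.ndarray:
        """Predict from an already-encoded feature matrix (by feature name)."""
        missing = [f for f in self.selected_features if f not in matrix.columns]
        if missing:
            raise ValueError(f"matrix lacks selected features, e.g. {missing[:3]}")
        return self.model.predict(
            matrix[list(self.selected_features)].to_numpy(dtype=float)
        )

    def predict_record(self, record: ProteinRecord) -> str:
        """Encode one record with this bundle's parameters and classify it."""
        vector = encode(record, self.encoder_params)
        frame = pd.DataFrame([vector.values], columns=list(vector.names))
        return str(self.predict_matrix(frame)[0])

    def save(self, path: PathLike) -> None:
        """Serialize as <path>/model.joblib plus a JSON manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.model, path / "model.joblib")
        self.encoder_params.table.to_tsv(path / "properties.tsv")
        manifest = {
            "format_version": 1,
            "selected_features": list(self.selected_features),
            "lam": self.encoder_params.lam,
            "omega": self.encoder_params.omega,
            "property_set": self.encoder_params.table.name,
            "C": self.svm_config.C,
            "gamma": self.svm_config.gamma,
            "classes": list(self.classes),
            "seed": self.seed,
            "metadata": self.metadata,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    @classmethod
    def load(cls, path: PathLike) -> "ModelBundle":
        from .physchem import load_property_table

        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        table = load_property_table(path / "properties.tsv")
        params = EncoderParams(
            lam=manifest["lam"], omega=manifest["omega"], table=table
        )
        return cls(
            model=joblib.load(path / "model.joblib"),
            selected_features=tuple(manifest["selected_features"]),
            encoder_params=params,
            svm_config=SvmConfig(C=manifest["C"], gamma=manifest["gamma"]),
            classes=tuple(manifest["classes"]),
            seed=manifest["seed"],
            metadata=manifest.get("metadata", {}),
        )


def train(
    dataset: LabeledDataset,
    encoder_params: EncoderParams,
    selected_features: Sequence[str] | None = None,
    svm_config: SvmConfig | None = None,
    seed: int = DEFAULT_SEED,
) -> ModelBundle:
    """Fit an RBF SVM (one-vs-one for K > 2) on the selected feature columns.

    ``selected_features`` defaults to all columns; ``svm_config`` defaults to
    C = 1, gamma = 1. Training is deterministic given identical inputs and
    seed.
    """
    if selected_features is None:
        selected_features = dataset.feature_names
    missing = [f for f in selected_features if f not in dataset.matrix.columns]
    if missing:
        raise ValueError(f"dataset lacks selected features, e.g. {missing[:3]}")
    if svm_config is None:
        svm_config = SvmConfig()
    x = dataset.matrix[list(selected_features)].to_numpy(dtype=float)
    model = _make_svc(svm_config.C, svm_config.gamma, seed)
    model.fit(x, dataset.labels)
    return ModelBundle(
        model=model,
        selected_features=tuple(selected_features),
        encoder_params=encoder_params,
        svm_config=svm_config,
        classes=tuple(str(c) for c in dataset.classes),
        seed=seed,
        metadata={
            "trained": datetime.date.today().isoformat(),
            "n_samples": dataset.n_samples,
        },
    )


def tune_and_evaluate(
    dataset: LabeledDataset,
    grid: Sequence[tuple[float, float]] | None = None,
    mode: str = "pooled",
    seed: int = DEFAULT_SEED,
) -> tuple[SvmConfig, EvalReport]:
    """Grid-search (C, gamma) and jackknife-evaluate the SVM.

    ``mode="pooled"`` tunes once on the full dataset and jackknifes
    with the winner fixed (mildly optimistic; a warning is logged).
    ``mode="nested"`` re-tunes inside every leave-one-out fold — unbiased,
    at roughly N times the cost; the reported config is then the winner of a
    final tune on the full data, used for deployment, while the report
    reflects the nested protocol.
    """
    if mode not in ("pooled", "nested"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "pooled":
        logger.warning(
            "pooled-tuning protocol: hyperparameters tuned on the full dataset "
            "before the jackknife; accuracies are mildly optimistic"
        )
        config, _ = grid_search(dataset, grid=grid, seed=seed)
        report = jackknife_evaluate(dataset, svm_train_predict(config, seed))
        return config, report

    # nested: each fold gets its own inner grid search
    if grid is None:
        grid = default_grid()
    x = dataset.matrix
    y = dataset.labels

    def _nested_fit_predict(x_train, y_train, x_test):
        inner = LabeledDataset(
            pd.DataFrame(x_train, columns=x.columns), y_train
        )
        config, _ = grid_search(inner, grid=grid, seed=seed)
        model = _make_svc(config.C, config.gamma, seed)
        model.fit(x_train, y_train)
        return model.predict(x_test)

    report = jackknife_evaluate(dataset, _nested_fit_predict)
    config, _ = grid_search(dataset, grid=grid, seed=seed)
    return config, report


# ---------------------------------------------------------------------------
# Hierarchical prediction flow
# ---------------------------------------------------------------------------

#: Leaf verdicts of the three-stage flow.
HIERARCHY_VERDICTS = ("NIC", "LGIC", "VGIC-K", "VGIC-Ca", "VGIC-Na", "VGIC-Anion")


@dataclass(frozen=True)
class HierarchyVerdict:
    """Per-record outcome: final verdict plus the per-stage decision path."""

    record_id: str
    verdict: str
    path: tuple[str, ...]
    reason: str | None = None


def _stage_predict(bundle: ModelBundle, record: ProteinRecord) -> str | None:
    """Predict one record at one stage; None means unencodable at this stage."""
    if record.length <= bundle.encoder_params.lam:
        return None
    try:
        return bundle.predict_record(record)
    except EncodingError:
        return None


def predict_hierarchy(
    records: Sequence[ProteinRecord],
    stage1: ModelBundle,
    stage2: ModelBundle,
    stage3: ModelBundle,
) -> list[HierarchyVerdict]:
    """Run the three-stage flow: IC/NIC, then VGIC/LGIC, then the VGIC type.

    Stage 1 must be a binary IC-vs-NIC model, stage 2 VGIC-vs-LGIC, stage 3
    the four VGIC types (classes named K, Ca, Na, Anion). Stages may use
    different encoder parameters; a record too short for a stage's lag depth
    receives an "unencodable" verdict naming the stage. Bundles with
    differing property tables are allowed but warned about.
    """
    for stage_name, bundle in (("stage2", stage2), ("stage3", stage3)):
        if bundle.encoder_params.table.name != stage1.encoder_params.table.name:
            warnings.warn(
                f"{stage_name} uses property set "
                f"{bundle.encoder_params.table.name!r} but stage1 uses "
                f"{stage1.encoder_params.table.name!r}",
                stacklevel=2,
            )
    verdicts: list[HierarchyVerdict] = []
    for record in records:
        path: list[str] = []
        decision = _stage_predict(stage1, record)
        if decision is None:
            verdicts.append(
                HierarchyVerdict(
                    record.id,
                    "unencodable",
                    tuple(path),
                    f"stage1: L <= lambda ({record.length} <= "
                    f"{stage1.encoder_params.lam})",
                )
            )
            continue
        path.append(decision)
        if decision == "NIC":
            verdicts.append(HierarchyVerdict(record.id, "NIC", tuple(path)))
            continue
        decision = _stage_predict(stage2, record)
        if decision is None:
            verdicts.append(
                HierarchyVerdict(
                    record.id,
                    "unencodable",
                    tuple(path),
                    f"stage2: L <= lambda ({record.length} <= "
                    f"{stage2.encoder_params.lam})",
                )
            )
            continue
        path.append(decision)
        if decision == "LGIC":
            verdicts.append(HierarchyVerdict(record.id, "LGIC", tuple(path)))
            continue
        decision = _stage_predict(stage3, record)
        if decision is None:
            verdicts.append(
                HierarchyVerdict(
                    record.id,
                    "unencodable",
                    tuple(path),
                    f"stage3: L <= lambda ({record.length} <= "
                    f"{stage3.encoder_params.lam})",
                )
            )
            continue
        path.append(decision)
        verdicts.append(HierarchyVerdict(record.id, f"VGIC-{decision}", tuple(path)))
    return verdicts


def write_verdicts(verdicts: Sequence[HierarchyVerdict], path: PathLike) -> None:
    """Write per-record verdicts as TSV: id, verdict, decision path, reason."""
    with Path(path).open("w") as handle:
        handle.write("id\tverdict\tpath\treason\n")
        for v in verdicts:
            handle.write(
                f"{v.record_id}\t{v.verdict}\t{'>'.join(v.path)}\t{v.reason or ''}\n"
            )
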