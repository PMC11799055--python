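"""Grade classification of ROI views: training, case-grouped CV, hard voting.

Cases — not ROIs — are the sampling unit, so cross-validation splits by
case: the cohort is divided into four groups (per grade in a 3,2,3,2
pattern for 10 cases/grade), two groups train the network, one validates
(epoch selection at minimum validation loss), one tests, and the roles
rotate so every ROI is tested exactly once.  A case's grade is then the
majority (hard) vote of its ROI predictions.

The default backbone is a compact from-scratch CNN suited to CPU-scale
synthetic experiments.  The ``vgg16_transfer`` backbone names the original
transfer-learning protocol (replace the final fully connected layer with a
3-way output, train only the last two fully connected and last two
convolutional layers, SGD with batch 64, dropout 0.75, learning rate
7.5e-5); it requires pretrained VGG-16 weights and a deep-learning runtime
and raises until both are available.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grading import GRADE_NAMES, GRADE_SEVERITY, CaseRecord
from .nn import SGD, SmallCNN

GRADE_INDEX = {g: i for i, g in enumerate(GRADE_NAMES)}

#: Case-count pattern of the four cross-validation groups, per grade.
FOLD_PATTERN = (3, 2, 3, 2)


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults mirror the clinical transfer-learning protocol (batch 64,
    dropout 0.75, learning rate 7.5e-5, epoch cap 18 with selection at
    minimum validation loss).  :meth:`small` returns the preset used with
    the compact CNN on 32 px synthetic ROI views, where a higher learning
    rate and milder dropout fit the much smaller network.
    """

    backbone: str = "small_cnn"
    n_classes: int = 3
    batch_size: int = 64
    learning_rate: float = 7.5e-5
    momentum: float = 0.9
    dropout: float = 0.75
    max_epochs: int = 18
    patience: int = 3
    input_size_px: tuple[int, int] = (224, 224)
    channels: tuple[int, int] = (8, 16)
    hidden: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in ("small_cnn", "vgg16_transfer"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.n_classes != len(GRADE_NAMES):
            raise ValueError("n_classes must equal the number of grades")

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "TrainConfig":
        kw = dict(
            backbone="small_cnn",
            learning_rate=0.02,
            dropout=0.25,
            input_size_px=(32, 32),
            max_epochs=18,
            patience=5,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class FoldAssignment:
    """Partition of case ids into four cross-validation groups."""

    groups: list

    def __post_init__(self) -> None:
        if len(self.groups) != 4:
            raise ValueError("expected exactly four groups")
        flat = [c for g in self.groups for c in g]
        if len(flat) != len(set(flat)):
            raise ValueError("groups must be pairwise disjoint")

    def all_cases(self) -> set:
        return {c for g in self.groups for c in g}

    def rotations(self):
        """Yield (train_cases, val_cases, test_cases) for the four rotations.

        Rotation 0 is the canonical assignment: train on groups 1-2,
        validate on group 3, test on group 4; subsequent rotations shift
        the roles so each group is the test set exactly once.
        """
        for k in range(4):
            train = set(self.groups[k]) | set(self.groups[(k + 1) % 4])
            val = set(self.groups[(k + 2) % 4])
            test = set(self.groups[(k + 3) % 4])
            yield train, val, test


@dataclass
class VoteResult:
    """Case-level outcome of hard voting over ROI predictions."""

    case_id: str
    roi_predictions: list
    case_grade: str
    margin: int


def make_folds(cases: list[CaseRecord], seed: int) -> FoldAssignment:
    """Assign cases to four groups, per grade in the (3,2,3,2) pattern.

    For other cohort sizes the pattern is scaled proportionally (largest
    remainder), keeping groups grade-balanced.  Requires at least four
    cases of every grade so each group can be populated.
    """
    rng = np.random.default_rng(seed)
    by_grade: dict[str, list[str]] = {}
    for c in cases:
        by_grade.setdefault(c.grade, []).append(c.case_id)
    groups: list[list[str]] = [[], [], [], []]
    for grade in sorted(by_grade, key=lambda g: GRADE_INDEX.get(g, 99)):
        ids = sorted(by_grade[grade])
        if len(ids) < 4:
            raise ValueError(f"grade {grade}: need >= 4 cases, got {len(ids)}")
        rng.shuffle(ids)
        n = len(ids)
        total = sum(FOLD_PATTERN)
        exact = [n * w / total for w in FOLD_PATTERN]
        counts = [int(np.floor(e)) for e in exact]
        # largest-remainder top-up, but never leave a group empty
        order = np.argsort([c - e for c, e in zip(counts, exact)])
        i = 0
        while sum(counts) < n:
            counts[order[i % 4]] += 1
            i += 1
        for gi in range(4):
            if counts[gi] == 0:
                donor = int(np.argmax(counts))
                counts[donor] -= 1
                counts[gi] += 1
        pos = 0
        for gi, k in enumerate(counts):
            groups[gi].extend(ids[pos:pos + k])
            pos += k
    return FoldAssignment(groups=groups)


def _build_model(config: TrainConfig) -> SmallCNN:
    if config.backbone == "vgg16_transfer":
        raise NotImplementedError(
            "vgg16_transfer requires pretrained VGG-16 weights and a deep-"
            "learning runtime; use backbone='small_cnn'"
        )
    if config.input_size_px[0] != config.input_size_px[1]:
        raise ValueError("small_cnn expects square inputs")
    return SmallCNN(
        input_size=config.input_size_px[0],
        n_classes=config.n_classes,
        channels=config.channels,
        hidden=config.hidden,
        dropout=config.dropout,
        seed=config.seed,
    )


def train_classifier(
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: TrainConfig,
) -> tuple[SmallCNN, list[dict]]:
    """Train on (N, 3, H, W) batches; return the minimum-validation-loss model.

    Early stopping: training halts once the validation loss has not
    improved for ``config.patience`` consecutive epochs or at
    ``config.max_epochs``, and the returned model carries the weights of
    the best epoch.  The log records per-epoch train/val loss and val
    accuracy.  Deterministic for a fixed seed (data order and weight
    initialization are seeded; bit-level identity across library versions
    is best-effort).
    """
    if len(train_x) == 0 or len(val_x) == 0:
        raise ValueError("training and validation sets must be nonempty")
    present = set(np.unique(train_y))
    if present != set(range(config.n_classes)):
        missing = sorted(set(range(config.n_classes)) - present)
        raise ValueError(f"training set is missing class indices {missing}")
    if train_x.shape[2:] != tuple(config.input_size_px):
        raise ValueError(
            f"input size {train_x.shape[2:]} != configured {config.input_size_px}"
        )

    model = _build_model(config)
    opt = SGD(model, lr=config.learning_rate, momentum=config.momentum)
    rng = np.random.default_rng(config.seed + 1)
    best = {"loss": np.inf, "params": model.get_params(), "epoch": 0}
    log: list[dict] = []
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_x))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            losses.append(model.loss_and_grads(train_x[idx], train_y[idx]))
            opt.step()
        val_probs = model.predict_proba(val_x)
        val_loss = float(
            -np.log(np.maximum(val_probs[np.arange(len(val_y)), val_y], 1e-12)).mean()
        )
        val_acc = float((val_probs.argmax(axis=1) == val_y).mean())
        log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_loss": val_loss, "val_acc": val_acc}
        )
        if val_loss < best["loss"]:
            best = {"loss": val_loss, "params": model.get_params(), "epoch": epoch}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    model.set_params(best["params"])
    model.best_epoch = best["epoch"]
    return model, log


def classify_rois(model: SmallCNN, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI predicted grade indices and class score vectors."""
    probs = model.predict_proba(x)
    return probs.argmax(axis=1), probs


def hard_vote(
    roi_predictions,
    scores: np.ndarray | None = None,
    case_id: str = "",
) -> VoteResult:
    """Majority vote over a case's ROI grade predictions.

    Ties are broken by the higher mean class score across the case's ROIs,
    then by severity (G2-3 over G1 over G0).  The margin is the winning
    count minus the runner-up count.
    """
    preds = [p if isinstance(p, str) else GRADE_NAMES[int(p)] for p in roi_predictions]
    if not preds:
        raise ValueError("hard_vote needs at least one ROI prediction")
    counts = Counter(preds)
    top = max(counts.values())
    tied = [g for g, c in counts.items() if c == top]
    if len(tied) == 1:
        winner = tied[0]
    elif scores is not None:
        mean_scores = np.asarray(scores, dtype=float).mean(axis=0)
        best = max(mean_scores[GRADE_INDEX[g]] for g in tied)
        close = [g for g in tied if mean_scores[GRADE_INDEX[g]] == best]
        winner = max(close, key=lambda g: GRADE_SEVERITY[g])
    else:
        winner = max(tied, key=lambda g: GRADE_SEVERITY[g])
    runner_up = max(
        (c for g, c in counts.items() if g != winner), default=0
    )
    return VoteResult(
        case_id=case_id,
        roi_predictions=preds,
        case_grade=winner,
        margin=top - runner_up,
    )


def _stack_views(records, view_kind: str) -> np.ndarray:
    return np.stack(
        [r.views[view_kind].rgb.transpose(2, 0, 1) for r in records]
    ).astype(np.float64)


def cross_validate(
    records,
    view_kind: str,
    folds: FoldAssignment,
    config: TrainConfig,
    permute_labels_seed: int | None = None,
) -> dict:
    """Four-rotation case-grouped cross-validation of one view type.

    Every ROI receives exactly one test-time prediction.  Returns per-ROI
    predictions (DataFrame), per-case hard-vote results, and the per-fold
    best-epoch counts.

    ``permute_labels_seed`` runs the standard permutation control: the
    grade-label column of the whole ROI table is shuffled once before
    cross-validation, and accuracy is scored against the permuted labels.
    Under the permutation null the test labels are exchangeable and
    independent of the predictions, so accuracy concentrates binomially
    around 1/3 regardless of how correlated the predictions themselves are.
    (Scoring a permuted-label model against the *original* labels does not
    have that property here: within-grade ROIs are statistically near-
    identical, so a collapsed model moves whole blocks of them together.)
    """
    x_all = _stack_views(records, view_kind)
    y_all = np.array([GRADE_INDEX[r.grade_label] for r in records])
    case_ids = np.array([r.case_id for r in records])
    if set(case_ids) != folds.all_cases():
        raise ValueError("fold assignment does not match the ROI set's cases")

    if permute_labels_seed is not None:
        y_all = y_all.copy()
        np.random.default_rng(permute_labels_seed).shuffle(y_all)
    y_train_src = y_all

    rows = []
    fold_epochs = []
    for fold_no, (train_c, val_c, test_c) in enumerate(folds.rotations()):
        tr = np.isin(case_ids, sorted(train_c))
        va = np.isin(case_ids, sorted(val_c))
        te = np.isin(case_ids, sorted(test_c))
        assert not (set(case_ids[tr]) & set(case_ids[te])), "case leakage"
        fold_cfg = TrainConfig(**{**config.__dict__, "seed": config.seed + fold_no})
        model, _ = train_classifier(
            x_all[tr], y_train_src[tr], x_all[va], y_train_src[va], fold_cfg
        )
        fold_epochs.append(model.best_epoch)
        labels, probs = classify_rois(model, x_all[te])
        for idx, lab, pr in zip(np.flatnonzero(te), labels, probs):
            rows.append(
                {
                    "roi_index": int(idx),
                    "case_id": case_ids[idx],
                    "fold": fold_no,
                    "true_grade": GRADE_NAMES[y_all[idx]],
                    "pred_grade": GRADE_NAMES[int(lab)],
                    **{f"score_{g}": float(pr[GRADE_INDEX[g]]) for g in GRADE_NAMES},
                }
            )
    roi_df = pd.DataFrame(rows).sort_values("roi_index").reset_index(drop=True)
    if len(roi_df) != len(records):
        raise RuntimeError("every ROI must be tested exactly once")

    votes = {}
    score_cols = [f"score_{g}" for g in GRADE_NAMES]
    for cid, grp in roi_df.groupby("case_id"):
        votes[cid] = hard_vote(
            grp["pred_grade"].tolist(), grp[score_cols].to_numpy(), case_id=cid
        )
    return {"roi": roi_df, "votes": votes, "fold_epochs": fold_epochs}
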