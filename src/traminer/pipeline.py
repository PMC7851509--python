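"""End-to-end experiment driver: events → trajectories → images → LOPO evaluation.

Glues the stages together for cohort-scale experiments: builds position
histories from event streams, cleans and segments them, renders the
TRAJ/SPEED image pair per trajectory, and runs leave-one-person-out
training/evaluation of the two-branch MLP with long-term (majority-vote)
diagnosis per person.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import TrainConfig, build_two_input_mlp, softmax, train_model
from .io_events import SensorMap, to_position_history
from .longterm_eval import (
    EvalReport,
    evaluate_cohort,
    evaluate_labels,
    long_term_diagnosis,
    lopo_split,
)
from .preprocess import CleaningConfig, Trajectory, clean_positions, segment_trajectories
from .visual_features import (
    flatten_binarize,
    make_layout_transform,
    render_speed_image,
    render_traj_image,
)

__all__ = ["CohortArrays", "LopoResult", "prepare_cohort_arrays", "run_lopo_experiment"]


@dataclass
class CohortArrays:
    """Vectorized cohort: one TRAJ and one SPEED feature vector per trajectory."""

    X_traj: np.ndarray  # (n, 3*W*H) float32 in {0,1}
    X_speed: np.ndarray
    persons: np.ndarray  # person id per trajectory
    labels: np.ndarray  # person's class per trajectory
    trajectories: list[Trajectory]


@dataclass
class LopoResult:
    """Pooled per-trajectory predictions and per-person long-term diagnoses."""

    trajectory_report: EvalReport
    longterm_report: EvalReport
    diagnoses: dict[str, str]
    trajectory_predictions: pd.DataFrame  # person, truth, prediction
    fold_histories: list[dict]


def prepare_cohort_arrays(
    cohort,
    T_s: float = 120.0,
    cleaning: CleaningConfig = CleaningConfig(),
    margin: float = 0.5,
) -> CohortArrays:
    """Clean, segment, and rasterize every person-day of a cohort."""
    lt = make_layout_transform(cohort.sensor_map, margin=margin)
    xt, xs, persons, labels, trajs = [], [], [], [], []
    for person in cohort.persons:
        events = person.events.copy()
        events["t"] = pd.to_datetime(events["timestamp"], format="ISO8601")
        history = to_position_history(
            events[["t", "s_id", "value"]],
            cohort.sensor_map,
            person_id=person.person_id,
        )
        history = clean_positions(history, cleaning)
        for traj in segment_trajectories(history, T_s):
            xt.append(flatten_binarize(render_traj_image(traj, lt)))
            xs.append(flatten_binarize(render_speed_image(traj, lt)))
            persons.append(person.person_id)
            labels.append(person.label)
            trajs.append(traj)
    return CohortArrays(
        X_traj=np.asarray(xt, dtype=np.float32),
        X_speed=np.asarray(xs, dtype=np.float32),
        persons=np.asarray(persons),
        labels=np.asarray(labels),
        trajectories=trajs,
    )


def run_lopo_experiment(
    arrays: CohortArrays,
    person_class: dict[str, str],
    cfg: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> LopoResult:
    """Leave-one-person-out training and long-term diagnosis.

    Per fold a fresh two-branch MLP is trained on the remaining persons'
    trajectory image pairs (10% of each category held out for early
    stopping) and applied to the held-out person's trajectories; the
    majority class of those predictions is the person's diagnosis.
    """
    from .classifier import ordered_classes

    classes = ordered_classes(list(person_class.values()))
    code = {c: i for i, c in enumerate(classes)}
    onehot = np.zeros((len(arrays.labels), len(classes)), dtype=np.float32)
    onehot[np.arange(len(arrays.labels)), [code[c] for c in arrays.labels]] = 1.0

    records = []
    diagnoses: dict[str, str] = {}
    histories = []
    for k, fold in enumerate(
        lopo_split(arrays.persons, person_class, seed=seed)
    ):
        spec = build_two_input_mlp(input_dim=arrays.X_traj.shape[1])
        fold_cfg = TrainConfig(
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            max_epochs=cfg.max_epochs,
            patience=cfg.patience,
            seed=(seed * 1009 + k) % (2**31),
        )
        net, hist = train_model(
            spec,
            ((arrays.X_traj[fold.train_idx], arrays.X_speed[fold.train_idx]),
             onehot[fold.train_idx]),
            ((arrays.X_traj[fold.val_idx], arrays.X_speed[fold.val_idx]),
             onehot[fold.val_idx]),
            fold_cfg,
        )
        histories.append(hist)
        probs = softmax(
            net.forward_logits(
                (arrays.X_traj[fold.test_idx], arrays.X_speed[fold.test_idx]),
                training=False,
            )
        )
        preds = classes[np.argmax(probs, axis=1)]
        for idx, pred in zip(fold.test_idx, preds):
            records.append(
                {
                    "person": fold.test_person,
                    "truth": person_class[fold.test_person],
                    "prediction": pred,
                }
            )
        diagnoses[fold.test_person] = long_term_diagnosis(preds).label
    df = pd.DataFrame(records)
    trajectory_report = evaluate_labels(df["truth"], df["prediction"], classes)
    longterm_report = evaluate_cohort(diagnoses, person_class, classes)
    return LopoResult(
        trajectory_report=trajectory_report,
        longterm_report=longterm_report,
        diagnoses=diagnoses,
        trajectory_predictions=df,
        fold_histories=histories,
    )
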