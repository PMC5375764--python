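"""Evaluation protocols: metrics, authentication, labeling and sweeps.

Gait *authentication* is a per-subject binary decision (accept/reject)
made by a classifier trained on the subject's enrolled AE-GDIs against
impostor images; gait *labeling* is K-way identification with a single
classifier over all enrolled subjects.  Probe decisions can fuse N
consecutive gait cycles.  ``simulate_cohort`` drives the whole pipeline
(simulate -> resample -> segment -> encode) on the synthetic generator so
experiments mirror the real protocols without any external dataset:
"different day" enrollment/probe pairs are modeled as separate sessions
with fresh random device orientations and noise draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import encoding, segmentation, synthetic
from .cnn import CnnSpec, TrainSpec, aggregate_cycles, build_cnn, predict, train
from .io import resample

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass
class Metrics:
    """Precision, recall and accuracy; ``None`` marks an undefined ratio."""

    precision: float | None
    recall: float | None
    accuracy: float | None


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), accuracy = (TP+TN)/all.

    A zero denominator yields ``None`` (undefined), never 0.
    """
    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return Metrics(
        precision=ratio(counts.tp, counts.tp + counts.fp),
        recall=ratio(counts.tp, counts.tp + counts.fn),
        accuracy=ratio(counts.tp + counts.tn, counts.total),
    )


@dataclass
class CycleImages:
    """AE-GDIs of one subject-session, in gait-cycle order."""

    subject: int
    session: int
    pixels: np.ndarray  # (n_cycles, Nl, Nh, Nw)

    def __len__(self) -> int:
        return self.pixels.shape[0]


@dataclass
class ExperimentConfig:
    """Protocol knobs shared by authentication and labeling runs.

    ``train_fraction`` is the percentage of each subject's gallery used
    for training; ``n_cycles`` is the number of consecutive cycles fused
    per probe decision.  The classifier defaults here are a scaled-down
    stack sized for the synthetic cohort (the full-cohort architecture is
    ``CnnSpec.for_task``'s default).
    """

    task: str = "labeling"
    train_fraction: float = 100.0
    n_cycles: int = 1
    folds: int = 1
    seed: int = 0
    feature_maps: tuple = (8, 16, 16)
    fc1_width: int = 96
    epochs: int = 20
    batch_size: int = 100
    learning_rate: float = 0.001
    aggregation: str = "mean"

    def cnn_spec(self, output_classes: int, input_channels: int) -> CnnSpec:
        return CnnSpec.for_task(
            output_classes=output_classes,
            input_channels=input_channels,
            feature_maps=self.feature_maps,
            fc1_width=self.fc1_width,
        )

    def train_spec(self, seed: int) -> TrainSpec:
        return TrainSpec(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# synthetic cohort pipeline
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_subjects: int,
    n_sessions: int,
    cycles_per_session: int,
    seed: int,
    rate_mean: float = 28.57,
    rate_sd: float = 4.17,
    resample_rate: float = 50.0,
    nw: int = encoding.DEFAULT_NW,
    nh: int = encoding.DEFAULT_NH,
    channels: str = "aq",
) -> list[CycleImages]:
    """Run the full pipeline on a synthetic cohort.

    Every session gets a fresh random device orientation.  Each recording
    is resampled to ``resample_rate``, segmented into gait cycles on the
    magnitude series, and encoded into AE-GDIs aligned to the detected
    starts.
    """
    out = []
    for sid in range(n_subjects):
        subject = synthetic.make_subject(sid, seed)
        duration = cycles_per_session * subject.cadence_period + 2.0
        for sess in range(n_sessions):
            session = synthetic.random_session(
                seed=int(np.random.SeedSequence([seed, sid, sess]).generate_state(1)[0] % (2**31)),
                duration=duration,
                target_rate_mean=rate_mean,
                target_rate_sd=rate_sd,
            )
            recording, _ = synthetic.simulate_recording(subject, session)
            series = resample(recording, resample_rate)
            config = segmentation.SegmentationConfig(rate=resample_rate)
            result = segmentation.segment_gait(series.aM, config)
            gyro = series.q if "q" in channels else None
            pixels, _ = encoding.encode_cycles(series.a, gyro, result.starts, nw, nh)
            if pixels.shape[0] == 0:
                logger.warning("subject %d session %d produced no AE-GDIs", sid, sess)
                continue
            out.append(CycleImages(subject=sid, session=sess, pixels=pixels))
    return out


def _group_consecutive(pixels: np.ndarray, n: int) -> list[np.ndarray]:
    """Split a cycle sequence into consecutive non-overlapping N-groups."""
    return [pixels[i : i + n] for i in range(0, len(pixels) - n + 1, n)]


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

@dataclass
class LabelingResult:
    accuracy: float
    per_subject: dict
    n_probes: int
    predictions: list = field(default_factory=list)
    classifier: object = None
    classes: list = field(default_factory=list)


def run_labeling(
    gallery: list[CycleImages],
    probe: list[CycleImages],
    config: ExperimentConfig | None = None,
) -> LabelingResult:
    """K-way identification with a single classifier.

    One CNN is trained on ``train_fraction`` percent of every gallery
    sequence; each probe sequence is labeled by aggregating the predicted
    probabilities of all its AE-GDIs.  Probe subjects absent from the
    gallery are excluded with a warning.
    """
    config = config or ExperimentConfig(task="labeling")
    classes = sorted({g.subject for g in gallery})
    if len(classes) < 2:
        raise ValueError("labeling needs at least 2 gallery subjects")
    index = {s: i for i, s in enumerate(classes)}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 411]))

    xs, ys = [], []
    for g in gallery:
        n_train = max(1, int(round(config.train_fraction / 100.0 * len(g))))
        pick = rng.permutation(len(g))[:n_train]
        xs.append(g.pixels[pick])
        ys.append(np.full(n_train, index[g.subject]))
    x = np.concatenate(xs)
    y = np.concatenate(ys)

    spec = config.cnn_spec(len(classes), x.shape[1])
    model = build_cnn(spec, seed=config.seed)
    clf = train(model, x, y, config.train_spec(config.seed))

    per_subject: dict[int, list[bool]] = {}
    predictions = []
    for p in probe:
        if p.subject not in index:
            logger.warning("probe subject %d absent from gallery; skipped", p.subject)
            continue
        probs = predict(model, p.pixels, batch_size=config.batch_size)
        label = classes[aggregate_cycles(probs, config.aggregation)]
        predictions.append((p.subject, p.session, label))
        per_subject.setdefault(p.subject, []).append(label == p.subject)
    if not predictions:
        raise ValueError("no usable probe sequences")
    correct = [ok for oks in per_subject.values() for ok in oks]
    return LabelingResult(
        accuracy=float(np.mean(correct)),
        per_subject={s: float(np.mean(v)) for s, v in per_subject.items()},
        n_probes=len(predictions),
        predictions=predictions,
        classifier=clf,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# authentication
# ---------------------------------------------------------------------------

@dataclass
class AuthResult:
    mean: Metrics
    per_subject: dict
    counts: ConfusionCounts


def run_authentication(
    gallery: list[CycleImages],
    probe: list[CycleImages],
    config: ExperimentConfig | None = None,
) -> AuthResult:
    """Per-subject binary accept/reject with N-cycle fusion.

    For every enrolled subject a 2-class CNN is trained on
    ``train_fraction`` percent of their gallery images (class 1) against
    an equal number of impostor images drawn uniformly from the other
    subjects (class 0).  Probes are consecutive N-cycle groups: the
    subject's own groups should be accepted, impostor groups (balanced
    1:1) rejected.  Metrics are averaged over subjects and folds; a
    subject with fewer than N probe cycles is excluded with a warning.
    """
    config = config or ExperimentConfig(task="authentication")
    subjects = sorted({g.subject for g in gallery})
    if len(subjects) < 2:
        raise ValueError("authentication needs at least 2 subjects for impostors")
    gal_by_subject = {s: np.concatenate([g.pixels for g in gallery if g.subject == s])
                      for s in subjects}
    probe_by_subject = {s: [p for p in probe if p.subject == s] for s in subjects}

    per_subject: dict[tuple[int, int], Metrics] = {}
    total = ConfusionCounts()
    for fold in range(config.folds):
        fold_seed = int(np.random.SeedSequence([config.seed, fold, 77]).generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(fold_seed)
        for s in subjects:
            pos = gal_by_subject[s]
            n_train = max(1, int(round(config.train_fraction / 100.0 * len(pos))))
            pos_train = pos[rng.permutation(len(pos))[:n_train]]
            neg_pool = np.concatenate([gal_by_subject[o] for o in subjects if o != s])
            neg_train = neg_pool[rng.choice(len(neg_pool), size=n_train, replace=False)
                                 if len(neg_pool) >= n_train
                                 else rng.choice(len(neg_pool), size=n_train)]
            x = np.concatenate([pos_train, neg_train])
            y = np.concatenate([np.ones(len(pos_train), dtype=int),
                                np.zeros(len(neg_train), dtype=int)])

            spec = config.cnn_spec(2, x.shape[1])
            model = build_cnn(spec, seed=fold_seed)
            train(model, x, y, config.train_spec(fold_seed))

            genuine_groups = [
                grp for p in probe_by_subject[s]
                for grp in _group_consecutive(p.pixels, config.n_cycles)
            ]
            if not genuine_groups:
                logger.warning(
                    "subject %d has fewer than %d probe cycles; excluded",
                    s, config.n_cycles,
                )
                continue
            impostor_groups = [
                grp for o in subjects if o != s
                for p in probe_by_subject[o]
                for grp in _group_consecutive(p.pixels, config.n_cycles)
            ]
            pick = rng.permutation(len(impostor_groups))[: len(genuine_groups)]
            impostor_groups = [impostor_groups[i] for i in pick]

            counts = ConfusionCounts()
            for grp in genuine_groups:
                probs = predict(model, grp, batch_size=config.batch_size)
                if aggregate_cycles(probs, config.aggregation) == 1:
                    counts.tp += 1
                else:
                    counts.fn += 1
            for grp in impostor_groups:
                probs = predict(model, grp, batch_size=config.batch_size)
                if aggregate_cycles(probs, config.aggregation) == 1:
                    counts.fp += 1
                else:
                    counts.tn += 1
            per_subject[(fold, s)] = compute_metrics(counts)
            total = total + counts

    if not per_subject:
        raise ValueError("no subject produced any probe decision")

    def mean_of(attr: str) -> float | None:
        vals = [getattr(m, attr) for m in per_subject.values()
                if getattr(m, attr) is not None]
        return float(np.mean(vals)) if vals else None

    mean = Metrics(mean_of("precision"), mean_of("recall"), mean_of("accuracy"))
    return AuthResult(mean=mean, per_subject=per_subject, counts=total)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def sweep(
    gallery: list[CycleImages],
    probe: list[CycleImages],
    configs: list[ExperimentConfig],
) -> pd.DataFrame:
    """Run one experiment per config; failures are recorded, not raised."""
    rows = []
    for cfg in configs:
        row = {
            "task": cfg.task,
            "train_fraction": cfg.train_fraction,
            "n_cycles": cfg.n_cycles,
            "folds": cfg.folds,
            "seed": cfg.seed,
            "feature_maps": str(cfg.feature_maps),
            "fc1_width": cfg.fc1_width,
            "epochs": cfg.epochs,
            "error": "",
        }
        try:
            if cfg.task == "labeling":
                res = run_labeling(gallery, probe, cfg)
                row.update(accuracy=res.accuracy, precision=None, recall=None)
            elif cfg.task == "authentication":
                res = run_authentication(gallery, probe, cfg)
                row.update(
                    accuracy=res.mean.accuracy,
                    precision=res.mean.precision,
                    recall=res.mean.recall,
                )
            else:
                raise ValueError(f"unknown task {cfg.task!r}")
        except Exception as exc:  # recorded per spec: sweep continues
            logger.warning("sweep point failed: %s", exc)
            row.update(accuracy=None, precision=None, recall=None, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


def mu_grid(base: ExperimentConfig, fractions) -> list[ExperimentConfig]:
    """Configs varying the gallery training percentage."""
    return [replace(base, train_fraction=float(mu)) for mu in fractions]
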