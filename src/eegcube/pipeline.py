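"""End-to-end subject-dependent experiments.

One experiment runs, independently for every subject: encode trials into
spatio-temporal blocks -> stratified 80:20 train/test split within the
subject -> train the network (with a pretrained checkpoint the backbone is
frozen and only the dense head trains, the transfer-learning recipe;
without one, backbone and head train end-to-end) -> tap deep features
at Dense 1 -> fit a hybrid decision head (ELM by default, optionally grid
searched on a validation split carved from the training side only) ->
predict the test stream -> mode-filter sweep over window sizes -> metrics.
Subject accuracies are then averaged (mean and population SD).

Everything is driven by one :class:`ExperimentConfig` with a single global
seed; rerunning an identical config reproduces identical reports.  The
default split is over 1-s blocks within each subject (matching block-level
evaluation); ``split_by="trial"`` keeps whole trials on one side instead,
which is stricter because temporally adjacent blocks of one clip can no
longer straddle the split.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .encode import BlockArray, FrameEncoder, build_blocks, triplicate
from .heads import GridSearchSpec, elm_fit, elm_predict, fit_shallow, grid_search, predict_shallow
from .metrics import confusion, metrics, subject_average
from .montage import ElectrodeMap, RawRecording, load_montage
from .nn import (
    BackboneConfig,
    HeadConfig,
    TrainConfig,
    attach_head,
    build_backbone,
    parameter_checksum,
    train_transfer,
)
from .postfilter import LabelSequence, mode_filter, window_sweep
from .synth import SynthConfig, generate_recordings

__all__ = ["ExperimentConfig", "SplitError", "split_blocks", "encode_corpus",
           "run_experiment"]


class SplitError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    """All knobs of one subject-dependent experiment."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    montage_name: str = "seed62"
    window_samples: int = 200
    stride_samples: int | None = None  # None = non-overlapping (stride = w)
    epsilon: float = 1.0
    frame_size: int = 64
    normalize: bool = True
    width_multiplier: float = 1.0
    max_epochs: int = 200
    learning_rate: float = 1e-4
    batch_size: int = 4
    pretrained_weights: str | None = None
    freeze_backbone: bool | None = None  # None: freeze iff pretrained given
    head_kind: str = "elm"
    head_params: dict = field(default_factory=dict)
    head_grid: dict | None = None
    filter_windows: tuple[int, ...] = (5, 7, 9, 11, 13, 15)
    tie_policy: str = "keep-original"
    split_ratio: float = 0.8
    split_by: str = "block"  # or "trial"
    seed: int = 42

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"] = {
            k: v for k, v in asdict(self.synth).items() if k not in ("montage", "patterns")
        }
        return d


def split_blocks(
    arr: BlockArray, ratio: float = 0.8, seed: int = 0, by: str = "block"
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified per-subject train/test indices at the given ratio.

    Stratification is by class within each subject; with ``by="trial"``
    whole trials are assigned to one side.  Deterministic per seed.  Raises
    :class:`SplitError` naming the subject/class with fewer than two units.
    """
    if not (0 < ratio < 1):
        raise SplitError(f"split ratio must lie in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for subject in np.unique(arr.subject):
        s_mask = arr.subject == subject
        for cls in np.unique(arr.labels[s_mask]):
            idx = np.flatnonzero(s_mask & (arr.labels == cls))
            if by == "trial":
                units = np.unique(
                    np.stack([arr.session[idx], arr.trial[idx]], axis=1), axis=0
                )
                n_units = len(units)
            else:
                n_units = idx.size
            if n_units < 2:
                raise SplitError(
                    f"subject {subject}, class {cls}: {n_units} "
                    f"{by}(s), need >= 2 to split"
                )
            if by == "trial":
                order = rng.permutation(n_units)
                n_train = min(max(int(n_units * ratio + 0.5), 1), n_units - 1)
                chosen = {tuple(units[i]) for i in order[:n_train]}
                in_train = np.array(
                    [(s, t) in chosen for s, t in zip(arr.session[idx], arr.trial[idx])]
                )
                train_idx.append(idx[in_train])
                test_idx.append(idx[~in_train])
            else:
                order = rng.permutation(n_units)
                # round half up so a 50:50 split of an odd cell is stable
                n_train = min(max(int(n_units * ratio + 0.5), 1), n_units - 1)
                train_idx.append(idx[order[:n_train]])
                test_idx.append(idx[order[n_train:]])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def encode_corpus(
    recordings: list[RawRecording],
    montage: ElectrodeMap,
    w: int,
    stride: int | None = None,
    epsilon: float = 1.0,
    out_shape: tuple[int, int] = (64, 64),
    normalize: bool = True,
) -> BlockArray:
    """Encode every recording and stack the blocks into one array."""
    encoder = FrameEncoder(montage, epsilon=epsilon, out_shape=out_shape)
    blocks = []
    for rec in recordings:
        blocks.extend(
            build_blocks(rec, montage, w, stride=stride, normalize=normalize,
                         encoder=encoder)
        )
    return BlockArray.from_blocks(blocks, epsilon=epsilon,
                                  montage_hash=montage.content_hash())


def _fit_decision_head(cfg: ExperimentConfig, feats, labels, n_classes, seed):
    params = dict(cfg.head_params)
    grid_table = None
    if cfg.head_grid:
        res = grid_search(
            GridSearchSpec(cfg.head_kind, cfg.head_grid, seed=seed), feats, labels
        )
        params.update(res.best_params)
        grid_table = [[c, s] for c, s in res.table]
    if cfg.head_kind == "elm":
        model = elm_fit(feats, labels, seed=seed, n_classes=n_classes, **params)
        predict = lambda f: elm_predict(model, f)[0]
    else:
        model = fit_shallow(cfg.head_kind, feats, labels, params, seed=seed)
        predict = lambda f: predict_shallow(model, f)
    return predict, params, grid_table


def _stream_order(arr: BlockArray, idx: np.ndarray) -> np.ndarray:
    key = np.stack([arr.session[idx], arr.trial[idx], arr.start[idx]])
    return idx[np.lexsort(key[::-1])]


def _boundaries(arr: BlockArray, idx: np.ndarray) -> list[tuple[int, int]]:
    runs = np.stack([arr.session[idx], arr.trial[idx]], axis=1)
    change = np.flatnonzero(np.any(runs[1:] != runs[:-1], axis=1)) + 1
    edges = [0, *change.tolist(), idx.size]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def run_experiment(
    cfg: ExperimentConfig,
    recordings: list[RawRecording] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full subject-dependent experiment; returns the report dict.

    With ``out_dir`` given, writes ``report.json`` and per-subject label
    streams (``trial,second,true,pred,pred_filtered`` CSV).
    """
    montage = load_montage(cfg.montage_name)
    if recordings is None:
        recordings = generate_recordings(cfg.synth)
    n_classes = int(max(r.label for r in recordings)) + 1
    arr = encode_corpus(
        recordings, montage, cfg.window_samples, stride=cfg.stride_samples,
        epsilon=cfg.epsilon, out_shape=(cfg.frame_size, cfg.frame_size),
        normalize=cfg.normalize,
    )
    train_idx, test_idx = split_blocks(
        arr, cfg.split_ratio, seed=cfg.seed, by=cfg.split_by
    )
    w = arr.blocks.shape[1]
    per_subject: dict[str, dict] = {}
    streams: dict[int, "object"] = {}
    subjects = np.unique(arr.subject)
    for subject in subjects:
        tr = train_idx[arr.subject[train_idx] == subject]
        te = test_idx[arr.subject[test_idx] == subject]
        x_train = np.repeat(arr.blocks[tr][:, None], 3, axis=1)
        x_test = np.repeat(arr.blocks[te][:, None], 3, axis=1)
        backbone = build_backbone(
            BackboneConfig(
                width_multiplier=cfg.width_multiplier,
                input_shape=(3, w, cfg.frame_size, cfg.frame_size),
                seed=cfg.seed + int(subject),
            )
        )
        freeze = cfg.freeze_backbone
        if freeze is None:
            freeze = cfg.pretrained_weights is not None
        if cfg.pretrained_weights is not None:
            from .nn import load_pretrained

            load_pretrained(backbone, cfg.pretrained_weights, strict=False)
        else:
            backbone.calibrate_bn(x_train)
        model = attach_head(backbone, HeadConfig(n_classes, seed=cfg.seed + int(subject)))
        pre_checksum = parameter_checksum(backbone.state())
        model, history = train_transfer(
            model, x_train, arr.labels[tr],
            TrainConfig(
                learning_rate=cfg.learning_rate, max_epochs=cfg.max_epochs,
                batch_size=cfg.batch_size, seed=cfg.seed + int(subject),
                freeze_backbone=freeze,
            ),
        )
        if freeze and parameter_checksum(backbone.state()) != pre_checksum:
            raise RuntimeError(
                f"subject {subject}: frozen backbone parameters changed"
            )
        f_train = model.features(x_train)
        f_test = model.features(x_test)
        predict, head_params, grid_table = _fit_decision_head(
            cfg, f_train, arr.labels[tr], n_classes, cfg.seed + int(subject)
        )
        mlp_pred = model.predict(x_test)
        head_pred = np.empty(len(arr), dtype=np.int64)
        head_pred[te] = predict(f_test)
        # mode filter on the time-ordered test stream of this subject
        ordered = _stream_order(arr, te)
        truth = LabelSequence(arr.labels[ordered], n_classes,
                              _boundaries(arr, ordered))
        pred_seq = LabelSequence(head_pred[ordered], n_classes,
                                 list(truth.boundaries))
        sweep = window_sweep(pred_seq, truth, list(cfg.filter_windows),
                             tie_policy=cfg.tie_policy)
        report = metrics(confusion(arr.labels[te], head_pred[te], n_classes))
        mlp_report = metrics(confusion(arr.labels[te], mlp_pred, n_classes))
        per_subject[str(int(subject))] = {
            "n_train": int(tr.size),
            "n_test": int(te.size),
            "mlp": mlp_report.to_dict(),
            "head": report.to_dict(),
            "head_params": head_params,
            "grid": grid_table,
            "final_train_accuracy": history["accuracy"][-1],
            "best_epoch": history.get("best_epoch", 0),
            "sweep": [[wd, acc] for wd, acc in sweep],
        }
        streams[int(subject)] = (ordered, truth, pred_seq)
    head_accs = [v["head"]["accuracy"] for v in per_subject.values()]
    mlp_accs = [v["mlp"]["accuracy"] for v in per_subject.values()]
    mean, sd = subject_average(head_accs)
    mlp_mean, mlp_sd = subject_average(mlp_accs)
    n_windows = len(cfg.filter_windows) + 1
    sweep_mean = [
        [per_subject[str(int(subjects[0]))]["sweep"][j][0],
         float(np.mean([v["sweep"][j][1] for v in per_subject.values()]))]
        for j in range(n_windows)
    ]
    report = {
        "config": cfg.to_dict(),
        "n_classes": n_classes,
        "per_subject": per_subject,
        "average": {
            "head_accuracy_mean": mean,
            "head_accuracy_sd": sd,
            "mlp_accuracy_mean": mlp_mean,
            "mlp_accuracy_sd": mlp_sd,
            "sweep_mean": sweep_mean,
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        import pandas as pd

        for subject, (ordered, truth, pred_seq) in streams.items():
            filtered = mode_filter(pred_seq, cfg.filter_windows[0],
                                   tie_policy=cfg.tie_policy)
            pd.DataFrame(
                {
                    "trial": arr.trial[ordered],
                    "second": arr.start[ordered] // max(int(arr.fs), 1),
                    "true": truth.labels,
                    "pred": pred_seq.labels,
                    "pred_filtered": filtered.labels,
                }
            ).to_csv(out_dir / f"stream_subject{subject:02d}.csv", index=False)
    return report
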