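"""Plain-text serialization of trained model bundles.

A bundle directory holds ``bundle.json`` (frame, ensemble config, fitted
per-class rates) plus one TSV per descriptor mode with the training rows:
binary modes store support sets, the evolution mode stores full float rows
per correlation tier.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .descriptors import GOVector
from .ensemble import EnsembleConfig, TrainedModel
from .etknn import Frame, TrainingSet

BUNDLE_FILE = "bundle.json"


def _write_binary_tsv(path: Path, training: TrainingSet) -> None:
    with open(path, "w") as fh:
        dim = training.X.shape[1]
        for row, label in zip(training.X, training.y):
            support = ",".join(str(i) for i in np.flatnonzero(row))
            fh.write(f"{training.frame.classes[label]}\t{dim}\t{support}\n")


def _read_binary_tsv(path: Path, frame: Frame) -> TrainingSet:
    rows, ys = [], []
    dim = 0
    for line in path.read_text().splitlines():
        label, dim_s, support = line.split("\t")
        dim = int(dim_s)
        arr = np.zeros(dim)
        if support:
            arr[[int(i) for i in support.split(",")]] = 1.0
        rows.append(arr)
        ys.append(frame.index(label))
    return TrainingSet(np.array(rows), np.array(ys), frame)


def _write_float_tsv(path: Path, training: TrainingSet) -> None:
    with open(path, "w") as fh:
        for row, label in zip(training.X, training.y):
            values = ",".join(repr(float(v)) for v in row)
            fh.write(f"{training.frame.classes[label]}\t{values}\n")


def _read_float_tsv(path: Path, frame: Frame) -> TrainingSet:
    rows, ys = [], []
    for line in path.read_text().splitlines():
        label, values = line.split("\t")
        rows.append(np.array([float(v) for v in values.split(",")]))
        ys.append(frame.index(label))
    return TrainingSet(np.array(rows), np.array(ys), frame)


def save_model(model: TrainedModel, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = model.config
    meta = {
        "frame": list(model.frame.classes),
        "config": {
            "k_grid": list(cfg.k_grid),
            "lambda_grid": list(cfg.lambda_grid),
            "tau": cfg.tau,
            "mode_weights": dict(cfg.mode_weights),
            "alpha": cfg.alpha,
            "fit_gammas": cfg.fit_gammas,
            "fit_max_iter": cfg.fit_max_iter,
            "seed": cfg.seed,
        },
        "gammas": {
            "go": None if model.go_gamma is None else list(map(float, model.go_gamma)),
            "fund": (
                None if model.fund_gamma is None else list(map(float, model.fund_gamma))
            ),
            "psepssm": {
                str(lam): list(map(float, gam)) for lam, gam in model.pse_gamma.items()
            },
        },
        "modes": {
            "go": model.go_training is not None,
            "fund": model.fund_training is not None,
            "psepssm": sorted(model.pse_training),
        },
    }
    (out / BUNDLE_FILE).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    if model.go_training is not None:
        _write_binary_tsv(out / "go_vectors.tsv", model.go_training)
    if model.fund_training is not None:
        _write_binary_tsv(out / "fund_vectors.tsv", model.fund_training)
    for lam, training in model.pse_training.items():
        _write_float_tsv(out / f"psepssm_{lam:02d}.tsv", training)
    return out / BUNDLE_FILE


def load_model(model_dir: str | Path) -> TrainedModel:
    path = Path(model_dir)
    meta = json.loads((path / BUNDLE_FILE).read_text())
    frame = Frame(tuple(meta["frame"]))
    c = meta["config"]
    config = EnsembleConfig(
        k_grid=tuple(c["k_grid"]),
        lambda_grid=tuple(c["lambda_grid"]),
        tau=c["tau"],
        mode_weights=c["mode_weights"],
        alpha=c["alpha"],
        fit_gammas=c["fit_gammas"],
        fit_max_iter=c["fit_max_iter"],
        seed=c["seed"],
    )
    model = TrainedModel(frame=frame, config=config)
    gammas = meta["gammas"]
    if meta["modes"]["go"]:
        model.go_training = _read_binary_tsv(path / "go_vectors.tsv", frame)
        model.go_gamma = np.array(gammas["go"])
        dim = model.go_training.X.shape[1]
        model.go_vectors = [
            GOVector(frozenset(int(i) for i in np.flatnonzero(row)), dim)
            for row in model.go_training.X
        ]
    if meta["modes"]["fund"]:
        model.fund_training = _read_binary_tsv(path / "fund_vectors.tsv", frame)
        model.fund_gamma = np.array(gammas["fund"])
    for lam in meta["modes"]["psepssm"]:
        model.pse_training[lam] = _read_float_tsv(
            path / f"psepssm_{lam:02d}.tsv", frame
        )
        model.pse_gamma[lam] = np.array(gammas["psepssm"][str(lam)])
    return model
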