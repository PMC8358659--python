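"""File formats: delimited feature matrices, epoch directories, model archives.

Feature files are delimited text (CSV), one sample per row, a header row
``f0,...,f{d-1},label`` and a trailing integer label column; in memory the
matrix is transposed to the samples-as-columns convention.

Epochs are read from a directory of per-epoch delimited matrices
(channels x timepoints, one file per epoch, lexicographic order) plus a
``labels.csv`` with one integer per line, or from a single ``.npz``
archive with arrays ``epoch_00000, ...`` and ``labels``.

Trained models are a single ``.npz`` archive holding the projections,
dictionary, class list, hyperparameters (JSON) and the training log.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .core import (
    ClassDictionary,
    DASRCModel,
    HyperParams,
    IterationRecord,
    ProjectionPair,
    TrainLog,
)
from .domain import LabeledDomain
from .errors import InputError
from .features import Epoch

__all__ = [
    "load_features",
    "save_features",
    "load_epochs",
    "save_model",
    "load_model",
]

LABEL_COLUMN = "label"


def save_features(domain: LabeledDomain, path: str | Path) -> None:
    """Write a labeled domain as row-sample CSV with a trailing label column."""
    df = pd.DataFrame(domain.X.T, columns=[f"f{i}" for i in range(domain.d)])
    df[LABEL_COLUMN] = domain.labels
    df.to_csv(path, index=False)


def load_features(path: str | Path) -> LabeledDomain:
    """Read a row-sample CSV (trailing integer label column) into a domain."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"feature file not found: {path}")
    df = pd.read_csv(path)
    if LABEL_COLUMN not in df.columns:
        raise InputError(f"{path}: missing '{LABEL_COLUMN}' column")
    labels = df[LABEL_COLUMN].to_numpy()
    X = df.drop(columns=[LABEL_COLUMN]).to_numpy(dtype=float).T
    if not np.all(labels == labels.astype(int)):
        raise InputError(f"{path}: non-integer labels")
    return LabeledDomain(X, labels.astype(int))


def load_epochs(path: str | Path, sampling_rate: float) -> List[Epoch]:
    """Read epochs from a directory of delimited matrices or an .npz archive."""
    path = Path(path)
    if path.is_dir():
        labels_file = path / "labels.csv"
        if not labels_file.exists():
            raise InputError(f"missing labels file: {labels_file}")
        labels = np.loadtxt(labels_file, dtype=int, ndmin=1)
        files = sorted(p for p in path.iterdir() if p.name != "labels.csv")
        if len(files) != len(labels):
            raise InputError(
                f"{path}: {len(files)} epoch files but {len(labels)} labels"
            )
        return [
            Epoch(np.loadtxt(f, delimiter=",", ndmin=2), sampling_rate, int(lab))
            for f, lab in zip(files, labels)
        ]
    if path.suffix == ".npz":
        with np.load(path) as npz:
            labels = npz["labels"]
            keys = sorted(k for k in npz.files if k.startswith("epoch_"))
            if len(keys) != len(labels):
                raise InputError(f"{path}: epoch/label count mismatch")
            return [
                Epoch(npz[k], sampling_rate, int(lab))
                for k, lab in zip(keys, labels)
            ]
    raise InputError(f"cannot read epochs from {path}")


def save_model(model: DASRCModel, path: str | Path) -> None:
    """Serialize a trained model to one .npz archive."""
    log = np.array(
        [
            [r.iteration, r.objective, r.fisher_num, r.fisher_den, r.trace_term,
             r.beta, r.gamma, r.ortho_violation, r.max_atom_norm, float(r.accepted)]
            for r in model.log.records
        ]
    ).reshape(-1, 10)
    hp = {k: v for k, v in dataclasses.asdict(model.hyper).items()}
    np.savez(
        path,
        Ms=model.projections.Ms,
        Mt=model.projections.Mt,
        atoms=model.dictionary.atoms,
        atom_class=model.dictionary.atom_class,
        classes=model.classes,
        hyper=np.frombuffer(json.dumps(hp).encode(), dtype=np.uint8),
        log=log,
    )


def load_model(path: str | Path) -> DASRCModel:
    """Load a model archive written by :func:`save_model`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"model file not found: {path}")
    with np.load(path) as npz:
        hp_dict = json.loads(bytes(npz["hyper"]).decode())
        hp = HyperParams(**hp_dict)
        records = [
            IterationRecord(
                int(row[0]), *[float(v) for v in row[1:9]], bool(row[9])
            )
            for row in npz["log"]
        ]
        return DASRCModel(
            projections=ProjectionPair(npz["Ms"], npz["Mt"]),
            dictionary=ClassDictionary(npz["atoms"], npz["atom_class"]),
            hyper=hp,
            log=TrainLog(records),
            classes=npz["classes"],
        )
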