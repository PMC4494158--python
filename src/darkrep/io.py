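"""Delimited-text input/output.

The on-disk dialect is deliberately plain: the signal matrix is a TSV whose
first column is the gene identifier and whose remaining columns are samples,
with a sidecar TSV of sample metadata (sample_id, condition, time_min,
experiment).  Ground-truth tables and result tables use the same flavour.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .containers import SAMPLE_COLUMNS, SignalMatrix


def write_signal_matrix(sm: SignalMatrix, values_path, meta_path) -> None:
    sm.values.to_csv(values_path, sep="\t", index_label="gene")
    sm.samples.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_signal_matrix(values_path, meta_path) -> SignalMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene")
    samples = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    samples["time_min"] = samples["time_min"].astype(int)
    samples["experiment"] = samples["experiment"].astype(int)
    return SignalMatrix(values, samples[list(SAMPLE_COLUMNS)])


def write_truth_table(truth, path) -> None:
    """Serialise a TruthTable as one wide TSV (fold columns `condition@time`)."""
    wide = truth.fold.copy()
    wide.columns = [f"{c}@{t}" for c, t in wide.columns]
    wide.insert(0, "class", truth.classes)
    wide.insert(1, "attenuated", truth.attenuated.astype(int))
    wide.to_csv(path, sep="\t", index_label="gene")


def read_truth_table(path):
    from .simulate import TruthTable  # local import avoids a cycle

    wide = pd.read_csv(path, sep="\t", index_col="gene")
    classes = wide.pop("class")
    attenuated = wide.pop("attenuated").astype(bool)
    cols = pd.MultiIndex.from_tuples(
        [(c, int(t)) for c, t in (name.rsplit("@", 1) for name in wide.columns)],
        names=["condition", "time_min"],
    )
    wide.columns = cols
    return TruthTable(classes=classes, fold=wide, attenuated=attenuated)


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
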