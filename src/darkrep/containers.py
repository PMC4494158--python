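"""Core data containers.

The central object is the :class:`SignalMatrix`: a nonnegative gene x sample
intensity table (already genomic-DNA-normalized) plus per-sample metadata
(condition label, time in minutes, experiment index).  Downstream stages
produce :class:`NormalizationFactors` and a :class:`DiffMatrix` of
differences from each experiment's light time-0 value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StructuralError

#: Canonical condition labels used throughout the pipeline.
LIGHT = "light"
DARK = "dark"
LIGHT_DCMU = "light+DCMU"
LIGHT_DBMIB = "light+DBMIB"
DARK_DBMIB = "dark+DBMIB"
DARK_DBMIB_RIF = "dark+DBMIB+rifampicin"

DEFAULT_CONDITIONS = (LIGHT, DARK, LIGHT_DCMU, LIGHT_DBMIB, DARK_DBMIB, DARK_DBMIB_RIF)

SAMPLE_COLUMNS = ("condition", "time_min", "experiment")


def make_sample_id(condition: str, time_min: int, experiment: int) -> str:
    return f"e{experiment}_{condition}_t{int(time_min):03d}"


@dataclass
class SignalMatrix:
    """Gene x sample intensities with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier, one column per sample id.
        All entries must be finite and nonnegative.
    samples
        DataFrame indexed by sample id with columns ``condition`` (str),
        ``time_min`` (int) and ``experiment`` (int).  Every (condition,
        time, experiment) key must be unique and a light time-0 sample
        must exist for every experiment.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise StructuralError(f"sample metadata lacks column {col!r}")
        if list(self.values.columns) != list(self.samples.index):
            # allow metadata in any order but covering the same samples
            if set(self.values.columns) != set(self.samples.index):
                raise StructuralError("values columns and sample metadata disagree")
            self.samples = self.samples.loc[self.values.columns]
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise StructuralError("signal matrix contains non-finite values")
        if (vals < 0).any():
            raise StructuralError("signal matrix contains negative intensities")
        keys = list(zip(self.samples["condition"], self.samples["time_min"],
                        self.samples["experiment"]))
        if len(set(keys)) != len(keys):
            raise StructuralError("duplicate (condition, time, experiment) sample keys")
        for n in self.experiments:
            try:
                self.sample_id(LIGHT, 0, n)
            except KeyError:
                raise StructuralError(
                    f"experiment {n} lacks a light time-0 sample") from None

    # -- accessors -----------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def experiments(self) -> list[int]:
        return sorted(self.samples["experiment"].unique())

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))

    @property
    def times(self) -> list[int]:
        return sorted(self.samples["time_min"].unique())

    def sample_id(self, condition: str, time_min: int, experiment: int) -> str:
        mask = ((self.samples["condition"] == condition)
                & (self.samples["time_min"] == time_min)
                & (self.samples["experiment"] == experiment))
        ids = self.samples.index[mask]
        if len(ids) == 0:
            raise KeyError(f"no sample ({condition!r}, t={time_min}, n={experiment})")
        return ids[0]

    def column(self, condition: str, time_min: int, experiment: int) -> pd.Series:
        return self.values[self.sample_id(condition, time_min, experiment)]

    def experiment_columns(self, experiment: int) -> list[str]:
        return list(self.samples.index[self.samples["experiment"] == experiment])

    def has_sample(self, condition: str, time_min: int, experiment: int) -> bool:
        try:
            self.sample_id(condition, time_min, experiment)
            return True
        except KeyError:
            return False

    def copy(self) -> "SignalMatrix":
        return SignalMatrix(self.values.copy(), self.samples.copy())


@dataclass
class NormalizationFactors:
    """Per-experiment total factor Y(n) and per-gene factor Z(g, n).

    ``Y`` is a Series indexed by experiment; ``Z`` a DataFrame indexed by
    gene with one column per experiment.  ``excluded_genes`` lists genes
    dropped because their light time-0 cross-experiment mean was zero.
    """

    Y: pd.Series | None = None
    Z: pd.DataFrame | None = None
    excluded_genes: list = field(default_factory=list)


@dataclass
class DiffMatrix:
    """dx(g, c, t, n): normalized signal minus the same experiment's light
    time-0 value.  Shares the sample-metadata layout of SignalMatrix but
    entries may be negative."""

    values: pd.DataFrame
    samples: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def experiments(self) -> list[int]:
        return sorted(self.samples["experiment"].unique())

    @property
    def times(self) -> list[int]:
        return sorted(self.samples["time_min"].unique())

    def sample_id(self, condition: str, time_min: int, experiment: int) -> str:
        mask = ((self.samples["condition"] == condition)
                & (self.samples["time_min"] == time_min)
                & (self.samples["experiment"] == experiment))
        ids = self.samples.index[mask]
        if len(ids) == 0:
            raise KeyError(f"no sample ({condition!r}, t={time_min}, n={experiment})")
        return ids[0]

    def has_sample(self, condition: str, time_min: int, experiment: int) -> bool:
        try:
            self.sample_id(condition, time_min, experiment)
            return True
        except KeyError:
            return False
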