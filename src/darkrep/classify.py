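"""Directional gene sets and their overlaps.

A :class:`DirectionalGeneSet` records, for one condition, the regulated
genes together with their direction (up/down).  Overlap counting is
*directional*: a gene is shared between sets only when its direction agrees
in every one of them; genes whose membership pattern agrees but whose
directions conflict are tallied separately so that region counts still
partition the union.

The *attenuation set* operationalises "DBMIB attenuated the dark
dependency": a dark-regulated gene is attenuated when its dark+DBMIB
profile differs significantly from its dark profile (modified-Dunnett
contrast with dark as the control) and the dark+DBMIB effect is pulled
toward the light state (smaller |mean dx| than under dark).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StructuralError
from .mulcom import MulcomResult

UP = "up"
DOWN = "down"


@dataclass
class DirectionalGeneSet:
    label: str
    members: pd.Series  # index gene -> 'up' | 'down'

    def __post_init__(self) -> None:
        if self.members.index.has_duplicates:
            raise ConfigurationError(
                f"set {self.label!r} lists a gene more than once")
        bad = set(self.members.unique()) - {UP, DOWN}
        if bad:
            raise ConfigurationError(f"invalid directions {bad} in {self.label!r}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene) -> bool:
        return gene in self.members.index


def build_set(result: MulcomResult, condition: str) -> DirectionalGeneSet:
    """The regulated genes of one condition, with directions."""
    if condition not in set(result.calls["condition"]):
        raise KeyError(f"condition {condition!r} not covered by this result")
    sub = result.calls[(result.calls["condition"] == condition)
                       & result.calls["regulated"]]
    members = pd.Series(sub["direction"].to_numpy(),
                        index=pd.Index(sub["gene"], name="gene"))
    return DirectionalGeneSet(label=condition, members=members)


@dataclass
class OverlapResult:
    """Exclusive Venn regions keyed by frozenset of set labels.

    ``regions[R]`` counts genes present in exactly the sets R with one
    shared direction; ``discordant[R]`` counts genes present in exactly R
    (|R| > 1) whose directions conflict.  Together the counts partition the
    union of the input sets.
    """

    regions: dict = field(default_factory=dict)
    discordant: dict = field(default_factory=dict)
    union_size: int = 0
    #: per-gene membership: gene, region (sorted labels joined by '&'),
    #: concordant flag
    members: pd.DataFrame = field(default_factory=pd.DataFrame)

    def shared(self, *labels) -> int:
        """Genes shared (same direction) by *at least* the given sets."""
        want = frozenset(labels)
        return sum(c for r, c in self.regions.items() if want <= r)


def directional_overlap(sets) -> OverlapResult:
    sets = list(sets)
    if len(sets) < 2:
        raise ConfigurationError("need at least two sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("set labels must be unique")
    union = sorted(set().union(*(set(s.members.index) for s in sets)))
    regions: dict = {}
    discordant: dict = {}
    rows = []
    for gene in union:
        present = frozenset(s.label for s in sets if gene in s)
        directions = {s.members.loc[gene] for s in sets if gene in s}
        concordant = len(directions) == 1
        bucket = regions if concordant else discordant
        bucket[present] = bucket.get(present, 0) + 1
        rows.append((gene, "&".join(sorted(present)), concordant))
    members = pd.DataFrame(rows, columns=["gene", "region", "concordant"])
    return OverlapResult(regions=regions, discordant=discordant,
                         union_size=len(union), members=members)


def attenuation_set(dark_set: DirectionalGeneSet,
                    result_darkDBMIB: MulcomResult,
                    condition: str = "dark+DBMIB") -> DirectionalGeneSet:
    """Dark-regulated genes whose dark+DBMIB behaviour differs significantly
    from dark, in the attenuating direction (|mean dx| reduced).

    ``result_darkDBMIB`` must come from a contrast of ``condition`` against
    the dark control.  Members keep their dark direction; the result is
    always a subset of ``dark_set``.
    """
    if condition not in set(result_darkDBMIB.calls["condition"]):
        raise StructuralError(
            f"result does not contain the {condition!r} contrast")
    calls = result_darkDBMIB.calls
    sub = calls[(calls["condition"] == condition) & calls["regulated"]]
    # attenuating direction: effect pulled toward light (smaller |mean dx|
    # than the dark control at the most significant time point)
    pulled = np.abs(sub["best_diff"] + sub["best_ctrl_mean"]) < np.abs(
        sub["best_ctrl_mean"])
    atten = set(sub.loc[pulled.to_numpy(), "gene"])
    members = dark_set.members[dark_set.members.index.isin(atten)]
    return DirectionalGeneSet(label=f"{dark_set.label}:{condition}-attenuated",
                              members=members.copy())


def summary_fractions(sets, universe_size: int,
                      reference_label: str | None = None) -> dict:
    """Set sizes as fractions (percent) of the gene universe and of one
    reference set, with numerators/denominators reported."""
    if universe_size <= 0:
        raise ConfigurationError("universe_size must be positive")
    sets = {s.label: s for s in sets}
    ref_n = len(sets[reference_label]) if reference_label else None
    report = {"universe_size": int(universe_size),
              "reference": reference_label, "sets": {}}
    for label, s in sets.items():
        entry = {"n": len(s), "universe": int(universe_size),
                 "pct_universe": 100.0 * len(s) / universe_size}
        if ref_n:
            entry["pct_reference"] = 100.0 * len(s) / ref_n
            entry["reference_n"] = ref_n
        report["sets"][label] = entry
    return report
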