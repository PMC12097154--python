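"""Experiment designs for multi-run proximity-labeling studies.

A design maps each MS sample to its run, bait construct, treatment,
timepoint and replicate. Designs are the backbone of the pipeline: they
define which samples form a biological triplicate (the unit for
missingness classification and MAR imputation) and which triplicate pairs
constitute legal within-run contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["ExperimentDesign", "generate_design", "torc_study_design"]

#: factor columns that identify a triplicate within a run
TRIPLICATE_KEY = ["run_id", "bait", "construct", "treatment", "timepoint_h"]

_CONSTRUCTS = ("constitutive", "inducible", "none")


def _parse_bait(token: str) -> tuple[str, str]:
    """Split ``"LST8:inducible"`` into (bait, construct).

    A bare bait name defaults to the constitutive construct, except the
    GFP control bait which carries no PUP(E) construct of its own.
    """
    if ":" in token:
        name, construct = token.split(":", 1)
        if construct not in _CONSTRUCTS:
            raise ValueError(
                f"unknown construct {construct!r}; expected one of {_CONSTRUCTS}"
            )
        return name, construct
    if token.upper() == "GFP":
        return token, "none"
    return token, "constitutive"


@dataclass(frozen=True)
class ExperimentDesign:
    """Sample-to-factor mapping for one or more MS runs.

    ``table`` has one row per sample with columns ``sample_id, run_id,
    bait, construct, treatment, timepoint_h, replicate``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = {"sample_id", "replicate", *TRIPLICATE_KEY} - set(t.columns)
        if missing:
            raise ValueError(f"design table lacks columns: {sorted(missing)}")
        if t["sample_id"].duplicated().any():
            dupes = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_ids: {dupes}")
        for key, grp in t.groupby(TRIPLICATE_KEY, sort=False):
            if len(grp) != 3 or sorted(grp["replicate"]) != [1, 2, 3]:
                raise ValueError(
                    f"group {key} is not a triplicate with replicates 1,2,3"
                )

    @property
    def samples(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def runs(self) -> list[str]:
        return list(dict.fromkeys(self.table["run_id"]))

    def triplicates(self) -> list[tuple[tuple, list[str]]]:
        """(factor-tuple, [3 sample_ids]) for every triplicate, in table order."""
        out = []
        for key, grp in self.table.groupby(TRIPLICATE_KEY, sort=False):
            out.append((key, grp.sort_values("replicate")["sample_id"].tolist()))
        return out

    def run_samples(self, run_id: str) -> list[str]:
        return self.table.loc[self.table["run_id"] == run_id, "sample_id"].tolist()

    def bait_construct(self, bait: str, construct: str) -> str:
        """Canonical construct identity, e.g. ``LST8/inducible`` or ``ScFKBP``."""
        return bait_construct_id(bait, construct)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ExperimentDesign":
        return cls(pd.read_csv(path, sep="\t"))


def bait_construct_id(bait: str, construct: str) -> str:
    if construct in ("none", "", None) or pd.isna(construct):
        return str(bait)
    return f"{bait}/{construct}"


def generate_design(
    n_runs: int,
    baits: Sequence[str],
    treatments: Sequence[str],
    timepoints: Sequence[float],
    seed: int = 0,
    run_prefix: str = "run",
) -> ExperimentDesign:
    """Fully crossed design: runs x baits x treatments x timepoints x 3 reps.

    ``baits`` entries may carry an explicit construct as ``"LST8:inducible"``;
    bare names default to constitutive (GFP to no construct). The layout is a
    deterministic function of its inputs; ``seed`` is accepted for interface
    symmetry with the stochastic generators.
    """
    del seed  # layout is deterministic
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    for name, lst in [("baits", baits), ("treatments", treatments),
                      ("timepoints", timepoints)]:
        if len(lst) == 0:
            raise ValueError(f"{name} must be non-empty")
    rows = []
    for r in range(1, n_runs + 1):
        run_id = f"{run_prefix}{r}"
        for token in baits:
            bait, construct = _parse_bait(str(token))
            for treatment in treatments:
                for tp in timepoints:
                    for rep in (1, 2, 3):
                        rows.append(
                            {
                                "sample_id": f"{run_id}.{bait}.{construct[:4]}."
                                f"{treatment}.{tp:g}h.{rep}",
                                "run_id": run_id,
                                "bait": bait,
                                "construct": construct,
                                "treatment": treatment,
                                "timepoint_h": float(tp),
                                "replicate": rep,
                            }
                        )
    return ExperimentDesign(pd.DataFrame(rows))


def concat_designs(designs: Iterable[ExperimentDesign]) -> ExperimentDesign:
    table = pd.concat([d.table for d in designs], ignore_index=True)
    return ExperimentDesign(table)


def torc_study_design() -> ExperimentDesign:
    """The default five-construct TORC study layout.

    Three MS runs emulating the study conditions: a constitutive-PUP(E) run
    (LST8 and RAPTOR baits plus the GFP control, sucrose vs mannitol, 24 h),
    an inducible-PUP(E) run (same baits and control, 4 and 24 h), and a
    rapamycin run (ScFKBP bait, rapamycin vs untreated, 4 and 24 h, where the
    untreated samples are the control condition instead of a control bait).
    """
    d1 = generate_design(
        1, ["LST8:constitutive", "RAPTOR:constitutive", "GFP"],
        ["sucrose", "mannitol"], [24], run_prefix="const",
    )
    d2 = generate_design(
        1, ["LST8:inducible", "RAPTOR:inducible", "GFP"],
        ["sucrose", "mannitol"], [4, 24], run_prefix="induc",
    )
    d3 = generate_design(
        1, ["ScFKBP:constitutive"], ["rapamycin", "none"], [4, 24],
        run_prefix="rapa",
    )
    return concat_designs([d1, d2, d3])


#: treatments regarded as the within-run control condition
CONTROL_TREATMENTS = frozenset({"mannitol", "none"})
#: the control bait for unspecific (non-bait-dependent) labeling
CONTROL_BAIT = "GFP"
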