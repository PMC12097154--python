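"""Synthetic peptide quantification data with planted ground truth.

Emulates a MaxLFQ-style peptide table from a multi-run proximity-labeling
study: log-normal intensities built additively on the log2 scale from a
protein baseline, peptide offsets, a planted bait-specific enrichment
effect and Gaussian noise; intensity-dependent (MNAR) and random (MAR)
dropout; decoy and contaminant rows. Every planted structure is recorded
in a :class:`GroundTruth` object so downstream stages can be scored.

The generator does not emulate raw spectra, retention times or the
peptide-search step; its output is the post-search quantification table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import (
    CONTROL_BAIT,
    CONTROL_TREATMENTS,
    ExperimentDesign,
    bait_construct_id,
)

__all__ = ["QuantSimParams", "GroundTruth", "generate_peptide_quant",
           "generate_reference_sets", "ReferenceSets"]

META_COLUMNS = ["peptide", "protein", "is_decoy", "is_contaminant", "n_ions"]


@dataclass
class QuantSimParams:
    """Generator settings; defaults are the study conditions.

    Intensities are additive on the log2 scale: protein baselines are
    N(25, 2) (MaxLFQ-like dynamic range), peptide offsets N(0, 1), noise
    N(0, ``noise_sd``). MNAR dropout probability is a decreasing logistic
    in the true log2 intensity with midpoint ``mnar_midpoint`` and slope
    ``mnar_slope`` (slope 0 disables it); MAR dropout is uniform at
    ``mar_rate``.
    """

    n_proteins: int = 400
    peptides_per_protein: tuple[int, int] = (2, 8)
    effect_log2_range: tuple[float, float] = (2.0, 4.0)
    noise_sd: float = 0.5
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    peptide_sd: float = 1.0
    mnar_midpoint: float = 21.5
    mnar_slope: float = 0.8
    mar_rate: float = 0.02
    frac_true_per_tier: dict = field(
        default_factory=lambda: {"core": 0.05, "wider": 0.05, "widest": 0.05}
    )
    frac_gfp: float = 0.03
    frac_control_enriched: float = 0.03
    frac_substrate: float = 0.02
    frac_contaminant: float = 0.05
    frac_decoy: float = 0.05
    frac_single_ion: float = 0.03
    frac_known_of_true: float = 0.5
    frac_thylakoid: float = 0.10
    frac_promiscuous: float = 0.20

    def validate(self) -> None:
        for name in ("mar_rate", "frac_gfp", "frac_control_enriched",
                     "frac_substrate", "frac_contaminant", "frac_decoy",
                     "frac_single_ion", "frac_known_of_true",
                     "frac_thylakoid", "frac_promiscuous"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


@dataclass
class ProteinTruth:
    true_tier: str = "none"
    enriched_in: set = field(default_factory=set)
    gfp_enriched: bool = False
    control_enriched: bool = False
    substrate: bool = False
    effect_log2: float = 0.0
    thylakoid: bool = False
    known_interactor: bool = False
    promiscuous: bool = False


@dataclass
class GroundTruth:
    """Planted structure of a synthetic study.

    ``proteins`` maps protein_id to its planted role; ``mnar_mask`` /
    ``mar_mask`` mark which cells were dropped by each mechanism;
    ``true_log2`` holds the pre-dropout log2 intensities.
    """

    proteins: dict[str, ProteinTruth]
    mnar_mask: pd.DataFrame = field(repr=False, default=None)
    mar_mask: pd.DataFrame = field(repr=False, default=None)
    true_log2: pd.DataFrame = field(repr=False, default=None)

    def tier_set(self, tier: str) -> set[str]:
        return {p for p, t in self.proteins.items() if t.true_tier == tier}

    def flagged(self, attr: str) -> set[str]:
        return {p for p, t in self.proteins.items() if getattr(t, attr)}

    def to_json_dict(self) -> dict:
        out = {}
        for pid, t in self.proteins.items():
            d = asdict(t)
            d["enriched_in"] = sorted([list(e) for e in t.enriched_in])
            out[pid] = d
        return out


def _plant_roles(design: ExperimentDesign, params: QuantSimParams,
                 rng: np.random.Generator) -> dict[str, ProteinTruth]:
    """Assign each real protein a role and a planted enrichment pattern."""
    from .interactome import tier_from_counts  # shared tier rules

    dt = design.table
    # (run, bait_construct) pairs available for bait-specific enrichment
    pairs = []
    for (run, bait, construct), _ in dt.groupby(["run_id", "bait", "construct"],
                                                sort=False):
        if bait != CONTROL_BAIT:
            pairs.append((run, bait_construct_id(bait, construct)))
    pairs = list(dict.fromkeys(pairs))

    n = params.n_proteins
    pids = [f"P{i:05d}" for i in range(1, n + 1)]
    roles = np.array(["none"] * n, dtype=object)
    fractions = [
        ("core", params.frac_true_per_tier.get("core", 0.0)),
        ("wider", params.frac_true_per_tier.get("wider", 0.0)),
        ("widest", params.frac_true_per_tier.get("widest", 0.0)),
        ("gfp", params.frac_gfp),
        ("control", params.frac_control_enriched),
        ("substrate", params.frac_substrate),
    ]
    order = rng.permutation(n)
    pos = 0
    for role, frac in fractions:
        k = int(round(frac * n))
        roles[order[pos:pos + k]] = role
        pos += k

    n_hits = {"core": 5, "wider": 3, "widest": 2, "substrate": 1, "control": 2}
    truth: dict[str, ProteinTruth] = {}
    for pid, role in zip(pids, roles):
        t = ProteinTruth()
        if role in n_hits:
            k = min(n_hits[role], len(pairs))
            hit_idx = rng.choice(len(pairs), size=k, replace=False)
            effect = rng.uniform(*params.effect_log2_range)
            for i in hit_idx:
                run, bc = pairs[i]
                sub = dt[dt["run_id"] == run]
                sub = sub[[bait_construct_id(b, c) == bc
                           for b, c in zip(sub["bait"], sub["construct"])]]
                for (treat, tp), _ in sub.groupby(["treatment", "timepoint_h"],
                                                  sort=False):
                    is_control = treat in CONTROL_TREATMENTS
                    if is_control and role != "control":
                        continue
                    if role == "control" and not is_control:
                        continue
                    t.enriched_in.add((bc, treat, float(tp)))
            t.effect_log2 = effect
            t.substrate = role == "substrate"
            t.control_enriched = role == "control"
        elif role == "gfp":
            effect = rng.uniform(*params.effect_log2_range)
            sub = dt[dt["bait"] == CONTROL_BAIT]
            for (treat, tp), _ in sub.groupby(["treatment", "timepoint_h"],
                                              sort=False):
                t.enriched_in.add((CONTROL_BAIT, treat, float(tp)))
            t.effect_log2 = effect
            t.gfp_enriched = True
        # replication count implied by the planted pattern
        rep_pairs = set()
        for run, bc in pairs:
            sub = dt[dt["run_id"] == run]
            conds = {(bait_construct_id(b, c), tr, float(tp))
                     for b, c, tr, tp in zip(sub["bait"], sub["construct"],
                                             sub["treatment"],
                                             sub["timepoint_h"])}
            run_has_control_bait = (sub["bait"] == CONTROL_BAIT).any()
            for bc_e, tr, tp in t.enriched_in:
                if bc_e != bc or (bc_e, tr, tp) not in conds:
                    continue
                if run_has_control_bait:
                    rep_pairs.add((run, bc))
                elif tr not in CONTROL_TREATMENTS and \
                        (bc_e, _control_treatment(sub), tp) not in t.enriched_in:
                    rep_pairs.add((run, bc))
        count = len(rep_pairs)
        t.true_tier = tier_from_counts(
            count, ever_gfp=t.gfp_enriched,
            ever_control=t.control_enriched, substrate=t.substrate,
        )
        truth[pid] = t

    # annotation flags, independent of intensities
    true_set = [p for p, t in truth.items() if t.true_tier != "none"]
    for p in true_set:
        truth[p].known_interactor = bool(rng.random() < params.frac_known_of_true)
    for p, t in truth.items():
        eligible = t.true_tier in ("none", "widest")
        t.thylakoid = bool(eligible and rng.random() < params.frac_thylakoid)
        t.promiscuous = bool(rng.random() < params.frac_promiscuous)
    return truth


def _control_treatment(run_table: pd.DataFrame) -> str:
    for tr in run_table["treatment"].unique():
        if tr in CONTROL_TREATMENTS:
            return tr
    return ""


def generate_peptide_quant(
    design: ExperimentDesign,
    params: Optional[QuantSimParams] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a peptide-level quantification table for ``design``.

    Returns the table (columns ``peptide, protein, is_decoy,
    is_contaminant, n_ions`` plus one intensity column per sample; missing
    cells are NaN) and the :class:`GroundTruth`. Bit-reproducible for a
    given (design, params, seed).
    """
    params = params or QuantSimParams()
    params.validate()
    rng = np.random.default_rng(seed)
    samples = design.samples
    dt = design.table.set_index("sample_id")

    truth = _plant_roles(design, params, rng)
    pids = list(truth.keys())

    lo, hi = params.peptides_per_protein
    n_pep = rng.integers(lo, hi + 1, size=len(pids))
    single = rng.random(len(pids)) < params.frac_single_ion
    n_pep[single] = 1

    rows_protein, rows_peptide, rows_ions = [], [], []
    for pid, k, is_single in zip(pids, n_pep, single):
        for j in range(k):
            rows_protein.append(pid)
            rows_peptide.append(f"{pid}_pep{j + 1}")
            rows_ions.append(1 if is_single else int(rng.integers(1, 6)))
    n_rows = len(rows_protein)

    baseline = {p: rng.normal(params.baseline_mean, params.baseline_sd)
                for p in pids}
    pep_offset = rng.normal(0.0, params.peptide_sd, size=n_rows)

    # per-sample planted effect per protein
    cond_of_sample = {
        s: (bait_construct_id(dt.at[s, "bait"], dt.at[s, "construct"]),
            dt.at[s, "treatment"], float(dt.at[s, "timepoint_h"]))
        for s in samples
    }
    effect = np.zeros((n_rows, len(samples)))
    for i, pid in enumerate(rows_protein):
        t = truth[pid]
        if not t.enriched_in:
            continue
        for j, s in enumerate(samples):
            if cond_of_sample[s] in t.enriched_in:
                effect[i, j] = t.effect_log2

    base = np.array([baseline[p] for p in rows_protein])
    log2 = (base[:, None] + pep_offset[:, None] + effect
            + rng.normal(0.0, params.noise_sd, size=(n_rows, len(samples))))

    # decoy / contaminant rows: baseline-only intensities, no planted effects
    extra_rows = []
    for flag, frac, tag in [("is_decoy", params.frac_decoy, "rev_DECOY"),
                            ("is_contaminant", params.frac_contaminant, "CONT")]:
        k = int(round(frac * params.n_proteins))
        for i in range(1, k + 1):
            npp = int(rng.integers(1, 4))
            b = rng.normal(params.baseline_mean, params.baseline_sd)
            for j in range(1, npp + 1):
                extra_rows.append((f"{tag}_{i:04d}", f"{tag}_{i:04d}_pep{j}",
                                   flag, b + rng.normal(0, 1),
                                   int(rng.integers(1, 6))))
    extra_log2 = np.array(
        [[b + rng.normal(0.0, params.noise_sd) for _ in samples]
         for (_, _, _, b, _) in extra_rows]
    ).reshape(len(extra_rows), len(samples))

    all_protein = rows_protein + [r[0] for r in extra_rows]
    all_peptide = rows_peptide + [r[1] for r in extra_rows]
    all_decoy = [False] * n_rows + [r[2] == "is_decoy" for r in extra_rows]
    all_cont = [False] * n_rows + [r[2] == "is_contaminant" for r in extra_rows]
    all_ions = rows_ions + [r[4] for r in extra_rows]
    all_log2 = np.vstack([log2, extra_log2]) if extra_rows else log2

    # dropout: MNAR is a decreasing logistic in true log2 intensity
    if params.mnar_slope > 0 and np.isfinite(params.mnar_midpoint):
        p_mnar = expit(-params.mnar_slope * (all_log2 - params.mnar_midpoint))
    else:
        p_mnar = np.zeros_like(all_log2)
    mnar = rng.random(all_log2.shape) < p_mnar
    mar = (~mnar) & (rng.random(all_log2.shape) < params.mar_rate)

    intensities = np.exp2(all_log2)
    intensities[mnar | mar] = np.nan

    table = pd.DataFrame({
        "peptide": all_peptide,
        "protein": all_protein,
        "is_decoy": all_decoy,
        "is_contaminant": all_cont,
        "n_ions": all_ions,
    })
    for j, s in enumerate(samples):
        table[s] = intensities[:, j]

    idx = table["peptide"]
    gt = GroundTruth(
        proteins=truth,
        mnar_mask=pd.DataFrame(mnar, index=idx, columns=samples),
        mar_mask=pd.DataFrame(mar, index=idx, columns=samples),
        true_log2=pd.DataFrame(all_log2, index=idx, columns=samples),
    )
    return table, gt


@dataclass
class ReferenceSets:
    """External annotation lists used for benchmarking an interactome."""

    known: dict[str, float]          # protein -> evidence score in [0, 1]
    vanleene: set[str] = field(default_factory=set)
    thylakoid: set[str] = field(default_factory=set)
    promiscuous: set[str] = field(default_factory=set)


def generate_reference_sets(
    truth: GroundTruth, fpr: float = 0.0, fnr: float = 0.0, seed: int = 0,
) -> ReferenceSets:
    """Reference lists consistent with ``truth`` up to the stated error rates.

    The known-interactor list drops each true entry with probability ``fnr``
    and adds each non-interactor with probability ``fpr``; each entry gets
    an evidence score in [0, 1]. Thylakoid and promiscuous lists mirror the
    planted flags exactly.
    """
    if not (0.0 <= fpr < 1.0 and 0.0 <= fnr < 1.0):
        raise ValueError("fpr and fnr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    known: dict[str, float] = {}
    for pid, t in sorted(truth.proteins.items()):
        if t.known_interactor:
            if rng.random() >= fnr:
                known[pid] = float(rng.uniform(0.3, 1.0))
        elif fpr > 0 and rng.random() < fpr:
            known[pid] = float(rng.uniform(0.0, 1.0))
    return ReferenceSets(
        known=known,
        vanleene=set(rng.choice(sorted(known), size=len(known) // 3,
                                replace=False)) if len(known) >= 3 else set(),
        thylakoid=truth.flagged("thylakoid"),
        promiscuous=truth.flagged("promiscuous"),
    )
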