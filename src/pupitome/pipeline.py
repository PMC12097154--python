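"""Configuration-driven orchestration of the full analysis.

A :class:`PipelineConfig` collects every tunable constant of the method
in one auditable place — imputation factors, tier thresholds, structural
cutoffs, motif settings — with defaults equal to the published analysis
parameters. :func:`run_pipeline` executes the stages in order
(preprocess -> enrichment -> tally/tiers -> structure profiles ->
phospho -> report); every artifact carries the config hash and seed, and
the run log records row counts after each filter.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import enrichment, interactome, io, phospho, preprocess, surface
from .design import CONTROL_BAIT, ExperimentDesign, torc_study_design
from .interactome import TierThresholds, tier_sets
from .simulate import QuantSimParams, generate_peptide_quant, \
    generate_reference_sets
from .toystructures import ToyStructureSpec, generate_toy_structures

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

log = logging.getLogger("pupitome")


@dataclass
class PipelineConfig:
    """All pipeline constants; defaults are the published analysis values."""

    # paths (None + synthetic=True generates inputs)
    peptide_table: Optional[str] = None
    design: Optional[str] = None
    references: Optional[str] = None
    structures_dir: Optional[str] = None
    phospho_table: Optional[str] = None
    lis_table: Optional[str] = None
    out_dir: str = "pupitome_out"
    synthetic: bool = True

    # differential enrichment
    alpha: float = 0.05
    control_bait: str = CONTROL_BAIT
    mar_factor: float = 0.95
    sd_mnar: float = 0.05
    low_quantile: float = 0.005
    # interactome
    tier_widest: int = 2
    tier_wider: int = 3
    tier_core: int = 5
    evidence_threshold: float = 0.25
    k_modules: int = 6
    coexpression_percentile: float = 99.0
    # structure
    rsa_cut: float = 0.7
    depth_cut_angstrom: float = 3.6
    disorder_window: int = 25
    # phospho
    loc_prob_threshold: float = 0.75
    substrate_fold_cut: float = 30.0

    seed: int = 0

    def tier_thresholds(self) -> TierThresholds:
        return TierThresholds(self.tier_widest, self.tier_wider,
                              self.tier_core)

    _PATH_FIELDS = ("peptide_table", "design", "references",
                    "structures_dir", "phospho_table", "lis_table",
                    "out_dir")

    def hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, seed included)."""
        d = {k: v for k, v in asdict(self).items()
             if k not in self._PATH_FIELDS}
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report dict and writes artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler)
               and h.stream is sys.stderr for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))
    cfg_hash = config.hash()
    log.info("config hash %s seed %d", cfg_hash, config.seed)
    config.to_json(out / "config.json")

    try:
        # ---------------------------------------------------------- inputs
        _stage("inputs")
        truth = None
        if config.synthetic:
            design = torc_study_design()
            table, truth = generate_peptide_quant(
                design, QuantSimParams(), seed=config.seed)
            refs = generate_reference_sets(truth, seed=config.seed + 1)
            phospho_sites = phospho.generate_phospho_table(
                design, seed=config.seed + 2)
            design.to_tsv(out / "design.tsv")
            io.write_peptide_table(table, out / "peptides.tsv")
            io.write_reference_sets(refs, out / "references.tsv")
            io.write_ground_truth(truth, out / "ground_truth.json")
            struct_dir = out / "structures"
            generate_toy_structures(
                [ToyStructureSpec("globule", 76, [1, 70, 74], "globule",
                                   tail_res=12),
                 ToyStructureSpec("extended", 40, [10, 20, 30], "extended")],
                struct_dir, seed=config.seed + 3)
        else:
            design = ExperimentDesign.from_tsv(_require(config.design,
                                                        "design"))
            table = io.read_peptide_table(_require(config.peptide_table,
                                                   "peptide_table"))
            refs = io.read_reference_sets(_require(config.references,
                                                   "references"))
            phospho_sites = (pd.read_csv(config.phospho_table, sep="\t")
                             if config.phospho_table else None)
            struct_dir = (Path(config.structures_dir)
                          if config.structures_dir else None)
        log.info("peptide table: %d rows, %d samples", len(table),
                 len(design.samples))

        # ------------------------------------------------------ preprocess
        _stage("preprocess")
        filtered = preprocess.filter_peptides(table, design)
        log.info("after filtering: %d rows", len(filtered))
        tm = preprocess.transform_and_center(filtered, design,
                                             config.low_quantile)
        mask = preprocess.classify_missingness(tm, design)
        complete = preprocess.impute_missing(
            tm, mask, design, config.sd_mnar, config.mar_factor,
            seed=config.seed + 4)
        io.write_mask(mask, filtered["peptide"], out / "missingness.tsv")
        complete.data.to_csv(out / "matrix.tsv", sep="\t", index=False)

        # ------------------------------------------------------ enrichment
        _stage("enrichment")
        prot = enrichment.aggregate_proteins(complete)
        log.info("proteins quantified: %d", len(prot))
        calls = enrichment.run_differential_enrichment(
            prot, design, config.control_bait, config.alpha)
        calls.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        log.info("contrasts: %d, enriched calls: %d",
                 calls["contrast"].nunique() if len(calls) else 0,
                 int(calls["enriched"].sum()) if len(calls) else 0)

        # --------------------------------------------------------- phospho
        _stage("phospho")
        substrates: set = set()
        motif_folds = {}
        if phospho_sites is not None and len(phospho_sites):
            localized = phospho.filter_localized(phospho_sites,
                                                 config.loc_prob_threshold)
            log.info("phosphosites: %d localized of %d", len(localized),
                     len(phospho_sites))
            fg = localized[localized[[c for c in localized.columns
                                      if c.startswith("q_")]].lt(
                config.alpha).all(axis=1)]
            bg = localized.drop(fg.index)
            if len(fg) and len(bg):
                for motif in (phospho.SP, phospho.RXXS, phospho.SXXP):
                    motif_folds[motif.name] = phospho.motif_fold_enrichment(
                        list(fg["window"]), list(bg["window"]), motif)
            substrates = phospho.flag_substrates(
                localized, fold_cut=config.substrate_fold_cut,
                alpha=config.alpha)

        # ----------------------------------------------------- interactome
        _stage("interactome")
        tally = interactome.tally_replication(calls, design,
                                              config.control_bait,
                                              alpha=config.alpha)
        tiers = interactome.assign_tiers(tally, substrates,
                                         config.tier_thresholds())
        robustness = interactome.interaction_robustness(
            calls[calls["varying_factor"] == "bait"])
        tiers["robustness"] = tiers["protein"].map(robustness).fillna(0.0)
        tiers.to_csv(out / "interactome.tsv", sep="\t", index=False)

        fc = calls[(calls["varying_factor"] == "bait")
                   | (~calls["run_id"].isin(
                       {r for r in design.runs
                        if (design.table.loc[design.table["run_id"] == r,
                                             "bait"]
                            == config.control_bait).any()}))]
        fc_matrix = fc.pivot_table(index="protein", columns="contrast",
                                   values="log2fc")
        modules = None
        if len(fc_matrix) >= config.k_modules:
            row_mod, col_mod = interactome.cluster_modules(
                fc_matrix, config.k_modules)
            modules = row_mod
            row_mod.rename("module").to_csv(out / "modules.tsv", sep="\t")

        # ------------------------------------------------------- structure
        _stage("structure")
        structure_summary = {}
        if struct_dir is not None and Path(struct_dir).exists():
            profiles = []
            for p in sorted(Path(struct_dir).glob("*.pdb")) + \
                    sorted(Path(struct_dir).glob("*.cif")):
                model = surface.read_structure(p, name=p.stem)
                prof = surface.residue_profile(
                    model, rsa_cut=config.rsa_cut,
                    depth_cut=config.depth_cut_angstrom,
                    window=config.disorder_window)
                prof.insert(0, "protein", p.stem)
                profiles.append(prof)
                n_surf, n_acc, _ = surface.accessible_lysines(
                    prof, config.rsa_cut, config.depth_cut_angstrom)
                structure_summary[p.stem] = {
                    "n_surface_lys": n_surf, "n_accessible_lys": n_acc,
                    "median_accessible_lys_disorder":
                        surface.median_accessible_lys_disorder(prof),
                }
            if profiles:
                pd.concat(profiles).to_csv(out / "residue_profiles.tsv",
                                           sep="\t", index=False)

        # ---------------------------------------------------------- report
        _stage("report")
        report = write_report(
            tiers, refs, universe_size=prot.shape[0],
            substrates=substrates, motif_folds=motif_folds,
            modules=modules, structure_summary=structure_summary,
            config_hash=cfg_hash, seed=config.seed,
            evidence_threshold=config.evidence_threshold,
        )
        (out / "report.json").write_text(json.dumps(report, indent=1))
        return report
    except Exception as err:
        log.error("pipeline aborted: %s", err)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _require(value, name):
    if value is None or not Path(value).exists():
        raise FileNotFoundError(f"stage 'inputs': missing {name} file: "
                                f"{value}")
    return value


def write_report(tiers: pd.DataFrame, refs, universe_size: int,
                 substrates: set = frozenset(), motif_folds: dict = None,
                 modules=None, structure_summary: dict = None,
                 config_hash: str = "", seed: int = 0,
                 evidence_threshold: float = 0.25) -> dict:
    """Machine-readable benchmarking summary (the stringency-table schema).

    Per tier: total interactors, reference overlaps, thylakoid count and
    the high:low confidence ratio; plus module assignments, substrate
    flags and structure summaries.
    """
    known = interactome.filter_reference_evidence(refs.known,
                                                  evidence_threshold)
    sets = tier_sets(tiers) if len(tiers) else {
        "core": set(), "wider": set(), "widest": set()}
    per_tier = {}
    for tier in ("widest", "wider", "core"):
        s = sets[tier]
        high, low, ratio = interactome.benchmark_ratio(
            s, refs) if s else (0, 0, float("nan"))
        p = interactome.overlap_significance(
            s, known | set(refs.vanleene), universe_size) if s else 1.0
        per_tier[tier] = {
            "total_interactors": len(s),
            "known_overlap": len(s & known),
            "vanleene_overlap": len(s & set(refs.vanleene)),
            "thylakoid": len(s & set(refs.thylakoid)),
            "high_confidence": high,
            "low_confidence": low,
            "high_low_ratio": None if not s or low == 0 else ratio,
            "ratio_flagged_infinite": bool(s) and low == 0,
            "overlap_p": p,
        }
    return {
        "config_hash": config_hash,
        "seed": seed,
        "universe_size": universe_size,
        "tiers": per_tier,
        "substrates": sorted(substrates),
        "motif_fold_enrichment": motif_folds or {},
        "modules": ({} if modules is None
                    else {str(k): int(v) for k, v in modules.items()}),
        "structures": structure_summary or {},
    }
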