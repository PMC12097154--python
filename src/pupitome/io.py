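"""Readers and writers for the pipeline's tab-separated dialects.

Peptide tables follow the FragPipe combined-peptide layout used
throughout: metadata columns ``peptide, protein, is_decoy,
is_contaminant, n_ions`` followed by one intensity column per sample;
missing cells are empty fields, never 0.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import GroundTruth, ProteinTruth, ReferenceSets

__all__ = ["read_peptide_table", "write_peptide_table", "write_mask",
           "read_reference_sets", "write_reference_sets",
           "write_ground_truth", "read_ground_truth"]


def read_peptide_table(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    for col in ("is_decoy", "is_contaminant"):
        t[col] = t[col].astype(bool)
    return t


def write_peptide_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_mask(mask: pd.DataFrame, peptides: pd.Series, path) -> None:
    """Long-format sidecar: peptide, sample, class — missing cells only."""
    long = mask.set_axis(peptides, axis=0).stack().rename("class")
    long.index.names = ["peptide", "sample"]
    long.reset_index().to_csv(path, sep="\t", index=False)


def write_reference_sets(refs: ReferenceSets, path) -> None:
    rows = [{"protein": p, "set": "known", "score": s}
            for p, s in sorted(refs.known.items())]
    for name in ("vanleene", "thylakoid", "promiscuous"):
        rows += [{"protein": p, "set": name, "score": ""}
                 for p in sorted(getattr(refs, name))]
    pd.DataFrame(rows, columns=["protein", "set", "score"]).to_csv(
        path, sep="\t", index=False)


def read_reference_sets(path) -> ReferenceSets:
    t = pd.read_csv(path, sep="\t")
    known = {r.protein: float(r.score)
             for r in t[t["set"] == "known"].itertuples()}
    sets = {name: set(t.loc[t["set"] == name, "protein"])
            for name in ("vanleene", "thylakoid", "promiscuous")}
    return ReferenceSets(known=known, **sets)


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=1))


def read_ground_truth(path) -> GroundTruth:
    raw = json.loads(Path(path).read_text())
    proteins = {}
    for pid, d in raw.items():
        d = dict(d)
        d["enriched_in"] = {(e[0], e[1], float(e[2]))
                            for e in d["enriched_in"]}
        proteins[pid] = ProteinTruth(**d)
    return GroundTruth(proteins=proteins)
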