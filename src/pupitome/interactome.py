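"""Replication-tiered interactome construction and benchmarking.

Integrates per-contrast enrichment calls across runs and bait constructs
into a single interactor table: a replication count (distinct
run x bait-construct pairs with enrichment over the control), flags for
unspecific (control-bait) and control-treatment enrichment, and a tier
assignment (widest / wider / core) of increasing stringency. Also houses
the benchmarking helpers (high:low confidence ratio, hypergeometric
overlap), 2D Ward clustering into response modules, cumulative
log-fold-change robustness scores, promiscuous-bait filtering and
coexpression community detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom

from .design import CONTROL_BAIT, CONTROL_TREATMENTS, ExperimentDesign

__all__ = [
    "TierThresholds", "tally_replication", "assign_tiers", "tier_from_counts",
    "benchmark_ratio", "overlap_significance", "filter_reference_evidence",
    "filter_promiscuous", "cluster_modules", "interaction_robustness",
    "coexpression_communities",
]

TIER_ORDER = ["core", "wider", "widest", "none"]


@dataclass(frozen=True)
class TierThresholds:
    """Minimum replication counts per tier (widest / wider / core)."""

    widest: int = 2
    wider: int = 3
    core: int = 5


def tier_from_counts(
    count: int,
    ever_gfp: bool,
    ever_control: bool,
    substrate: bool = False,
    thresholds: TierThresholds = TierThresholds(),
    treatment_filter: bool = True,
    substrate_clause: bool = True,
) -> str:
    """Tier of a single protein from its replication count and flags.

    core: enriched with >= ``thresholds.core`` bait constructs and never
    with the control bait, or flagged as a putative kinase substrate;
    wider: >= ``thresholds.wider`` and never with the control bait;
    widest: >= ``thresholds.widest`` (no unspecificity filter). The
    treatment filter removes control-condition-enriched proteins from
    wider and core (not widest).
    """
    blocked = treatment_filter and ever_control
    if substrate_clause and substrate:
        return "core"
    if count >= thresholds.core and not ever_gfp and not blocked:
        return "core"
    if count >= thresholds.wider and not ever_gfp and not blocked:
        return "wider"
    if count >= thresholds.widest:
        return "widest"
    return "none"


def tally_replication(
    calls: pd.DataFrame,
    design: ExperimentDesign,
    control_bait: str = CONTROL_BAIT,
    control_treatments: Iterable[str] = CONTROL_TREATMENTS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein replication counts and filter flags from enrichment calls.

    ``calls`` is the long-format contrast table produced by
    :func:`pupitome.enrichment.run_differential_enrichment` (one row per
    protein x contrast with factor metadata, ``log2fc``, ``q``,
    ``enriched``).

    A *biological replication* is an independent (run, bait construct)
    sample finding the interaction: a protein enriched in run 1 with both
    LST8 and RAPTOR baits and in run 2 with LST8 counts as thrice
    replicated. Enrichment over control means a bait-vs-control-bait
    contrast, or — in runs without the control bait — a
    treatment-vs-control-treatment contrast.
    """
    control_treatments = set(control_treatments)
    runs_with_control = {
        run for run in design.runs
        if (design.table.loc[design.table["run_id"] == run, "bait"]
            == control_bait).any()
    }

    c = calls
    sig_pos = (c["q"] < alpha) & (c["log2fc"] > 0)
    sig_neg = (c["q"] < alpha) & (c["log2fc"] < 0)

    vs_control_a = (
        (c["varying_factor"] == "bait") & (c["bait_b"] == control_bait)
    ) | (
        (c["varying_factor"] == "treatment")
        & c["treatment_b"].isin(control_treatments)
        & (c["bait_a"] != control_bait)
        & ~c["run_id"].isin(runs_with_control)
    )

    out: dict[str, dict] = {}

    def rec(pid: str) -> dict:
        return out.setdefault(pid, {
            "protein": pid, "rep_pairs": set(), "bait_constructs_hit": set(),
            "ever_gfp_enriched": False, "ever_control_enriched": False,
        })

    for row, pos, neg, vs_ctrl in zip(c.itertuples(index=False), sig_pos,
                                      sig_neg, vs_control_a):
        if not (pos or neg):
            continue
        # the favored side of the comparison
        if pos:
            bait, bc = row.bait_a, row.bait_construct_a
            treatment = row.treatment_a
        else:
            bait, bc = row.bait_b, row.bait_construct_b
            treatment = row.treatment_b
        r = rec(row.protein)
        if bait == control_bait:
            r["ever_gfp_enriched"] = True
            continue
        if treatment in control_treatments:
            r["ever_control_enriched"] = True
        if pos and vs_ctrl:
            r["rep_pairs"].add((row.run_id, bc))
            r["bait_constructs_hit"].add(bc)

    records = []
    for pid in sorted(out):
        r = out[pid]
        records.append({
            "protein": pid,
            "replication_count": len(r["rep_pairs"]),
            "bait_constructs_hit": frozenset(r["bait_constructs_hit"]),
            "ever_gfp_enriched": r["ever_gfp_enriched"],
            "ever_control_enriched": r["ever_control_enriched"],
        })
    cols = ["protein", "replication_count", "bait_constructs_hit",
            "ever_gfp_enriched", "ever_control_enriched"]
    return pd.DataFrame(records, columns=cols)


def assign_tiers(
    tally: pd.DataFrame,
    substrates: Optional[set] = None,
    thresholds: TierThresholds = TierThresholds(),
    treatment_filter: bool = True,
    substrate_clause: bool = True,
) -> pd.DataFrame:
    """Add ``substrate`` and ``tier`` columns to a replication tally."""
    substrates = substrates or set()
    t = tally.copy()
    t["substrate"] = t["protein"].isin(substrates)
    t["tier"] = [
        tier_from_counts(c, g, ctl, s, thresholds, treatment_filter,
                         substrate_clause)
        for c, g, ctl, s in zip(t["replication_count"], t["ever_gfp_enriched"],
                                t["ever_control_enriched"], t["substrate"])
    ]
    return t


def tier_sets(tiers: pd.DataFrame, nested: bool = True) -> dict[str, set]:
    """Protein sets per tier; ``nested`` includes higher tiers in lower ones."""
    exact = {tier: set(tiers.loc[tiers["tier"] == tier, "protein"])
             for tier in ("core", "wider", "widest")}
    if not nested:
        return exact
    return {
        "core": exact["core"],
        "wider": exact["core"] | exact["wider"],
        "widest": exact["core"] | exact["wider"] | exact["widest"],
    }


def benchmark_ratio(
    tier_set: set, refs, count_substrate_rescues: bool = True,
) -> tuple[int, int, float]:
    """(high, low, ratio): previously reported vs thylakoid-predicted hits.

    Previously reported interactions (the known list plus the independent
    Van Leene set) are high-confidence; thylakoid-predicted proteins,
    unlikely to contact a cytosolic kinase complex, are low-confidence.
    Their ratio is a rough signal-to-noise proxy. A zero low count yields
    ``inf`` (flagged by the caller via ``math.isinf``), not an exception.
    """
    del count_substrate_rescues
    if not tier_set:
        return 0, 0, float("nan")
    known = set(refs.known) | set(refs.vanleene)
    high = len(tier_set & known)
    low = len(tier_set & set(refs.thylakoid))
    ratio = high / low if low else (inf if high else float("nan"))
    return high, low, ratio


def overlap_significance(set_a: set, set_b: set, universe_size: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= |a & b|).

    Population ``universe_size``, ``|set_b|`` successes, ``|set_a|`` draws.
    """
    if len(set_a) > universe_size or len(set_b) > universe_size:
        raise ValueError("set larger than universe")
    k = len(set_a & set_b)
    return float(hypergeom.sf(k - 1, universe_size, len(set_b), len(set_a)))


def filter_reference_evidence(known: dict, threshold: float = 0.25) -> set:
    """Entries with evidence score strictly above ``threshold``."""
    return {p for p, s in known.items() if s > threshold}


def filter_promiscuous(tier_set: set, promiscuous: set) -> tuple[set, set]:
    """Partition ``tier_set`` into bait-specific and promiscuous interactors."""
    prom = tier_set & set(promiscuous)
    return tier_set - prom, prom


def cluster_modules(
    fc_matrix: pd.DataFrame, k: int = 6, col_k: Optional[int] = None,
) -> tuple[pd.Series, pd.Series]:
    """2D hierarchical clustering of a protein x condition log2fc matrix.

    Proteins undetected in a run are imputed as unchanged (0); rows and
    columns are clustered independently with Ward's minimum-variance
    linkage on Euclidean distances and cut into ``k`` (rows) and
    ``col_k`` (columns, default min(k, n_cols)) modules. Deterministic.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > fc_matrix.shape[0]:
        raise ValueError(f"k={k} exceeds number of proteins {fc_matrix.shape[0]}")
    x = fc_matrix.fillna(0.0).to_numpy(dtype=float)
    row_labels = fcluster(linkage(x, method="ward"), t=k, criterion="maxclust")
    col_k = col_k or min(k, x.shape[1])
    if x.shape[1] >= 2 and col_k >= 2:
        col_labels = fcluster(linkage(x.T, method="ward"), t=col_k,
                              criterion="maxclust")
    else:
        col_labels = np.ones(x.shape[1], dtype=int)
    return (pd.Series(row_labels, index=fc_matrix.index, name="module"),
            pd.Series(col_labels, index=fc_matrix.columns, name="module"))


def interaction_robustness(calls: pd.DataFrame) -> pd.Series:
    """Cumulative enriched log2 fold change vs control, per protein.

    The robustness of an interaction is the sum of the observed log2 fold
    enrichment over the control across all bait-vs-control comparisons in
    which the protein was called enriched. Proteins with no enriched call
    score 0 (absent from the result).
    """
    if calls.empty:
        return pd.Series(dtype=float, name="robustness")
    sel = calls[calls["enriched"].astype(bool)]
    s = sel.groupby("protein")["log2fc"].sum()
    s.name = "robustness"
    return s


def coexpression_communities(
    edges: Sequence[tuple], percentile: float = 99.0,
) -> dict[str, int]:
    """Communities of a coexpression network filtered to its strongest edges.

    Edge strengths are standardized to unit variance across the whole
    network, edges below the ``percentile`` of standardized strength are
    removed, and communities are found by greedy modularity maximization.
    Singleton nodes are dropped. Returns node -> community label.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    strengths = np.array([e[2] for e in edges], dtype=float)
    if not np.all(np.isfinite(strengths)):
        raise ValueError("edge strengths must be finite")
    sd = strengths.std(ddof=1) if len(strengths) > 1 else 0.0
    if sd == 0:
        raise ValueError("edge strengths have zero variance")
    z = strengths / sd
    cut = np.percentile(z, percentile)
    g = nx.Graph()
    for (a, b, _), w in zip(edges, z):
        if w >= cut:
            g.add_edge(a, b, weight=w)
    labels: dict[str, int] = {}
    communities = nx.community.greedy_modularity_communities(g, weight="weight")
    lab = 0
    for comm in communities:
        if len(comm) < 2:
            continue
        lab += 1
        for node in sorted(comm):
            labels[node] = lab
    return labels
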