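"""Phosphosite filtering, sequence windows and motif fold enrichment.

Sites are filtered for unambiguous localization, an 11-residue window is
built around each phospho-acceptor, and declared kinase-motif patterns
are counted in foreground (bait-enriched) versus background windows with
a Jeffreys-style pseudocount. Sites enriched beyond a fold threshold in
every required bait are flagged as putative direct kinase substrates and
feed the substrate clause of the interactome tiers.

The proline-directed "SP" motif places P immediately after the
phospho-acceptor; "RxxS" places R three positions before it. The basic
"SxxP" variant (P three positions after) ships as well, since both
spellings appear in the TOR-substrate literature for the same site sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["MotifPattern", "SP", "RXXS", "SXXP", "filter_localized",
           "extract_window", "motif_fold_enrichment", "flag_substrates",
           "PhosphoSimParams", "generate_phospho_table"]

PAD = "_"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifPattern:
    """Positional pattern over an 11-mer, positions -5..+5 around the site."""

    name: str
    positions: dict = field(default_factory=dict)   # offset -> allowed chars

    def __post_init__(self) -> None:
        for off in self.positions:
            if not -5 <= off <= 5:
                raise ValueError(f"offset {off} outside -5..+5")

    def matches(self, window: str) -> bool:
        if len(window) != 11:
            raise ValueError("window must be an 11-mer")
        center = 5
        for off, allowed in self.positions.items():
            ch = window[center + off]
            if ch == PAD or ch not in allowed:
                return False
        return True


#: proline-directed TOR-associated motif: phospho-S/T followed by P
SP = MotifPattern("SP", {0: "ST", 1: "P"})
#: basophilic motif of the downstream kinase: R three before the site
RXXS = MotifPattern("RxxS", {-3: "R", 0: "ST"})
#: prose variant of the second motif: P three after the site
SXXP = MotifPattern("SxxP", {0: "ST", 3: "P"})


def filter_localized(sites: pd.DataFrame,
                     threshold: float = 0.75) -> pd.DataFrame:
    """Keep sites with localization probability >= ``threshold``."""
    return sites[sites["loc_prob"] >= threshold]


def extract_window(sequence: str, position: int, width: int = 11) -> str:
    """``width``-mer centered on ``position`` (1-based), padded with '_'."""
    if width % 2 == 0:
        raise ValueError("width must be odd")
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence of length "
                         f"{len(sequence)}")
    half = width // 2
    i = position - 1
    left = sequence[max(0, i - half):i]
    right = sequence[i + 1:i + 1 + half]
    return (PAD * (half - len(left)) + left + sequence[i]
            + right + PAD * (half - len(right)))


def motif_fold_enrichment(fg_windows: Sequence[str],
                          bg_windows: Sequence[str],
                          motif: MotifPattern,
                          pseudocount: float = 0.5) -> float:
    """Foreground-over-background motif frequency ratio.

    fold = [(fg hits + c) / (|fg| + 2c)] / [(bg hits + c) / (|bg| + 2c)]
    with pseudocount c, finite for all inputs and converging to the raw
    frequency ratio for large samples.
    """
    if len(fg_windows) == 0:
        raise ValueError("empty foreground")
    if len(bg_windows) == 0:
        raise ValueError("empty background")
    c = pseudocount
    fg_hits = sum(motif.matches(w) for w in fg_windows)
    bg_hits = sum(motif.matches(w) for w in bg_windows)
    fg_rate = (fg_hits + c) / (len(fg_windows) + 2 * c)
    bg_rate = (bg_hits + c) / (len(bg_windows) + 2 * c)
    return fg_rate / bg_rate


def flag_substrates(sites: pd.DataFrame,
                    baits_required: Iterable[str] = ("LST8", "RAPTOR"),
                    fold_cut: float = 30.0,
                    alpha: float = 0.05) -> set[str]:
    """Proteins with a site enriched > ``fold_cut``-fold in every bait.

    Expects per-bait columns ``log2fc_<bait>`` and ``q_<bait>``. A site
    qualifies when log2fc exceeds log2(fold_cut) with q < alpha in each
    required bait; the protein set feeds the core-tier substrate clause.
    """
    lfc_cut = np.log2(fold_cut)
    keep = pd.Series(True, index=sites.index)
    for bait in baits_required:
        keep &= (sites[f"log2fc_{bait}"] > lfc_cut) \
            & (sites[f"q_{bait}"] < alpha)
    return set(sites.loc[keep, "protein"])


# ------------------------------------------------------------------ synthetic

@dataclass
class PhosphoSimParams:
    """Phosphosite generator settings; defaults are the study conditions.

    ``frac_sp`` / ``frac_rxxs`` give (foreground, background) motif
    frequencies: the planted fold enrichment is their ratio.
    """

    n_sites: int = 500
    frac_sp: tuple[float, float] = (0.5, 0.1)
    frac_rxxs: tuple[float, float] = (0.3, 0.06)
    frac_enriched: float = 0.2
    effect_log2: float = 6.0
    loc_prob_range: tuple[float, float] = (0.7, 1.0)
    baits: tuple[str, ...] = ("LST8", "RAPTOR")

    def validate(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        for pair in (self.frac_sp, self.frac_rxxs):
            if not all(0.0 <= f <= 1.0 for f in pair):
                raise ValueError("motif fractions must lie in [0, 1]")
        if not 0.0 <= self.frac_enriched <= 1.0:
            raise ValueError("frac_enriched must lie in [0, 1]")


def _random_window(rng: np.random.Generator, plant_sp: bool,
                   plant_rxxs: bool) -> str:
    chars = list(rng.choice(list(AMINO_ACIDS), size=11))
    chars[5] = "S" if rng.random() < 0.8 else "T"
    # +1 is P exactly when SP is planted; -3 is R exactly when RxxS is
    # planted, so planted fractions are the true motif frequencies
    if plant_sp:
        chars[6] = "P"
    elif chars[6] == "P":
        chars[6] = "A"
    if plant_rxxs:
        chars[2] = "R"
    elif chars[2] == "R":
        chars[2] = "G"
    return "".join(chars)


def generate_phospho_table(design=None, params: Optional[PhosphoSimParams] = None,
                           seed: int = 0) -> pd.DataFrame:
    """Synthetic phosphosite table with planted motif enrichment.

    Enriched sites carry the SP / RxxS contexts at the foreground
    frequencies and a planted per-bait log2 fold change; background sites
    carry background frequencies and null fold changes. ``design`` is
    accepted for interface symmetry (the per-bait columns are derived
    from ``params.baits``).
    """
    del design
    params = params or PhosphoSimParams()
    params.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(params.n_sites):
        enriched = rng.random() < params.frac_enriched
        f_sp = params.frac_sp[0] if enriched else params.frac_sp[1]
        f_rx = params.frac_rxxs[0] if enriched else params.frac_rxxs[1]
        window = _random_window(rng, rng.random() < f_sp,
                                rng.random() < f_rx)
        row = {
            "protein": f"PP{i // 3 + 1:04d}",
            "position": int(rng.integers(6, 400)),
            "residue": window[5],
            "loc_prob": float(rng.uniform(*params.loc_prob_range)),
            "window": window,
            "enriched_truth": enriched,
        }
        for bait in params.baits:
            if enriched:
                row[f"log2fc_{bait}"] = params.effect_log2 + rng.normal(0, 0.3)
                row[f"q_{bait}"] = float(rng.uniform(1e-6, 0.01))
            else:
                row[f"log2fc_{bait}"] = rng.normal(0, 0.5)
                row[f"q_{bait}"] = float(rng.uniform(0.05, 1.0))
        rows.append(row)
    cols = ["protein", "position", "residue", "loc_prob", "window",
            "enriched_truth"] + [f"{k}_{b}" for b in params.baits
                                 for k in ("log2fc", "q")]
    return pd.DataFrame(rows, columns=cols)
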