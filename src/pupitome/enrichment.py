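"""Protein-level differential enrichment with moderated statistics.

Peptide profiles are aggregated to protein level by Tukey median polish
(robust to single outlying peptide cells), contrasts are enumerated as
all within-run triplicate pairs differing in exactly one design factor,
and per-protein two-sample statistics are moderated by empirical-Bayes
variance shrinkage in the style of limma: per-protein sample variances
are squeezed toward a scaled inverse-chi-square prior whose degrees of
freedom and scale are estimated from the variance distribution across
proteins, and the t-statistic uses the posterior variance with augmented
degrees of freedom. p-values are BH-adjusted within each contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .design import (
    CONTROL_BAIT,
    CONTROL_TREATMENTS,
    ExperimentDesign,
    bait_construct_id,
)

__all__ = ["Contrast", "median_polish", "aggregate_proteins",
           "enumerate_contrasts", "test_contrast", "adjust_and_call",
           "run_differential_enrichment", "squeeze_variances"]


# ---------------------------------------------------------------- aggregation

def median_polish(x: np.ndarray, max_iter: int = 50,
                  tol: float = 1e-8) -> tuple[float, np.ndarray, np.ndarray,
                                              np.ndarray]:
    """Tukey median polish of a 2D array.

    Returns (overall, row_effects, col_effects, residuals) with
    x ~= overall + row[:, None] + col[None, :] + residuals.
    """
    r = np.array(x, dtype=float)
    overall = 0.0
    row = np.zeros(r.shape[0])
    col = np.zeros(r.shape[1])
    prev = np.inf
    for _ in range(max_iter):
        rmed = np.median(r, axis=1)
        row += rmed
        r -= rmed[:, None]
        cmed = np.median(row)
        overall += cmed
        row -= cmed
        ccol = np.median(r, axis=0)
        col += ccol
        r -= ccol[None, :]
        rmed2 = np.median(col)
        overall += rmed2
        col -= rmed2
        total = np.abs(r).sum()
        if abs(prev - total) <= tol * max(total, 1.0):
            break
        prev = total
    return overall, row, col, r


def aggregate_proteins(matrix) -> pd.DataFrame:
    """Protein x sample summaries of the complete peptide matrix.

    Each protein's peptide block is median-polished; the protein profile
    is the overall effect plus the per-sample column effects, so a
    constant offset between peptides is absorbed into row effects.
    Single-peptide proteins pass through unchanged.
    """
    data, samples = matrix.data, matrix.samples
    profiles = {}
    for pid, block in data.groupby("protein", sort=False):
        x = block[samples].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"protein {pid!r} has missing values; "
                             "aggregate after imputation")
        if x.shape[0] == 1:
            profiles[pid] = x[0]
        else:
            overall, _, col, _ = median_polish(x)
            profiles[pid] = overall + col
    return pd.DataFrame.from_dict(profiles, orient="index", columns=samples)


# ------------------------------------------------------------------ contrasts

@dataclass(frozen=True)
class Contrast:
    """A pair of same-run triplicates differing in exactly one factor."""

    run_id: str
    varying_factor: str                      # bait | treatment | timepoint
    key_a: tuple                             # (bait, construct, treatment, tp)
    key_b: tuple
    samples_a: tuple[str, ...]
    samples_b: tuple[str, ...]

    @property
    def label(self) -> str:
        fa = "{}/{}.{}.{:g}h".format(*self.key_a)
        fb = "{}/{}.{}.{:g}h".format(*self.key_b)
        return f"{self.run_id}:{fa}-vs-{fb}"

    def reversed(self) -> "Contrast":
        return Contrast(self.run_id, self.varying_factor, self.key_b,
                        self.key_a, self.samples_b, self.samples_a)


def enumerate_contrasts(design: ExperimentDesign,
                        control_bait: str = CONTROL_BAIT,
                        control_treatments=CONTROL_TREATMENTS) -> list[Contrast]:
    """All within-run triplicate pairs varying in exactly one factor.

    No comparisons are made across MS runs. Orientation: bait contrasts
    are bait-minus-control-bait, treatment contrasts are
    treatment-minus-control-treatment (e.g. sucrose-mannitol,
    rapamycin-none), timepoint contrasts later-minus-earlier; remaining
    ties are ordered lexicographically.
    """
    control_treatments = set(control_treatments)
    out: list[Contrast] = []
    for run in design.runs:
        trips = [(key, samples) for key, samples in design.triplicates()
                 if key[0] == run]
        for i in range(len(trips)):
            for j in range(i + 1, len(trips)):
                (k1, s1), (k2, s2) = trips[i], trips[j]
                a1, a2 = k1[1:], k2[1:]          # (bait, construct, treat, tp)
                diff = [(a1[0], a1[1]) != (a2[0], a2[1]),
                        a1[2] != a2[2], a1[3] != a2[3]]
                if sum(diff) != 1:
                    continue
                factor = ("bait", "treatment", "timepoint")[diff.index(True)]
                swap = False
                if factor == "bait":
                    swap = a1[0] == control_bait
                    if control_bait not in (a1[0], a2[0]):
                        swap = a1[0] > a2[0]
                elif factor == "treatment":
                    swap = a1[2] in control_treatments
                    if not (a1[2] in control_treatments
                            or a2[2] in control_treatments):
                        swap = a1[2] > a2[2]
                else:
                    swap = a1[3] < a2[3]         # later minus earlier
                if swap:
                    (k1, s1), (k2, s2) = (k2, s2), (k1, s1)
                out.append(Contrast(run, factor, k1[1:], k2[1:],
                                    tuple(s1), tuple(s2)))
    return out


# ----------------------------------------------------- moderated statistics

def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (vectorized)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float,
                                                          float]:
    """Empirical-Bayes shrinkage of per-protein sample variances.

    Fits a scaled F/inverse-chi-square prior to the observed variances by
    matching moments of log(s2) and returns (posterior variances,
    prior df, prior variance). With infinite prior df all posteriors
    collapse to the prior variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(polygamma(1, df / 2.0))
    if evar > 0:
        df_prior = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s2_prior = float(np.exp(emean + digamma(df_prior / 2.0)
                                - np.log(df_prior / 2.0)))
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(emean))
    if np.isfinite(df_prior):
        s2_post = (df_prior * s2_prior + df * s2) / (df_prior + df)
    else:
        s2_post = np.full_like(s2, s2_prior)
    return s2_post, df_prior, s2_prior


def test_contrast(protein_matrix: pd.DataFrame, contrast: Contrast,
                  prior_df: float | None = None) -> pd.DataFrame:
    """Moderated two-sample statistics for one contrast.

    log2fc is mean(group a) - mean(group b); the t-statistic uses the
    empirical-Bayes posterior variance with ``df + prior df`` degrees of
    freedom and a two-sided p from the t distribution. ``prior_df=0``
    disables moderation (ordinary pooled-variance t-test).
    """
    a = [s for s in contrast.samples_a if s in protein_matrix.columns]
    b = [s for s in contrast.samples_b if s in protein_matrix.columns]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"contrast {contrast.label} has a group of size < 2")
    xa = protein_matrix[a].to_numpy(dtype=float)
    xb = protein_matrix[b].to_numpy(dtype=float)
    n1, n2 = xa.shape[1], xb.shape[1]
    lfc = xa.mean(axis=1) - xb.mean(axis=1)
    df = n1 + n2 - 2
    pooled = (xa.var(axis=1, ddof=1) * (n1 - 1)
              + xb.var(axis=1, ddof=1) * (n2 - 1)) / df

    if prior_df == 0:
        s2_post, d0 = pooled, 0.0
    else:
        s2_post, d0, _ = squeeze_variances(pooled, df)
        if prior_df is not None:
            raise ValueError("prior_df may only be 0 (moderation off) or None")
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    total_df = df + d0 if np.isfinite(d0) else np.inf
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.DataFrame({"protein": protein_matrix.index, "log2fc": lfc,
                         "t": t, "p": p})


def adjust_and_call(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH adjustment within one contrast family plus the enrichment call.

    ``enriched`` is q < alpha AND log2fc > 0 — only bait-side (positive)
    enrichment counts.
    """
    out = results.copy()
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    out["enriched"] = (out["q"] < alpha) & (out["log2fc"] > 0)
    return out


def run_differential_enrichment(
    protein_matrix: pd.DataFrame, design: ExperimentDesign,
    control_bait: str = CONTROL_BAIT, alpha: float = 0.05,
) -> pd.DataFrame:
    """All contrasts of the design as one long-format call table."""
    frames = []
    for c in enumerate_contrasts(design, control_bait):
        res = adjust_and_call(test_contrast(protein_matrix, c), alpha)
        ba, ca, ta, pa = c.key_a
        bb, cb, tb, pb = c.key_b
        res.insert(1, "run_id", c.run_id)
        res.insert(2, "varying_factor", c.varying_factor)
        res["bait_a"], res["construct_a"] = ba, ca
        res["bait_construct_a"] = bait_construct_id(ba, ca)
        res["treatment_a"], res["timepoint_a"] = ta, pa
        res["bait_b"], res["construct_b"] = bb, cb
        res["bait_construct_b"] = bait_construct_id(bb, cb)
        res["treatment_b"], res["timepoint_b"] = tb, pb
        res["contrast"] = c.label
        frames.append(res)
    if not frames:
        return pd.DataFrame(columns=["protein", "run_id", "varying_factor",
                                     "log2fc", "t", "p", "q", "enriched"])
    return pd.concat(frames, ignore_index=True)
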