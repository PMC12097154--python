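"""Peptide-matrix preprocessing: filtering, transformation and imputation.

The raw input is a FragPipe/MaxLFQ-style peptide table. Processing order:

1. drop decoy and contaminant rows;
2. blank peptides observed in <= 1 sample within a run (drop the peptide
   when no run retains two observations) and drop all peptides of protein
   groups identified by a single ion across runs;
3. log2-transform and median-center each sample;
4. classify missing cells as MAR (exactly one missing value in a
   triplicate — a technical dropout) or MNAR (two or three missing — an
   abundance-driven dropout);
5. impute MAR cells as 95% of the lowest observed value of that peptide
   within its triplicate, and MNAR cells by a MinProb draw from a
   Gaussian centered on the run's 0.5% observed-intensity quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .simulate import META_COLUMNS

__all__ = ["TransformedMatrix", "filter_peptides", "transform_and_center",
           "classify_missingness", "impute_missing", "preprocess_table"]

MAR, MNAR = "MAR", "MNAR"


@dataclass
class TransformedMatrix:
    """log2, median-centered peptide x sample matrix.

    ``data`` keeps the metadata columns alongside one column per sample;
    ``run_quantiles`` maps run_id to the 0.5% quantile of the centered
    observed values in that run (the MinProb imputation mean).
    """

    data: pd.DataFrame = field(repr=False)
    samples: list[str]
    run_quantiles: dict[str, float] = field(default_factory=dict)

    @property
    def values(self) -> pd.DataFrame:
        return self.data[self.samples]

    def copy(self) -> "TransformedMatrix":
        return TransformedMatrix(self.data.copy(), list(self.samples),
                                 dict(self.run_quantiles))


def _sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def filter_peptides(table: pd.DataFrame,
                    design: ExperimentDesign) -> pd.DataFrame:
    """Contaminant/decoy, single-sample and single-ion filtering.

    Peptides detected in at most one sample within a given MS run have
    those cells blanked (set missing) and are dropped entirely when this
    holds in every run; proteins whose total distinct ion count across
    runs is 1 lose all their peptides. Row order is preserved and the
    operation is idempotent.
    """
    samples = _sample_columns(table)
    unknown = set(samples) - set(design.samples)
    if unknown:
        raise ValueError(f"sample columns not in design: {sorted(unknown)}")

    out = table.loc[~table["is_decoy"].astype(bool)
                    & ~table["is_contaminant"].astype(bool)].copy()

    for run in design.runs:
        run_cols = [s for s in design.run_samples(run) if s in samples]
        if not run_cols:
            continue
        n_obs = out[run_cols].notna().sum(axis=1)
        out.loc[n_obs <= 1, run_cols] = np.nan
    out = out[out[samples].notna().any(axis=1)]

    ions = out.groupby("protein")["n_ions"].sum()
    single_ion = set(ions[ions <= 1].index)
    out = out[~out["protein"].isin(single_ion)]
    return out


def transform_and_center(table: pd.DataFrame, design: ExperimentDesign,
                         low_quantile: float = 0.005) -> TransformedMatrix:
    """log2-transform and median-center each sample column.

    Observed cells must be positive. Also records the per-run
    ``low_quantile`` (default 0.5%) quantile of the centered observed
    values for downstream MNAR imputation; quantiles use linear
    interpolation between order statistics.
    """
    samples = _sample_columns(table)
    data = table.copy()
    vals = data[samples].to_numpy(dtype=float)
    bad = np.argwhere(vals <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive intensity at peptide "
            f"{data['peptide'].iloc[i]!r}, sample {samples[j]!r}"
        )
    logv = np.log2(vals)
    med = np.nanmedian(logv, axis=0)
    centered = logv - med
    data[samples] = centered

    run_quantiles = {}
    for run in design.runs:
        run_cols = [s for s in design.run_samples(run) if s in samples]
        obs = data[run_cols].to_numpy().ravel()
        obs = obs[~np.isnan(obs)]
        if obs.size:
            run_quantiles[run] = float(np.quantile(obs, low_quantile))
    return TransformedMatrix(data, samples, run_quantiles)


def classify_missingness(matrix: TransformedMatrix,
                         design: ExperimentDesign) -> pd.DataFrame:
    """MAR/MNAR mask for every missing cell.

    Within each peptide x triplicate block: exactly one of the three
    values missing -> MAR; two or three missing -> MNAR. Observed cells
    stay unclassified (NaN in the mask).
    """
    vals = matrix.values
    mask = pd.DataFrame(np.full(vals.shape, np.nan, dtype=object),
                        index=vals.index, columns=vals.columns)
    for _, trip in design.triplicates():
        cols = [s for s in trip if s in vals.columns]
        if not cols:
            continue
        if len(cols) != 3:
            raise ValueError(f"triplicate {trip} incomplete in matrix")
        block = vals[cols].isna()
        n_missing = block.sum(axis=1)
        for col in cols:
            is_mar = block[col] & (n_missing == 1)
            is_mnar = block[col] & (n_missing >= 2)
            mask.loc[is_mar, col] = MAR
            mask.loc[is_mnar, col] = MNAR
    return mask


def impute_missing(matrix: TransformedMatrix, mask: pd.DataFrame,
                   design: ExperimentDesign, sd_mnar: float = 0.05,
                   mar_factor: float = 0.95, seed: int = 0,
                   mar_scale: str = "transformed") -> TransformedMatrix:
    """Fill every missing cell; observed values are untouched.

    MAR cells become ``mar_factor`` (default 95%) of the lowest observed
    value of that peptide within its triplicate. MNAR cells are drawn
    from Normal(run 0.5% quantile, ``sd_mnar``), the MinProb model of
    below-detection-limit intensities. ``mar_scale`` selects whether the
    0.95 factor multiplies the centered log2 value directly
    ("transformed", the literal pipeline order) or the raw intensity
    ("raw", i.e. subtract log2(1/0.95) on the log scale).
    """
    if mar_scale not in ("transformed", "raw"):
        raise ValueError("mar_scale must be 'transformed' or 'raw'")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    vals = out.data

    run_of = {s: run for run in design.runs for s in design.run_samples(run)}
    trip_of = {}
    for key, trip in design.triplicates():
        for s in trip:
            trip_of[s] = tuple(trip)

    for col in out.samples:
        col_mask = mask[col]
        # MAR: triplicate-local minimum scaled by mar_factor
        mar_rows = col_mask[col_mask == MAR].index
        if len(mar_rows):
            trip_cols = [s for s in trip_of[col] if s in out.samples]
            block = vals.loc[mar_rows, trip_cols]
            mins = block.min(axis=1, skipna=True)
            if mins.isna().any():
                raise RuntimeError(
                    "MAR cell in a triplicate without observed values"
                )
            if mar_scale == "transformed":
                vals.loc[mar_rows, col] = mar_factor * mins
            else:
                vals.loc[mar_rows, col] = mins + np.log2(mar_factor)
        # MNAR: MinProb draw around the run's low quantile
        mnar_rows = col_mask[col_mask == MNAR].index
        if len(mnar_rows):
            mu = out.run_quantiles[run_of[col]]
            vals.loc[mnar_rows, col] = rng.normal(mu, sd_mnar,
                                                  size=len(mnar_rows))
    return out


def preprocess_table(table: pd.DataFrame, design: ExperimentDesign,
               sd_mnar: float = 0.05, mar_factor: float = 0.95,
               low_quantile: float = 0.005, seed: int = 0,
               mar_scale: str = "transformed"):
    """Full preprocessing chain; returns (matrix, mask)."""
    filtered = filter_peptides(table, design)
    tm = transform_and_center(filtered, design, low_quantile)
    mask = classify_missingness(tm, design)
    complete = impute_missing(tm, mask, design, sd_mnar, mar_factor, seed,
                              mar_scale)
    return complete, mask
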