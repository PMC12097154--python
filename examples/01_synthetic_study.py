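"""Generate a synthetic proximity-labeling study with known ground truth.

Builds the default five-construct design (two bait-vs-GFP runs plus a
rapamycin run), simulates a MaxLFQ-style peptide table with planted
bait-specific enrichment and MAR/MNAR dropout, and summarizes what was
planted.
"""

from collections import Counter

from pupitome import QuantSimParams, generate_peptide_quant, \
    torc_study_design

design = torc_study_design()
table, truth = generate_peptide_quant(design, QuantSimParams(), seed=1)

samples = [c for c in table.columns
           if c not in ("peptide", "protein", "is_decoy", "is_contaminant",
                        "n_ions")]
missing = table[samples].isna().mean().mean()

print(f"design: {len(design.samples)} samples, "
      f"{len(design.triplicates())} triplicates, {len(design.runs)} runs")
print(f"peptide table: {len(table)} rows x {len(samples)} samples, "
      f"{missing:.1%} missing cells")
print("planted tiers:", dict(Counter(t.true_tier
                                     for t in truth.proteins.values())))
# The tier counts are the recovery targets for the downstream pipeline;
# the missing fraction reflects the intensity-dependent (MNAR) and random
# (MAR) dropout mechanisms combined.
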