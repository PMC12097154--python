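import numpy as np
import pandas as pd
import pytest

from pupitome.design import generate_design, torc_study_design
from pupitome.simulate import QuantSimParams, generate_peptide_quant


@pytest.fixture(scope="session")
def small_design():
    """One run, one bait vs the GFP control, two treatments, one timepoint."""
    return generate_design(1, ["LST8", "GFP"], ["sucrose", "mannitol"], [4])


@pytest.fixture(scope="session")
def study_design():
    return torc_study_design()


@pytest.fixture(scope="session")
def study_data(study_design):
    """Synthetic study at default conditions with its ground truth."""
    table, truth = generate_peptide_quant(study_design, QuantSimParams(),
                                          seed=11)
    return table, truth


def make_peptide_table(design, rows):
    """Hand-built peptide table: rows = (peptide, protein, decoy, cont,
    n_ions, {sample: value})."""
    samples = design.samples
    cols = ["peptide", "protein", "is_decoy", "is_contaminant",
            "n_ions"] + samples
    recs = []
    for pep, prot, dec, cont, ions, cells in rows:
        r = {"peptide": pep, "protein": prot, "is_decoy": dec,
             "is_contaminant": cont, "n_ions": ions}
        for s in samples:
            r[s] = cells.get(s, np.nan)
        recs.append(r)
    t = pd.DataFrame(recs, columns=cols)
    t["is_decoy"] = t["is_decoy"].astype(bool)
    t["is_contaminant"] = t["is_contaminant"].astype(bool)
    return t
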