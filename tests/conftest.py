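import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def transition_file(tmp_path):
    """Write a small well-formed transition report and return its path."""
    def _write(rows, columns=None, name="transitions.tsv"):
        columns = columns or ["modified_sequence", "precursor_charge",
                              "fragment_ion", "label_channel", "sample_id",
                              "replicate", "area"]
        path = tmp_path / name
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t",
                                                   index=False)
        return path
    return _write


@pytest.fixture
def toy_design():
    """Label-free design: 2 conditions x 3 replicates plus 3 controls."""
    rows = [(f"{c}_{r}", c, r, c == "ctrl")
            for c in ("WT", "ctrl") for r in (1, 2, 3)]
    return pd.DataFrame(rows, columns=["sample_id", "condition",
                                       "replicate", "is_control"])


def make_group_row(pid="P1", unique=2, peptides=4, msms=6, reverse=False,
                   contaminant=False, only_by_site=False, design=None,
                   identified=True, value=100.0):
    """One parsed protein-group row consistent with a design table."""
    row = {"protein_ids": pid, "gene_names": pid, "reverse": reverse,
           "contaminant": contaminant, "only_by_site": only_by_site,
           "unique_peptides": unique, "peptides": peptides,
           "msms_count": msms}
    if design is not None:
        for i, s in enumerate(design["sample_id"]):
            ident = identified[i] if isinstance(identified, (list, tuple)) \
                else identified
            row[f"iBAQ {s}"] = value if ident else np.nan
            row[f"Identification type {s}"] = bool(ident)
    return row
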