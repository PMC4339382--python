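"""Packaged cohort summary fixture.

``table1.tsv`` transcribes the printed per-patient clinical summary of
the CTCR-OV03/04 high-grade serous ovarian cancer cohort: stage,
response, survival endpoints in days, sample counts before/after QC, and
the published TH/CE heterogeneity indices with the star-topology test
p-value.  It carries the downstream (index and survival) stages without
the raw genomic data, which are not redistributed here.

Censoring indicators are not part of the printed table; event indicators
default to "event observed" for both endpoints, which suffices for group
medians but means log-rank and Cox p-values computed from this fixture
are illustrative, not reproductions.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_table1", "table1_indices", "table1_clinical"]


def load_table1() -> pd.DataFrame:
    """The verbatim per-patient summary table as a DataFrame."""
    with resources.files("cnevol.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def table1_indices(min_samples: int = 3) -> pd.DataFrame:
    """Per-patient heterogeneity indices for evaluable patients.

    Patients with fewer than ``min_samples`` post-QC samples have no
    indices and are dropped, leaving the 14 evaluable patients.
    """
    df = load_table1()
    keep = df[df.samples_used >= min_samples].copy()
    return keep[["patient_id", "samples_used", "th_index", "ce_index", "star_p"]].reset_index(
        drop=True
    )


def table1_clinical() -> pd.DataFrame:
    """Clinical records in the pipeline's clinical-table dialect."""
    df = load_table1()
    out = df[["patient_id", "pfs_days", "os_days", "stage", "age_bracket"]].copy()
    out["pfs_event"] = 1
    out["os_event"] = 1
    out["residual_disease"] = np.nan  # not printed in the summary table
    return out[
        ["patient_id", "pfs_days", "pfs_event", "os_days", "os_event", "stage", "age_bracket",
         "residual_disease"]
    ]
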