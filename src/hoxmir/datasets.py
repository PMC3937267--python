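"""Published desk-scale example data.

Clinical covariate tables for the Huntington's disease (HD) and control
prefrontal-cortex (Brodmann Area 9) brain series whose small-RNA
analysis this package reimplements, as printed in the source study, and
the published group-mean normalized expressions of the differentially
expressed miRNAs and miRNA-target genes.  These are the worked-example
inputs for the clinical statistics and signed fold changes; the
underlying sequencing data are not redistributed here (they are
deposited at ArrayExpress under accession E-MTAB-2206).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def hd_clinical() -> pd.DataFrame:
    """Clinical covariates of the twelve HD brains.

    Columns: pmi (hours), rin, death_age, onset_age, duration (years),
    cag (HTT CAG repeat size), neuron_loss (0 absent / 1 mild /
    2 moderate).  Onset age and duration are unknown for HD-08.
    """
    rows = [
        ("HD-01", 37.0, 7.1, 55, 44.0, 11.0, 45, 1),
        ("HD-02", 6.0, 7.5, 69, 63.0, 6.0, 41, 1),
        ("HD-03", 21.0, 7.0, 71, 52.0, 19.0, 43, 1),
        ("HD-05", 19.0, 6.9, 48, 25.0, 23.0, 48, 2),
        ("HD-06", np.nan, 6.2, 40, 34.0, 6.0, 51, 1),
        ("HD-07", 8.0, 8.5, 72, 55.0, 17.0, 41, 1),
        ("HD-08", 21.0, 7.4, 43, np.nan, np.nan, 49, 1),
        ("HD-09", 4.0, 7.8, 68, 45.0, 23.0, 42, 1),
        ("HD-10", 6.0, 8.3, 59, 35.0, 24.0, 46, 1),
        ("HD-12", 13.0, 6.0, 68, 52.0, 16.0, 42, 0),
        ("HD-13", 25.0, 6.1, 57, 40.0, 17.0, 49, 1),
        ("HD-14", 11.0, 7.3, 48, 38.0, 10.0, 45, 1),
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "sample", "pmi", "rin", "death_age", "onset_age",
            "duration", "cag", "neuron_loss",
        ],
    ).set_index("sample")
    df["condition"] = "HD"
    return df


def control_clinical() -> pd.DataFrame:
    """Clinical covariates of the eleven control brains.

    C-35 and C-37 failed the PCA outlier filter in the miRNA-seq
    analysis (``passed_mirna_pca`` False) but passed mRNA-seq QC.
    """
    rows = [
        ("C-14", 21.0, 8.0, 79, True),
        ("C-21", 26.0, 7.3, 76, True),
        ("C-29", 13.0, 6.4, 93, True),
        ("C-31", 24.0, 7.3, 53, True),
        ("C-32", 24.0, 8.3, 57, True),
        ("C-33", 15.0, 7.5, 43, True),
        ("C-35", 21.0, 7.6, 46, False),
        ("C-36", 17.0, 7.5, 40, True),
        ("C-37", 28.0, 8.3, 44, False),
        ("C-38", 20.0, 7.7, 57, True),
        ("C-39", 15.0, 7.3, 80, True),
    ]
    df = pd.DataFrame(
        rows, columns=["sample", "pmi", "rin", "death_age", "passed_mirna_pca"]
    ).set_index("sample")
    df["condition"] = "control"
    return df


def de_mirna_means() -> pd.DataFrame:
    """Published group-mean normalized expression of the five
    differentially expressed miRNAs (control n = 9, HD n = 12)."""
    rows = [
        ("miR-196a-5p", 1.47, 27.49),
        ("miR-10b-5p", 915.81, 26020.05),
        ("miR-615-3p", 1.09, 6.66),
        ("miR-1247-5p", 49.44, 102.01),
        ("miR-196b-5p", 2.49, 11.01),
    ]
    return pd.DataFrame(
        rows, columns=["mirna", "mean_control", "mean_hd"]
    ).set_index("mirna")


def de_target_means() -> pd.DataFrame:
    """Published group-mean expression of differentially expressed
    miRNA-target genes (control n = 9, HD n = 12; subset)."""
    rows = [
        ("SERPINE1", 22.91, 140.82),
        ("CDKN1A", 336.73, 841.75),
        ("EGFR", 784.95, 1762.88),
        ("KRT5", 113.74, 51.99),
        ("HOXD1", 55.91, 22.80),
    ]
    return pd.DataFrame(
        rows, columns=["gene", "mean_control", "mean_hd"]
    ).set_index("gene")
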