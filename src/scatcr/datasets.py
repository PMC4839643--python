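"""Published reference data from the Amur tiger scat survey (NE China, 2013-2015).

These are the printed summary tables of the source study: per-locus
microsatellite characteristics, the winter transect capture-history
matrix, and the sample-accounting totals. They are bundled so that the
estimators can be exercised against the published inputs without any
external download (the raw genotypes were never deposited).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .abundance import CaptureHistory

#: Per-locus characteristics of the 10-microsatellite identification panel.
#: Columns: number of alleles, allele size range (bp), expected/observed
#: heterozygosity, polymorphism information content, allelic-dropout and
#: false-allele rates.
LOCUS_TABLE: pd.DataFrame = pd.DataFrame(
    [
        ("FCA77", 3, 151, 165, 0.44, 0.62, 0.355, 0.040, 0.035),
        ("FCA94", 2, 209, 211, 0.38, 0.24, 0.310, 0.056, 0.004),
        ("D06", 2, 295, 299, 0.48, 0.64, 0.365, 0.029, 0.003),
        ("F42", 2, 205, 233, 0.50, 0.78, 0.374, 0.040, 0.007),
        ("FCA105", 3, 195, 207, 0.51, 0.69, 0.443, 0.024, 0.009),
        ("FCA441", 3, 149, 157, 0.52, 0.68, 0.437, 0.067, 0.032),
        ("FCA304", 3, 126, 134, 0.13, 0.09, 0.124, 0.092, 0.009),
        ("6HDZ089", 3, 211, 223, 0.57, 0.55, 0.512, 0.069, 0.017),
        ("FCA161", 2, 182, 188, 0.44, 0.39, 0.346, 0.087, 0.008),
        ("F124", 3, 208, 220, 0.21, 0.16, 0.189, 0.094, 0.002),
    ],
    columns=[
        "locus", "n_alleles", "size_min", "size_max",
        "h_exp", "h_obs", "pic", "ado", "fa",
    ],
)

#: Winter transect survey: nine individuals x nine 6-day occasions.
#: ``total`` is the number of genotyped scats per individual over the
#: 54-day window (row sums of the binary matrix are <= total because an
#: individual can be detected several times within one occasion).
CAPTURE_TABLE: pd.DataFrame = pd.DataFrame(
    [
        ("F1", "F", "111111000", 20),
        ("F2", "F", "011111010", 11),
        ("F3", "F", "001101110", 6),
        ("F4", "F", "001100000", 2),
        ("F5", "F", "000000010", 1),
        ("F6", "F", "000000011", 2),
        ("M1", "M", "111010101", 8),
        ("M2", "M", "110010100", 4),
        ("M3", "M", "000000100", 1),
    ],
    columns=["individual_id", "sex", "history", "total"],
)

#: Sample accounting by collection method: scats collected, confirmed as
#: tiger, and yielding a usable (>= 9 loci) multi-locus genotype.
ACCOUNTING_TABLE: pd.DataFrame = pd.DataFrame(
    [
        ("routine", 100, 72, 34),
        ("transect", 67, 64, 55),
    ],
    columns=["method", "collected", "tiger_positive", "usable"],
)


def winter_capture_history() -> CaptureHistory:
    """The published nine-individual, nine-occasion capture history."""
    mat = np.array(
        [[int(c) for c in h] for h in CAPTURE_TABLE["history"]], dtype=bool
    )
    return CaptureHistory(
        individuals=list(CAPTURE_TABLE["individual_id"]),
        sexes=list(CAPTURE_TABLE["sex"]),
        matrix=mat,
        counts=CAPTURE_TABLE["total"].to_numpy(),
        occasion_length_days=6,
    )


def winter_scat_counts() -> np.ndarray:
    """Genotyped-scat counts per individual in the winter transect survey."""
    return CAPTURE_TABLE["total"].to_numpy().copy()


def locus_allele_counts() -> np.ndarray:
    return LOCUS_TABLE["n_alleles"].to_numpy().copy()
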