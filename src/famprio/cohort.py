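"""Presence/absence screening of a candidate variant in external cohorts.

A candidate that survives the family cascade is checked in sporadic-case
cohorts (carrier counts over a genotype matrix) and in population
frequency catalogues (simple lookup returning :data:`ABSENT` when the
variant is uncatalogued).  Absence from both supports a family-private
pathogenic allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np

from .model import MISSING, GenotypeMatrix


class _Absent:
    """Sentinel for a variant missing from a frequency catalogue."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ABSENT"

    def __bool__(self) -> bool:
        return False


ABSENT = _Absent()


@dataclass(frozen=True)
class ScreenReport:
    """Carrier and allele-frequency summary of one variant in one cohort."""

    vid: str
    n_samples: int
    n_carriers: int
    n_missing: int
    allele_count: int
    allele_freq: float
    absent: bool

    def to_dict(self) -> dict:
        return {
            "vid": self.vid,
            "n_samples": self.n_samples,
            "n_carriers": self.n_carriers,
            "n_missing": self.n_missing,
            "allele_count": self.allele_count,
            "allele_freq": self.allele_freq,
            "absent": self.absent,
        }


def screen_cohort(vid: str, gt: GenotypeMatrix) -> ScreenReport:
    """Count carriers and alternate alleles of a variant in a cohort.

    Carriers are samples with call 1 or 2; MISSING calls are excluded
    from the allele-frequency denominator.  The ``absent`` flag is the
    per-sample claim — no carrier observed — mirroring how Sanger-style
    validation reports presence per individual.
    """
    calls = gt.row(vid)
    n_samples = len(calls)
    missing = calls == MISSING
    n_missing = int(missing.sum())
    carriers = (calls == 1) | (calls == 2)
    n_carriers = int(carriers.sum())
    allele_count = int(calls[~missing].sum())
    denom = 2 * (n_samples - n_missing)
    allele_freq = allele_count / denom if denom else 0.0
    return ScreenReport(
        vid=vid,
        n_samples=n_samples,
        n_carriers=n_carriers,
        n_missing=n_missing,
        allele_count=allele_count,
        allele_freq=allele_freq,
        absent=n_carriers == 0,
    )


def population_lookup(
    vid: str, freq_table: Mapping[str, float]
) -> Union[float, _Absent]:
    """Look up a variant's catalogued population frequency.

    Returns the frequency when catalogued and :data:`ABSENT` otherwise;
    never raises for an uncatalogued variant.
    """
    if vid in freq_table:
        return float(freq_table[vid])
    return ABSENT
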