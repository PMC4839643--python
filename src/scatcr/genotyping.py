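"""Species/sex assignment and multi-tube consensus genotyping.

Replicate PCR amplifications of noninvasive samples are error-prone:
heterozygotes lose alleles (allelic dropout, ADO) and spurious alleles
appear (false alleles, FA). The multi-tube protocol repeats each
sample x locus reaction and only accepts a genotype once confirmation
thresholds are met:

* heterozygote: both alleles observed in at least ``het_threshold``
  (default 3) positive replicates;
* homozygote: the allele observed in at least ``hom_threshold``
  (default 5) positive replicates with no other allele ever observed.

Reactions start with 3 replicates and continue one at a time until a
locus is accepted or ``max_replicates`` (default 7) attempts are used.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up

__all__ = [
    "ReplicateCall",
    "SpeciesEvidence",
    "ConsensusGenotype",
    "LocusErrorRates",
    "assign_species",
    "assign_sex",
    "call_consensus",
    "estimate_error_rates",
    "accounting_summary",
    "TIGER_BAND",
    "LEOPARD_BAND",
]

#: Diagnostic mitochondrial fragment labels used by the species screen.
TIGER_BAND = "271bp"
LEOPARD_BAND = "156bp"

Species = Literal["tiger", "leopard", "dog_other", "unidentified", "conflict"]


@dataclass(frozen=True)
class ReplicateCall:
    """One PCR replicate for one sample at one locus.

    ``alleles`` is a canonically sorted pair of allele labels (fragment
    sizes in bp), or ``None`` for a failed amplification.
    """

    sample_id: str
    locus: str
    replicate_index: int
    alleles: tuple[int, int] | None

    def __post_init__(self) -> None:
        if self.alleles is not None:
            a, b = self.alleles
            if a > b:
                object.__setattr__(self, "alleles", (b, a))

    @property
    def failed(self) -> bool:
        return self.alleles is None


@dataclass
class SpeciesEvidence:
    """Results of the three diagnostic-fragment screens for one sample."""

    sample_id: str
    screen_results: list[str]  # each in {TIGER_BAND, LEOPARD_BAND, "other", "none"}

    def __post_init__(self) -> None:
        if len(self.screen_results) != 3:
            raise ValueError("exactly 3 species screens are required")


@dataclass
class ConsensusGenotype:
    """Per-sample multi-locus consensus with per-locus bookkeeping."""

    sample_id: str
    calls: dict[str, tuple[int, int] | None]
    n_replicates_used: dict[str, int]
    status: Literal["usable", "discarded"]
    contaminated_loci: list[str] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return sum(1 for v in self.calls.values() if v is not None)


@dataclass
class LocusErrorRates:
    locus: str
    ado: float  # NaN when no heterozygous-consensus amplifications exist
    fa: float
    n_het_amplifications: int
    n_amplifications: int


def assign_species(evidence: SpeciesEvidence) -> Species:
    """Call the species from three diagnostic screens (>= 2 concordant).

    A conflicting double positive (both tiger and leopard bands seen
    twice) is returned as ``"conflict"`` for manual review rather than
    silently resolved.
    """
    counts = Counter(evidence.screen_results)
    tiger = counts[TIGER_BAND] >= 2
    leopard = counts[LEOPARD_BAND] >= 2
    if tiger and leopard:
        return "conflict"
    if tiger:
        return "tiger"
    if leopard:
        return "leopard"
    if counts["other"] >= 2:
        return "dog_other"
    return "unidentified"


def assign_sex(
    x_marker: Sequence[bool], y_marker: Sequence[bool]
) -> Literal["F", "M", "U"]:
    """Sex from triplicate X- and Y-marker amplifications.

    Male requires both markers in >= 2 of 3 replicates; female requires
    the X marker in >= 2 replicates with zero Y amplifications; anything
    else is unknown.
    """
    if len(x_marker) != 3 or len(y_marker) != 3:
        raise ValueError("3 replicates per sex marker are required")
    x, y = sum(map(bool, x_marker)), sum(map(bool, y_marker))
    if x >= 2 and y >= 2:
        return "M"
    if x >= 2 and y == 0:
        return "F"
    return "U"


def _evaluate_locus(
    allele_counts: Counter, het_threshold: int, hom_threshold: int
) -> tuple[tuple[int, int] | None, bool]:
    """Return ``(accepted_pair_or_None, contaminated)`` for current counts."""
    confirmed = [a for a, c in allele_counts.items() if c >= het_threshold]
    if len(confirmed) >= 3:
        return None, True
    if len(confirmed) == 2:
        pair = tuple(sorted(confirmed))
        return (pair[0], pair[1]), False
    if len(allele_counts) == 1:
        ((allele, count),) = allele_counts.items()
        if count >= hom_threshold:
            return (allele, allele), False
    return None, False


def call_consensus(
    replicates: Iterable[ReplicateCall],
    min_loci: int = 9,
    het_threshold: int = 3,
    hom_threshold: int = 5,
    max_replicates: int = 7,
) -> ConsensusGenotype:
    """Call a multi-locus consensus genotype for one sample.

    Replicates are consumed in ``replicate_index`` order, locus by locus,
    mimicking the sequential lab protocol: after the initial 3 attempts a
    locus keeps using one more replicate at a time until its acceptance
    rule fires or ``max_replicates`` attempts are spent. A locus where 3
    distinct alleles each reach the heterozygote threshold is flagged as
    contaminated and set missing. The sample is ``usable`` when at least
    ``min_loci`` loci are accepted.
    """
    reps = list(replicates)
    if not reps:
        raise ValueError("no replicates supplied")
    sample_ids = {r.sample_id for r in reps}
    if len(sample_ids) != 1:
        raise ValueError(f"replicates from multiple samples: {sorted(sample_ids)}")
    (sample_id,) = sample_ids

    calls: dict[str, tuple[int, int] | None] = {}
    used: dict[str, int] = {}
    contaminated: list[str] = []
    by_locus: dict[str, list[ReplicateCall]] = {}
    for r in reps:
        by_locus.setdefault(r.locus, []).append(r)

    for locus, locus_reps in by_locus.items():
        locus_reps = sorted(locus_reps, key=lambda r: r.replicate_index)[:max_replicates]
        counts: Counter = Counter()
        accepted: tuple[int, int] | None = None
        attempts = 0
        for i, rep in enumerate(locus_reps, start=1):
            attempts = i
            if not rep.failed:
                counts.update(set(rep.alleles))
            if i < 3:
                continue
            accepted, contam = _evaluate_locus(counts, het_threshold, hom_threshold)
            if contam:
                contaminated.append(locus)
                accepted = None
                break
            if accepted is not None:
                break
        calls[locus] = accepted
        used[locus] = attempts

    n_accepted = sum(1 for v in calls.values() if v is not None)
    return ConsensusGenotype(
        sample_id=sample_id,
        calls=calls,
        n_replicates_used=used,
        status="usable" if n_accepted >= min_loci else "discarded",
        contaminated_loci=contaminated,
    )


def estimate_error_rates(
    replicates: Iterable[ReplicateCall],
    consensuses: Iterable[ConsensusGenotype],
) -> list[LocusErrorRates]:
    """Per-locus ADO and FA rates by the threshold method.

    ADO: among positive amplifications of samples whose consensus at the
    locus is heterozygous, the fraction showing exactly one of the two
    consensus alleles. FA: among positive amplifications of samples with
    an accepted consensus at the locus, the fraction containing at least
    one allele absent from that consensus. Zero denominators give NaN.
    """
    cons_by_sample = {c.sample_id: c for c in consensuses}
    ado_num: Counter = Counter()
    ado_den: Counter = Counter()
    fa_num: Counter = Counter()
    fa_den: Counter = Counter()
    loci: list[str] = []
    for rep in replicates:
        if rep.locus not in loci:
            loci.append(rep.locus)
        if rep.failed:
            continue
        cons = cons_by_sample.get(rep.sample_id)
        if cons is None:
            continue
        call = cons.calls.get(rep.locus)
        if call is None:
            continue
        fa_den[rep.locus] += 1
        if any(a not in call for a in rep.alleles):
            fa_num[rep.locus] += 1
        if call[0] != call[1]:
            ado_den[rep.locus] += 1
            seen = set(rep.alleles) & set(call)
            if len(seen) == 1:
                ado_num[rep.locus] += 1
    out = []
    for locus in loci:
        out.append(
            LocusErrorRates(
                locus=locus,
                ado=ado_num[locus] / ado_den[locus] if ado_den[locus] else math.nan,
                fa=fa_num[locus] / fa_den[locus] if fa_den[locus] else math.nan,
                n_het_amplifications=ado_den[locus],
                n_amplifications=fa_den[locus],
            )
        )
    return out


def accounting_summary(samples: pd.DataFrame) -> pd.DataFrame:
    """Sample accounting by collection method, plus a total row.

    Expects one row per collected sample with columns ``method``,
    ``species`` and ``status`` (``"usable"``/``"discarded"``; samples
    never genotyped may hold NaN). Returns collected / tiger-positive /
    usable counts with species-ID and genotyping success percentages
    rounded to one decimal. Strata with zero collected samples are
    omitted with a warning.
    """
    rows = []
    groups = list(samples.groupby("method", sort=True, observed=False))
    groups.append(("total", samples))
    for method, grp in groups:
        collected = len(grp)
        if collected == 0:
            warnings.warn(f"stratum {method!r} has no collected samples; omitted",
                          stacklevel=2)
            continue
        tiger = int((grp["species"] == "tiger").sum())
        usable = int((grp["status"] == "usable").sum())
        rows.append(
            {
                "method": method,
                "collected": collected,
                "tiger_positive": tiger,
                "usable": usable,
                "species_id_success_pct": round_half_up(100.0 * tiger / collected, 1),
                "genotyping_success_pct": (
                    round_half_up(100.0 * usable / tiger, 1) if tiger else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
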