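"""Individual identification and probability-of-identity statistics.

Usable consensus genotypes are clustered into individuals: two samples
match when they share at least ``min_loci`` comparable loci (both typed)
and disagree at no more than one of them; individuals are the connected
components of the match graph. The discriminatory power of the marker
panel is summarized by the probability of identity (PID) for unrelated
individuals (theoretical and small-sample unbiased forms) and for full
siblings.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "AlleleFrequencyTable",
    "PIDResult",
    "match_genotypes",
    "allele_frequencies",
    "pid_statistics",
    "to_genepop",
]


@dataclass
class Individual:
    individual_id: str
    sex: str  # 'F' | 'M' | 'U'
    consensus: dict[str, tuple[int, int] | None]
    member_samples: list[str]
    flagged_for_review: bool = False

    @property
    def n_samples(self) -> int:
        return len(self.member_samples)


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies estimated from unique individuals."""

    frequencies: dict[str, dict[int, float]]
    n_typed: dict[str, int]  # individuals typed per locus

    def __post_init__(self) -> None:
        for locus, freqs in self.frequencies.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} sum to {total}, not 1")

    @property
    def loci(self) -> list[str]:
        return list(self.frequencies)


@dataclass
class PIDResult:
    locus_order: list[str]
    per_locus: pd.DataFrame  # columns: pid_theoretical, pid_unbiased, pid_sib
    cumulative: pd.DataFrame  # same columns, cumulative product in locus_order


def _pairs_match(
    a: dict[str, tuple[int, int] | None],
    b: dict[str, tuple[int, int] | None],
    min_loci: int,
    max_mismatch: int,
) -> tuple[bool, int]:
    comparable = 0
    mismatches = 0
    for locus, ga in a.items():
        gb = b.get(locus)
        if ga is None or gb is None:
            continue
        comparable += 1
        if ga != gb:
            mismatches += 1
    return comparable >= min_loci and mismatches <= max_mismatch, mismatches


def match_genotypes(
    consensuses,
    sex_calls: dict[str, str] | None = None,
    min_loci: int = 9,
    max_mismatch: int = 1,
) -> list[Individual]:
    """Cluster usable consensus genotypes into individuals.

    Parameters
    ----------
    consensuses
        Usable :class:`~scatcr.genotyping.ConsensusGenotype` objects (or
        any object with ``sample_id`` and ``calls``).
    sex_calls
        Optional per-sample sex calls; an individual's sex is the
        majority over its member samples.
    min_loci, max_mismatch
        Two samples match when they are comparable (both typed) at
        ``min_loci`` or more loci and differ at no more than
        ``max_mismatch`` of them.

    Individuals are connected components of the match graph, so matching
    is independent of input order. A component whose members are not
    pairwise consistent (some pair differs at more than ``max_mismatch``
    loci) is flagged for review. IDs are assigned per sex in descending
    order of sample count (F1, F2, ..., M1, ..., U1, ...).
    """
    cons = sorted(consensuses, key=lambda c: c.sample_id)
    n = len(cons)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    mism = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            ok, m = _pairs_match(cons[i].calls, cons[j].calls, min_loci, max_mismatch)
            mism[i, j] = mism[j, i] = m
            if ok:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    individuals: list[Individual] = []
    for members in groups.values():
        flagged = any(
            mism[i, j] > max_mismatch for i in members for j in members if i < j
        )
        if flagged:
            warnings.warn(
                "non-transitive match component flagged for review: "
                + ", ".join(cons[i].sample_id for i in members),
                stacklevel=2,
            )
        # majority genotype per locus across member samples
        consensus: dict[str, tuple[int, int] | None] = {}
        loci: list[str] = []
        for i in members:
            for locus in cons[i].calls:
                if locus not in loci:
                    loci.append(locus)
        for locus in loci:
            votes = Counter(
                cons[i].calls[locus]
                for i in members
                if cons[i].calls.get(locus) is not None
            )
            consensus[locus] = votes.most_common(1)[0][0] if votes else None
        sample_ids = [cons[i].sample_id for i in members]
        if sex_calls:
            sex_votes = Counter(
                sex_calls.get(s, "U") for s in sample_ids
            )
            sex_votes.pop("U", None)
            if len(sex_votes) == 1:
                sex = next(iter(sex_votes))
            elif len(sex_votes) == 2 and sex_votes.most_common(2)[0][1] > sex_votes.most_common(2)[1][1]:
                sex = sex_votes.most_common(1)[0][0]
            else:
                sex = "U"
        else:
            sex = "U"
        individuals.append(
            Individual(
                individual_id="",  # assigned below
                sex=sex,
                consensus=consensus,
                member_samples=sample_ids,
                flagged_for_review=flagged,
            )
        )

    for sex in ("F", "M", "U"):
        ranked = sorted(
            (ind for ind in individuals if ind.sex == sex),
            key=lambda ind: (-ind.n_samples, ind.member_samples[0]),
        )
        for rank, ind in enumerate(ranked, start=1):
            ind.individual_id = f"{sex}{rank}"
    individuals.sort(key=lambda ind: (ind.sex, int(ind.individual_id[1:])))
    return individuals


def allele_frequencies(individuals) -> AlleleFrequencyTable:
    """Allele frequencies over unique individuals (2 gene copies each).

    Loci typed in zero individuals are excluded with a warning.
    """
    if not individuals:
        raise ValueError("at least one individual is required")
    counts: dict[str, Counter] = {}
    typed: dict[str, int] = {}
    loci: list[str] = []
    for ind in individuals:
        for locus, call in ind.consensus.items():
            if locus not in loci:
                loci.append(locus)
            if call is None:
                continue
            counts.setdefault(locus, Counter()).update(call)
            typed[locus] = typed.get(locus, 0) + 1
    freqs: dict[str, dict[int, float]] = {}
    for locus in loci:
        if locus not in counts:
            warnings.warn(f"locus {locus} typed in no individual; excluded",
                          stacklevel=2)
            continue
        total = sum(counts[locus].values())
        freqs[locus] = {a: c / total for a, c in sorted(counts[locus].items())}
    return AlleleFrequencyTable(frequencies=freqs, n_typed=typed)


def _pid_single(p: np.ndarray, n: int | None) -> tuple[float, float, float]:
    """(theoretical, unbiased, sib) PID for one locus.

    ``n`` is the number of genotyped individuals; the unbiased form is
    NaN when ``n`` is None or <= 3.
    """
    a2 = float(np.sum(p**2))
    a3 = float(np.sum(p**3))
    a4 = float(np.sum(p**4))
    theo = 2 * a2**2 - a4
    sib = 0.25 + 0.5 * a2 + 0.5 * a2**2 - 0.25 * a4
    if n is None or n <= 3:
        unb = float("nan")
    else:
        unb = (
            n**3 * (2 * a2**2 - a4)
            - 2 * n**2 * (a3 + 2 * a2)
            + n * (9 * a2 + 2)
            - 6
        ) / ((n - 1) * (n - 2) * (n - 3))
    return theo, unb, sib


def pid_statistics(
    freqs: AlleleFrequencyTable,
    locus_order: list[str] | str = "least-informative-first",
) -> PIDResult:
    """Per-locus and cumulative probability-of-identity statistics.

    ``locus_order`` is either an explicit list of loci or
    ``"least-informative-first"`` (descending theoretical PID, so the
    cumulative curves start with the weakest markers). Cumulative values
    are products over the included loci and are non-increasing.
    """
    rows = {}
    for locus, f in freqs.frequencies.items():
        p = np.asarray(list(f.values()))
        n = freqs.n_typed.get(locus)
        rows[locus] = _pid_single(p, n)
    if locus_order == "least-informative-first":
        order = sorted(rows, key=lambda loc: -rows[loc][0])
    else:
        order = list(locus_order)
        unknown = set(order) - set(rows)
        if unknown:
            raise ValueError(f"unknown loci in locus_order: {sorted(unknown)}")
    per_locus = pd.DataFrame(
        [rows[loc] for loc in order],
        index=pd.Index(order, name="locus"),
        columns=["pid_theoretical", "pid_unbiased", "pid_sib"],
    )
    cumulative = per_locus.cumprod()
    return PIDResult(locus_order=order, per_locus=per_locus, cumulative=cumulative)


def to_genepop(individuals, loci: list[str] | None = None, title: str = "scatcr export") -> str:
    """Serialize individual genotypes in GENEPOP text format (3-digit alleles)."""
    if loci is None:
        seen: list[str] = []
        for ind in individuals:
            for locus in ind.consensus:
                if locus not in seen:
                    seen.append(locus)
        loci = seen
    lines = [title]
    lines.extend(loci)
    lines.append("Pop")
    for ind in individuals:
        parts = []
        for locus in loci:
            call = ind.consensus.get(locus)
            if call is None:
                parts.append("000000")
            else:
                parts.append(f"{call[0]:03d}{call[1]:03d}")
        lines.append(f"{ind.individual_id}, " + " ".join(parts))
    return "\n".join(lines) + "\n"
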