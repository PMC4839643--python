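"""Synthetic scat surveys with known ground truth.

The generator draws a small diploid population (genotypes under
Hardy-Weinberg proportions at each locus), deposits scats per individual
under a two-class rate model (an "easy" class deposits/mixes more scats
per occasion than a "hard" class, mirroring the heterogeneity assumed by
the two-innate-rates estimator), and then pushes every tiger scat
through a noisy replicate-PCR process: amplification failure by season,
allelic dropout of one heterozygote allele, and false-allele
substitution from the locus allele support. Species screens and sex
markers are simulated per sample. Everything downstream of field
collection is therefore testable against known truth.

The per-individual two-class deposition model is an assumption; the
source data only constrain its skew (per-individual detection counts
ranging from 1 to 20 in the reference survey).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .genotyping import LEOPARD_BAND, TIGER_BAND, ReplicateCall, SpeciesEvidence

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "default_loci",
    "default_config",
    "simulate_survey",
    "truth_report",
]

WINTER_MONTHS = (12, 1, 2)
MAX_REPLICATES = 7


def default_loci() -> dict[str, dict[int, float]]:
    """A 10-locus panel shaped like the reference survey's marker set.

    Allele counts per locus are (3,2,2,2,3,3,3,3,2,3); labels are
    fragment sizes spread over each locus's published size range.
    """
    from .datasets import LOCUS_TABLE

    freq_by_count = {2: [0.70, 0.30], 3: [0.55, 0.30, 0.15]}
    loci: dict[str, dict[int, float]] = {}
    for row in LOCUS_TABLE.itertuples():
        sizes = np.linspace(row.size_min, row.size_max, row.n_alleles).round().astype(int)
        loci[row.locus] = dict(zip(sizes.tolist(), freq_by_count[row.n_alleles]))
    return loci


@dataclass
class SimulationConfig:
    """Parameters of a synthetic survey.

    Defaults mirror the reference survey: 6-day occasions over a 54-day
    winter window, seasonal amplification success of 77.2% (winter) /
    49.1% (other), and per-locus ADO/FA error rates from the published
    panel characterization.
    """

    n_individuals: int = 10
    sex_ratio: float = 0.6  # fraction female
    loci: dict[str, dict[int, float]] = field(default_factory=default_loci)
    deposition_rates: tuple[float, float] = (2.0, 0.35)  # mean scats/occasion: (easy, hard)
    class_a_fraction: float = 0.4  # fraction of individuals in the easy class
    n_occasions: int = 9
    occasion_length_days: int = 6
    amp_success: dict[str, float] = field(
        default_factory=lambda: {"winter": 0.772, "other": 0.491}
    )
    ado_rates: dict[str, float] | float = 0.06
    fa_rates: dict[str, float] | float = 0.013
    species_mix: dict[str, float] = field(
        default_factory=lambda: {
            "tiger": 0.815,
            "leopard": 0.018,
            "dog": 0.047,
            "unamplifiable": 0.120,
        }
    )
    home_range_centers: list[tuple[float, float]] | None = None
    home_range_radius_km: float = 8.0
    extent_km: float = 40.0
    start_date: dt.date = dt.date(2014, 12, 1)
    method: str = "transect"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.ado_rates, (int, float)):
            self.ado_rates = {loc: float(self.ado_rates) for loc in self.loci}
        if isinstance(self.fa_rates, (int, float)):
            self.fa_rates = {loc: float(self.fa_rates) for loc in self.loci}

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be a positive integer")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.n_occasions < 1:
            raise ValueError("n_occasions must be >= 1")
        if self.occasion_length_days < 1:
            raise ValueError("occasion_length_days must be >= 1")
        if not 0.0 <= self.class_a_fraction <= 1.0:
            raise ValueError("class_a_fraction must lie in [0, 1]")
        if min(self.deposition_rates) < 0:
            raise ValueError("deposition_rates must be non-negative")
        if not self.loci:
            raise ValueError("loci must contain at least one locus")
        for locus, freqs in self.loci.items():
            if not freqs:
                raise ValueError(f"loci[{locus}] has no alleles")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"loci[{locus}] frequencies do not sum to 1")
        if abs(sum(self.species_mix.values()) - 1.0) > 1e-9:
            raise ValueError("species_mix probabilities do not sum to 1")
        for name, rates in (("ado_rates", self.ado_rates), ("fa_rates", self.fa_rates)):
            missing = set(self.loci) - set(rates)
            if missing:
                raise ValueError(f"{name} missing loci: {sorted(missing)}")
            if any(not 0.0 <= r <= 1.0 for r in rates.values()):
                raise ValueError(f"{name} must lie in [0, 1]")
        for season, pr in self.amp_success.items():
            if not 0.0 <= pr <= 1.0:
                raise ValueError(f"amp_success[{season}] must lie in [0, 1]")
        if self.home_range_centers is not None and len(self.home_range_centers) != self.n_individuals:
            raise ValueError("home_range_centers must have one entry per individual")


@dataclass
class SyntheticTruth:
    """Ground truth plus the simulated observable data."""

    config: SimulationConfig
    true_genotypes: dict[str, dict[str, tuple[int, int]]]
    true_sexes: dict[str, str]
    true_classes: dict[str, str]  # 'A' (easy) / 'B' (hard)
    scats: pd.DataFrame  # sample_id, individual_id, species, occasion, day, date, season, x_km, y_km, method
    replicate_table: list[ReplicateCall]
    species_evidence: list[SpeciesEvidence]
    sex_markers: dict[str, tuple[tuple[bool, bool, bool], tuple[bool, bool, bool]]]

    @property
    def n_individuals(self) -> int:
        return len(self.true_genotypes)


def _season_of(date: dt.date) -> str:
    return "winter" if date.month in WINTER_MONTHS else "other"


def simulate_survey(config: SimulationConfig) -> SyntheticTruth:
    """Generate a complete synthetic survey; identical seeds give identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    inds = [f"T{i+1:02d}" for i in range(n)]

    sexes = {ind: ("F" if rng.random() < config.sex_ratio else "M") for ind in inds}
    classes = {
        ind: ("A" if rng.random() < config.class_a_fraction else "B") for ind in inds
    }
    genotypes: dict[str, dict[str, tuple[int, int]]] = {}
    locus_alleles = {
        locus: (np.array(list(freqs)), np.array(list(freqs.values())))
        for locus, freqs in config.loci.items()
    }
    for ind in inds:
        g: dict[str, tuple[int, int]] = {}
        for locus, (alleles, probs) in locus_alleles.items():
            pair = rng.choice(alleles, size=2, p=probs)
            g[locus] = (int(min(pair)), int(max(pair)))
        genotypes[ind] = g

    if config.home_range_centers is None:
        centers = {
            ind: tuple(rng.uniform(0.0, config.extent_km, size=2)) for ind in inds
        }
    else:
        centers = dict(zip(inds, config.home_range_centers))

    rate = {
        ind: config.deposition_rates[0] if classes[ind] == "A" else config.deposition_rates[1]
        for ind in inds
    }

    rows: list[dict[str, Any]] = []
    for occ in range(config.n_occasions):
        for ind in inds:
            for _ in range(rng.poisson(rate[ind])):
                day = occ * config.occasion_length_days + int(
                    rng.integers(config.occasion_length_days)
                )
                date = config.start_date + dt.timedelta(days=day)
                theta = rng.uniform(0, 2 * np.pi)
                radius = config.home_range_radius_km * np.sqrt(rng.random())
                cx, cy = centers[ind]
                rows.append(
                    {
                        "individual_id": ind,
                        "species": "tiger",
                        "occasion": occ + 1,
                        "day": day,
                        "date": date.isoformat(),
                        "season": _season_of(date),
                        "x_km": cx + radius * np.cos(theta),
                        "y_km": cy + radius * np.sin(theta),
                        "method": config.method,
                    }
                )
    n_tiger = len(rows)
    p_tiger = config.species_mix.get("tiger", 1.0)
    window_days = config.n_occasions * config.occasion_length_days
    for other in ("leopard", "dog", "unamplifiable"):
        p_other = config.species_mix.get(other, 0.0)
        if p_other <= 0 or p_tiger <= 0:
            continue
        for _ in range(rng.poisson(n_tiger * p_other / p_tiger)):
            day = int(rng.integers(window_days))
            date = config.start_date + dt.timedelta(days=day)
            rows.append(
                {
                    "individual_id": None,
                    "species": other,
                    "occasion": day // config.occasion_length_days + 1,
                    "day": day,
                    "date": date.isoformat(),
                    "season": _season_of(date),
                    "x_km": rng.uniform(0.0, config.extent_km),
                    "y_km": rng.uniform(0.0, config.extent_km),
                    "method": config.method,
                }
            )
    columns = [
        "individual_id", "species", "occasion", "day", "date", "season",
        "x_km", "y_km", "method",
    ]
    scats = pd.DataFrame(rows, columns=columns)
    scats.insert(0, "sample_id", [f"S{i+1:04d}" for i in range(len(scats))])

    # species screens: the diagnostic band amplifies with the seasonal
    # success probability; dog scats show an off-target band
    evidence: list[SpeciesEvidence] = []
    for row in scats.itertuples():
        amp = config.amp_success.get(row.season, 0.5)
        screens = []
        for _ in range(3):
            if row.species == "tiger":
                screens.append(TIGER_BAND if rng.random() < amp else "none")
            elif row.species == "leopard":
                screens.append(LEOPARD_BAND if rng.random() < amp else "none")
            elif row.species == "dog":
                screens.append("other" if rng.random() < amp else "none")
            else:
                screens.append("none")
        evidence.append(SpeciesEvidence(sample_id=row.sample_id, screen_results=screens))

    # replicate amplifications for true tiger scats
    replicates: list[ReplicateCall] = []
    sex_markers: dict[str, tuple[tuple[bool, bool, bool], tuple[bool, bool, bool]]] = {}
    tiger_scats = scats[scats["species"] == "tiger"]
    for row in tiger_scats.itertuples():
        amp = config.amp_success.get(row.season, 0.5)
        truth = genotypes[row.individual_id]
        for locus, (alleles, _) in locus_alleles.items():
            a, b = truth[locus]
            for r in range(1, MAX_REPLICATES + 1):
                if rng.random() >= amp:
                    replicates.append(ReplicateCall(row.sample_id, locus, r, None))
                    continue
                call = [a, b]
                if a != b and rng.random() < config.ado_rates[locus]:
                    keep = call[int(rng.integers(2))]
                    call = [keep, keep]
                if rng.random() < config.fa_rates[locus]:
                    pos = int(rng.integers(2))
                    others = alleles[alleles != call[pos]]
                    if len(others):
                        call[pos] = int(rng.choice(others))
                replicates.append(
                    ReplicateCall(row.sample_id, locus, r, (min(call), max(call)))
                )
        x_reps = tuple(bool(rng.random() < amp) for _ in range(3))
        if sexes[row.individual_id] == "M":
            y_reps = tuple(bool(rng.random() < amp) for _ in range(3))
        else:
            y_reps = (False, False, False)
        sex_markers[row.sample_id] = (x_reps, y_reps)

    return SyntheticTruth(
        config=config,
        true_genotypes=genotypes,
        true_sexes=sexes,
        true_classes=classes,
        scats=scats,
        replicate_table=replicates,
        species_evidence=evidence,
        sex_markers=sex_markers,
    )


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


def truth_report(truth: SyntheticTruth) -> dict:
    """Ground-truth summary for comparison with downstream estimates.

    Reports the true population size, per-individual scat counts, and the
    realized (as-simulated) per-locus ADO/FA frequencies measured against
    the true genotypes over positive replicates.
    """
    tiger = truth.scats[truth.scats["species"] == "tiger"]
    scat_counts = {
        ind: int((tiger["individual_id"] == ind).sum()) for ind in truth.true_genotypes
    }
    sample_to_ind = dict(zip(tiger["sample_id"], tiger["individual_id"]))
    ado_num: dict[str, int] = {}
    ado_den: dict[str, int] = {}
    fa_num: dict[str, int] = {}
    fa_den: dict[str, int] = {}
    for rep in truth.replicate_table:
        if rep.failed:
            continue
        ind = sample_to_ind.get(rep.sample_id)
        if ind is None:
            continue
        a, b = truth.true_genotypes[ind][rep.locus]
        fa_den[rep.locus] = fa_den.get(rep.locus, 0) + 1
        if any(x not in (a, b) for x in rep.alleles):
            fa_num[rep.locus] = fa_num.get(rep.locus, 0) + 1
        if a != b:
            ado_den[rep.locus] = ado_den.get(rep.locus, 0) + 1
            if len(set(rep.alleles) & {a, b}) == 1:
                ado_num[rep.locus] = ado_num.get(rep.locus, 0) + 1
    realized_ado = {
        loc: (ado_num.get(loc, 0) / den if den else float("nan"))
        for loc, den in ((loc, ado_den.get(loc, 0)) for loc in truth.config.loci)
    }
    realized_fa = {
        loc: (fa_num.get(loc, 0) / den if den else float("nan"))
        for loc, den in ((loc, fa_den.get(loc, 0)) for loc in truth.config.loci)
    }
    return {
        "true_n": truth.n_individuals,
        "true_sexes": dict(truth.true_sexes),
        "scat_counts": scat_counts,
        "realized_ado": realized_ado,
        "realized_fa": realized_fa,
        "n_het_amplifications": {loc: ado_den.get(loc, 0) for loc in truth.config.loci},
    }
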