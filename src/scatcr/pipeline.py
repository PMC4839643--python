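"""End-to-end orchestration: simulate -> genotype -> identify -> diversity
-> abundance -> spatial.

Each stage is an ordinary function over in-memory objects so it can be
invoked independently; :func:`run_pipeline` chains them, writes every
intermediate as delimited text, and emits a JSON summary. All
randomness flows from one root seed, split per stage with
:class:`numpy.random.SeedSequence`, so identical configs reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .abundance import build_capture_history, closure_test, eggert_fit, huggins_fit, tirm_fit
from .diversity import hwe_test, ld_test, locus_diversity, sequential_bonferroni
from .genotyping import accounting_summary, assign_sex, assign_species, call_consensus, estimate_error_rates
from .identity import allele_frequencies, match_genotypes, pid_statistics, to_genepop
from .simulate import SimulationConfig, simulate_survey
from .spatial import mcp

logger = logging.getLogger("scatcr")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline settings; defaults follow the reference survey design."""

    outdir: str = "scatcr_out"
    seed: int = 0
    window_days: int = 54
    occasion_days: int = 6
    match_min_loci: int = 9
    het_threshold: int = 3
    hom_threshold: int = 5
    max_replicates: int = 7
    n_boot: int = 10_000
    n_perm: int = 1_000
    n_max: int = 200
    hwe_permutations: int = 2_000
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if self.window_days % self.occasion_days != 0:
            raise ValueError(
                f"window_days={self.window_days} not divisible by "
                f"occasion_days={self.occasion_days}"
            )
        for name in ("match_min_loci", "het_threshold", "hom_threshold",
                     "max_replicates", "n_boot", "n_perm", "n_max"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            if isinstance(sim.get("start_date"), str):
                import datetime as dt

                sim["start_date"] = dt.date.fromisoformat(sim["start_date"])
            if "deposition_rates" in sim:
                sim["deposition_rates"] = tuple(sim["deposition_rates"])
            if "home_range_centers" in sim and sim["home_range_centers"] is not None:
                sim["home_range_centers"] = [tuple(c) for c in sim["home_range_centers"]]
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_yaml(self, path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = d["simulation"]
            sim["start_date"] = self.simulation.start_date.isoformat()
            sim["deposition_rates"] = list(self.simulation.deposition_rates)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the JSON-ready summary dict."""
    config.validate()
    if config.simulation is None:
        raise ValueError("run_pipeline currently requires a simulation block")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0]) for s in seeds]

    # --- simulate -----------------------------------------------------
    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
    truth = simulate_survey(sim_cfg)
    io.write_replicates(truth.replicate_table, out / "replicates.csv")
    io.write_metadata(truth.scats, out / "metadata.csv")
    io.write_species_evidence(truth.species_evidence, out / "species_evidence.csv")
    io.write_truth(truth, out / "truth.json")
    logger.info("simulated %d scats from %d individuals", len(truth.scats), truth.n_individuals)

    # --- genotype -----------------------------------------------------
    species = {e.sample_id: assign_species(e) for e in truth.species_evidence}
    sex_calls = {
        sid: assign_sex(x, y) for sid, (x, y) in truth.sex_markers.items()
    }
    reps_by_sample: dict[str, list] = {}
    for rep in truth.replicate_table:
        reps_by_sample.setdefault(rep.sample_id, []).append(rep)
    consensuses = [
        call_consensus(
            reps,
            min_loci=config.match_min_loci,
            het_threshold=config.het_threshold,
            hom_threshold=config.hom_threshold,
            max_replicates=config.max_replicates,
        )
        for sid, reps in sorted(reps_by_sample.items())
        if species.get(sid) == "tiger"
    ]
    loci = list(sim_cfg.loci)
    io.write_consensus(consensuses, loci, out / "consensus.csv")
    error_rates = estimate_error_rates(truth.replicate_table, consensuses)
    pd.DataFrame([dataclasses.asdict(e) for e in error_rates]).to_csv(
        out / "error_rates.csv", index=False
    )
    status = {c.sample_id: c.status for c in consensuses}
    samples = truth.scats.assign(
        species=truth.scats["sample_id"].map(species),
        status=truth.scats["sample_id"].map(status),
    )
    accounting = accounting_summary(samples)
    accounting.to_csv(out / "accounting.csv", index=False)

    # --- identify -----------------------------------------------------
    usable = [c for c in consensuses if c.status == "usable"]
    if not usable:
        raise RuntimeError("identify stage failed: no usable genotypes")
    individuals = match_genotypes(usable, sex_calls, min_loci=config.match_min_loci)
    io.write_individuals(individuals, loci, out / "individuals.csv")
    (out / "individuals.gen").write_text(to_genepop(individuals, loci))
    freqs = allele_frequencies(individuals)
    pid = pid_statistics(freqs)
    pid.cumulative.assign(order=range(1, len(pid.locus_order) + 1)).to_csv(
        out / "pid_curves.csv"
    )

    # --- diversity ----------------------------------------------------
    records, means = locus_diversity(individuals)
    div = pd.DataFrame([dataclasses.asdict(r) for r in records])
    div.to_csv(out / "diversity.csv", index=False)
    hwe_p = {}
    for i, rec in enumerate(records):
        try:
            hwe_p[rec.locus] = hwe_test(
                individuals, rec.locus, n_permutations=config.hwe_permutations,
                seed=stage_seed[1] + i,
            ).p_value
        except ValueError:
            continue
    hwe_flags = dict(zip(hwe_p, sequential_bonferroni(list(hwe_p.values()))))

    # --- abundance ----------------------------------------------------
    sample_to_ind = {
        s: ind.individual_id for ind in individuals for s in ind.member_samples
    }
    ind_sex = {ind.individual_id: ind.sex for ind in individuals}
    tiger = truth.scats[truth.scats["sample_id"].isin(sample_to_ind)]
    detections = pd.DataFrame(
        {
            "individual_id": tiger["sample_id"].map(sample_to_ind),
            "date": tiger["day"],
        }
    )
    detections["sex"] = detections["individual_id"].map(ind_sex)
    history = build_capture_history(
        detections, window_start=0,
        window_days=config.window_days, occasion_days=config.occasion_days,
    )
    io.write_capture_history(history, out / "capture_history.csv")
    huggins = huggins_fit(history)
    tirm = tirm_fit(
        history.counts, n_boot=config.n_boot, n_max=config.n_max, seed=stage_seed[2]
    )
    sequence = detections.sort_values("date")["individual_id"].to_numpy()
    eggert = eggert_fit(sequence, n_perm=config.n_perm, seed=stage_seed[3])
    closure = closure_test(history)

    # --- spatial ------------------------------------------------------
    ranges = []
    for ind in individuals:
        pts = truth.scats[truth.scats["sample_id"].isin(ind.member_samples)][
            ["x_km", "y_km"]
        ].to_numpy()
        ranges.append(mcp(pts, individual_id=ind.individual_id))
    io.write_geojson(ranges, out / "ranges.geojson")
    pd.DataFrame(
        [
            {"individual_id": r.individual_id, "n_points": r.n_points,
             "area_km2": r.area if not r.insufficient else None}
            for r in ranges
        ]
    ).to_csv(out / "range_areas.csv", index=False)

    summary = {
        "seed": config.seed,
        "true_n": truth.n_individuals,
        "n_samples": int(len(truth.scats)),
        "n_usable": len(usable),
        "n_individuals": len(individuals),
        "diversity_means": means.to_dict(),
        "hwe_significant": hwe_flags,
        "abundance": {
            est.estimator: {
                "n_hat": est.n_hat,
                "raw": est.raw,
                "se": est.se,
                "ci": [est.ci_low, est.ci_high],
            }
            for est in (huggins, tirm, eggert)
        },
        "closure": {
            "chi2": closure.chi2,
            "df": closure.df,
            "p_value": closure.p_value,
            "testable": closure.testable,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary
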