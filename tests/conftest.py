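import pytest

from scatcr.genotyping import assign_sex, assign_species, call_consensus
from scatcr.simulate import SimulationConfig, simulate_survey


def error_free_config(n_individuals: int = 9, seed: int = 11, **overrides) -> SimulationConfig:
    base = dict(
        n_individuals=n_individuals,
        seed=seed,
        ado_rates=0.0,
        fa_rates=0.0,
        amp_success={"winter": 1.0, "other": 1.0},
        species_mix={"tiger": 1.0, "leopard": 0.0, "dog": 0.0, "unamplifiable": 0.0},
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def error_free_truth():
    """Nine individuals, no genotyping errors, perfect amplification."""
    return simulate_survey(error_free_config())


def genotype_survey(truth, min_loci: int = 9):
    """Run the genotyping stage of a synthetic survey in memory."""
    species = {e.sample_id: assign_species(e) for e in truth.species_evidence}
    sex_calls = {sid: assign_sex(x, y) for sid, (x, y) in truth.sex_markers.items()}
    by_sample = {}
    for rep in truth.replicate_table:
        by_sample.setdefault(rep.sample_id, []).append(rep)
    consensuses = [
        call_consensus(reps, min_loci=min_loci)
        for sid, reps in sorted(by_sample.items())
        if species.get(sid) == "tiger"
    ]
    return species, sex_calls, consensuses


@pytest.fixture(scope="session")
def error_free_consensuses(error_free_truth):
    return genotype_survey(error_free_truth)
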