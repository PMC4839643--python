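import math
import random

import numpy as np
import pandas as pd
import pytest

from scatcr.genotyping import (
    LEOPARD_BAND,
    TIGER_BAND,
    ConsensusGenotype,
    ReplicateCall,
    SpeciesEvidence,
    accounting_summary,
    assign_sex,
    assign_species,
    call_consensus,
    estimate_error_rates,
)


def reps(sample, locus, calls):
    """Build ReplicateCalls from a list of allele pairs / None."""
    return [
        ReplicateCall(sample, locus, i + 1, c) for i, c in enumerate(calls)
    ]


# --------------------------------------------------------------- species

@pytest.mark.parametrize(
    "screens, expected",
    [
        ([TIGER_BAND, TIGER_BAND, "none"], "tiger"),
        ([LEOPARD_BAND, "none", LEOPARD_BAND], "leopard"),
        ([TIGER_BAND, "none", "none"], "unidentified"),
        (["other", "other", "none"], "dog_other"),
        (["none", "none", "none"], "unidentified"),
        ([TIGER_BAND, TIGER_BAND, TIGER_BAND], "tiger"),
    ],
)
def test_assign_species(screens, expected):
    assert assign_species(SpeciesEvidence("s", screens)) == expected


def test_species_mixed_signals_resolved_by_majority():
    ev = SpeciesEvidence("s", [TIGER_BAND, TIGER_BAND, LEOPARD_BAND])
    assert assign_species(ev) == "tiger"
    ev2 = SpeciesEvidence("s", [TIGER_BAND, LEOPARD_BAND, "none"])
    assert assign_species(ev2) == "unidentified"


def test_species_requires_three_screens():
    with pytest.raises(ValueError):
        SpeciesEvidence("s", [TIGER_BAND, TIGER_BAND])


# ------------------------------------------------------------------- sex

@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((1, 1, 1), (1, 1, 0), "M"),
        ((1, 1, 1), (0, 0, 0), "F"),
        ((1, 0, 0), (0, 0, 0), "U"),
        ((1, 1, 0), (1, 0, 0), "U"),  # Y seen once: neither rule fires
        ((0, 0, 0), (1, 1, 1), "U"),
    ],
)
def test_assign_sex(x, y, expected):
    assert assign_sex(x, y) == expected


# ------------------------------------------------------------- consensus

def test_heterozygote_accepted_after_three_replicates():
    cons = call_consensus(reps("s", "L1", [(151, 165)] * 3))
    assert cons.calls["L1"] == (151, 165)
    assert cons.n_replicates_used["L1"] == 3


def test_homozygote_accepted_after_five_replicates():
    cons = call_consensus(reps("s", "L1", [(209, 209)] * 5))
    assert cons.calls["L1"] == (209, 209)
    assert cons.n_replicates_used["L1"] == 5


def test_unresolved_second_allele_blocks_homozygote():
    # 209 seen five times but 211 once: neither threshold fires within
    # seven attempts, so the locus stays missing
    calls = [(209, 209)] * 4 + [(209, 211)] + [None, None]
    cons = call_consensus(reps("s", "L1", calls))
    assert cons.calls["L1"] is None
    assert cons.n_replicates_used["L1"] == 7


def test_contamination_flag_three_confirmed_alleles():
    # three distinct alleles all reach the confirmation threshold on the
    # same replicate: unresolvable mixture, locus set missing
    calls = [(151, 165), (151, 158), (158, 165), (158, 158), (151, 165)]
    cons = call_consensus(reps("s", "L1", calls))
    assert cons.calls["L1"] is None
    assert "L1" in cons.contaminated_loci


def test_failed_replicates_consume_attempts():
    calls = [None, None, None, None, (151, 165), (151, 165), (151, 165)]
    cons = call_consensus(reps("s", "L1", calls))
    assert cons.calls["L1"] == (151, 165)  # accepted exactly at attempt 7


def test_replicate_cap_enforced():
    # a ninth confirming replicate may not rescue the locus
    calls = [None] * 6 + [(151, 165)] * 3
    cons = call_consensus(reps("s", "L1", calls), max_replicates=7)
    assert cons.calls["L1"] is None


def test_consensus_order_invariant():
    calls = [(151, 165), (151, 151), (151, 165), (151, 165), (151, 151)]
    base = reps("s", "L1", calls)
    shuffled = base[:]
    random.Random(0).shuffle(shuffled)
    assert call_consensus(base).calls == call_consensus(shuffled).calls


def test_usable_status_requires_nine_loci():
    replicates = []
    for i in range(10):
        replicates += reps("s", f"L{i}", [(100, 102)] * 3)
    assert call_consensus(replicates).status == "usable"
    # knock two loci down to missing
    replicates = []
    for i in range(8):
        replicates += reps("s", f"L{i}", [(100, 102)] * 3)
    for i in (8, 9):
        replicates += reps("s", f"L{i}", [None] * 7)
    assert call_consensus(replicates).status == "discarded"


def test_error_free_consensus_equals_truth(error_free_truth, error_free_consensuses):
    _, _, consensuses = error_free_consensuses
    sample_to_ind = dict(
        zip(error_free_truth.scats["sample_id"], error_free_truth.scats["individual_id"])
    )
    assert consensuses, "no consensuses called"
    for cons in consensuses:
        assert cons.status == "usable"
        truth = error_free_truth.true_genotypes[sample_to_ind[cons.sample_id]]
        for locus, call in cons.calls.items():
            if call is not None:
                assert call == truth[locus]


# ------------------------------------------------------------ error rates

def _consensus(sample, calls):
    return ConsensusGenotype(sample, calls, {}, "usable")


def test_ado_direct_ratio():
    # 10 positive amplifications of a het-consensus sample, one shows a
    # single allele -> ado = 0.10
    calls = [(151, 165)] * 9 + [(151, 151)]
    rates = estimate_error_rates(
        reps("s", "L1", calls), [_consensus("s", {"L1": (151, 165)})]
    )
    assert rates[0].ado == pytest.approx(0.10)
    assert rates[0].n_het_amplifications == 10


def test_fa_zero_when_no_outside_allele():
    calls = [(151, 165)] * 6
    rates = estimate_error_rates(
        reps("s", "L1", calls), [_consensus("s", {"L1": (151, 165)})]
    )
    assert rates[0].fa == 0.0


def test_fa_counts_outside_alleles():
    calls = [(151, 165)] * 8 + [(151, 158), (158, 165)]
    rates = estimate_error_rates(
        reps("s", "L1", calls), [_consensus("s", {"L1": (151, 165)})]
    )
    assert rates[0].fa == pytest.approx(0.2)


def test_zero_denominator_reports_nan():
    # homozygous consensus only: no het amplifications -> ado undefined
    calls = [(209, 209)] * 5
    rates = estimate_error_rates(
        reps("s", "L1", calls), [_consensus("s", {"L1": (209, 209)})]
    )
    assert math.isnan(rates[0].ado)
    assert rates[0].fa == 0.0


def test_error_free_rates_all_zero(error_free_truth, error_free_consensuses):
    _, _, consensuses = error_free_consensuses
    rates = estimate_error_rates(error_free_truth.replicate_table, consensuses)
    for r in rates:
        if r.n_het_amplifications:
            assert r.ado == 0.0
        assert r.fa == 0.0


def test_estimated_ado_near_configured_rate():
    from scatcr.simulate import simulate_survey
    from conftest import error_free_config, genotype_survey

    truth = simulate_survey(error_free_config(n_individuals=15, seed=21, ado_rates=0.06))
    _, _, consensuses = genotype_survey(truth)
    rates = estimate_error_rates(truth.replicate_table, consensuses)
    num = sum(r.ado * r.n_het_amplifications for r in rates if r.n_het_amplifications)
    den = sum(r.n_het_amplifications for r in rates)
    assert den > 500
    phat = num / den
    # threshold-method estimate vs generating rate, generous binomial CI
    assert abs(phat - 0.06) < 0.02


# ------------------------------------------------------------- accounting

def _samples_frame(rows):
    return pd.DataFrame(rows, columns=["method", "species", "status"])


def test_accounting_transect_species_success():
    rows = [("transect", "tiger", "usable")] * 64 + [
        ("transect", "unidentified", None)
    ] * 3
    out = accounting_summary(_samples_frame(rows))
    transect = out[out["method"] == "transect"].iloc[0]
    assert transect["collected"] == 67
    assert transect["species_id_success_pct"] == 95.5


def test_accounting_total_genotyping_success():
    rows = (
        [("routine", "tiger", "usable")] * 34
        + [("routine", "tiger", "discarded")] * 38
        + [("routine", "unidentified", None)] * 28
        + [("transect", "tiger", "usable")] * 55
        + [("transect", "tiger", "discarded")] * 9
        + [("transect", "unidentified", None)] * 3
    )
    out = accounting_summary(_samples_frame(rows))
    total = out[out["method"] == "total"].iloc[0]
    assert total["collected"] == 167
    assert total["tiger_positive"] == 136
    assert total["usable"] == 89
    assert total["genotyping_success_pct"] == 65.4


def test_accounting_empty_stratum_omitted_with_warning():
    df = _samples_frame([("transect", "tiger", "usable")] * 4)
    df["method"] = pd.Categorical(df["method"], categories=["transect", "routine"])
    with pytest.warns(UserWarning, match="routine"):
        out = accounting_summary(df)
    assert "routine" not in set(out["method"])
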