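"""Plain-text readers/writers for the pipeline's interchange formats.

All intermediates are delimited text so that a run can be inspected,
archived, or resumed stage by stage: replicate calls and sample metadata
as CSV, consensus genotypes as one ``a/b`` column per locus, capture
histories shaped like the published table, individuals as CSV +
GENEPOP, polygons as GeoJSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import CaptureHistory
from .genotyping import ConsensusGenotype, ReplicateCall, SpeciesEvidence
from .identity import Individual
from .simulate import SyntheticTruth

__all__ = [
    "write_replicates",
    "read_replicates",
    "write_metadata",
    "write_species_evidence",
    "read_species_evidence",
    "write_consensus",
    "read_consensus",
    "write_individuals",
    "write_capture_history",
    "read_capture_history",
    "write_truth",
    "write_geojson",
]


def write_replicates(replicates: list[ReplicateCall], path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "locus": r.locus,
            "replicate": r.replicate_index,
            "allele1": "" if r.failed else r.alleles[0],
            "allele2": "" if r.failed else r.alleles[1],
        }
        for r in replicates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_replicates(path) -> list[ReplicateCall]:
    df = pd.read_csv(path, dtype={"sample_id": str, "locus": str})
    out = []
    for row in df.itertuples():
        failed = pd.isna(row.allele1) or pd.isna(row.allele2)
        out.append(
            ReplicateCall(
                sample_id=row.sample_id,
                locus=row.locus,
                replicate_index=int(row.replicate),
                alleles=None if failed else (int(row.allele1), int(row.allele2)),
            )
        )
    return out


def write_metadata(scats: pd.DataFrame, path) -> None:
    cols = ["sample_id", "date", "x_km", "y_km", "method"]
    scats[cols].to_csv(path, index=False)


def write_species_evidence(evidence: list[SpeciesEvidence], path) -> None:
    rows = [
        {"sample_id": e.sample_id, "screen1": e.screen_results[0],
         "screen2": e.screen_results[1], "screen3": e.screen_results[2]}
        for e in evidence
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_species_evidence(path) -> list[SpeciesEvidence]:
    df = pd.read_csv(path, dtype=str)
    return [
        SpeciesEvidence(row.sample_id, [row.screen1, row.screen2, row.screen3])
        for row in df.itertuples()
    ]


def write_consensus(consensuses: list[ConsensusGenotype], loci: list[str], path) -> None:
    rows = []
    for c in consensuses:
        row: dict = {"sample_id": c.sample_id, "status": c.status}
        for locus in loci:
            call = c.calls.get(locus)
            row[locus] = "" if call is None else f"{call[0]}/{call[1]}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_consensus(path) -> list[ConsensusGenotype]:
    df = pd.read_csv(path, dtype=str)
    loci = [c for c in df.columns if c not in ("sample_id", "status")]
    out = []
    for d in df.to_dict("records"):
        calls = {}
        for locus in loci:
            v = d[locus]
            if pd.isna(v) or v == "":
                calls[locus] = None
            else:
                a, b = v.split("/")
                calls[locus] = (int(a), int(b))
        out.append(
            ConsensusGenotype(
                sample_id=d["sample_id"],
                calls=calls,
                n_replicates_used={},
                status=d["status"],
            )
        )
    return out


def write_individuals(individuals: list[Individual], loci: list[str], path) -> None:
    rows = []
    for ind in individuals:
        row = {
            "individual_id": ind.individual_id,
            "sex": ind.sex,
            "n_samples": ind.n_samples,
            "samples": ";".join(ind.member_samples),
        }
        for locus in loci:
            call = ind.consensus.get(locus)
            row[locus] = "" if call is None else f"{call[0]}/{call[1]}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_capture_history(history: CaptureHistory, path) -> None:
    df = pd.DataFrame(
        {
            "individual_id": history.individuals,
            "sex": history.sexes,
            "history": ["".join("1" if v else "0" for v in row) for row in history.matrix],
            "total": history.counts,
        }
    )
    df.to_csv(path, index=False)


def read_capture_history(path) -> CaptureHistory:
    df = pd.read_csv(path, dtype={"individual_id": str, "sex": str, "history": str})
    matrix = np.array([[c == "1" for c in h] for h in df["history"]])
    return CaptureHistory(
        individuals=list(df["individual_id"]),
        sexes=list(df["sex"]),
        matrix=matrix,
        counts=df["total"].to_numpy(),
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "n_individuals": truth.n_individuals,
        "true_sexes": truth.true_sexes,
        "true_classes": truth.true_classes,
        "true_genotypes": {
            ind: {locus: list(call) for locus, call in g.items()}
            for ind, g in truth.true_genotypes.items()
        },
        "scat_assignments": {
            row.sample_id: row.individual_id
            for row in truth.scats.itertuples()
            if row.individual_id is not None
        },
        "seed": truth.config.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_geojson(ranges, path) -> None:
    features = []
    for r in ranges:
        if r.insufficient:
            continue
        ring = [list(v) for v in r.polygon] + [list(r.polygon[0])]
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "individual_id": r.individual_id,
                    "area_km2": r.area,
                    "n_points": r.n_points,
                },
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
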