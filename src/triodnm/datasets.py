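"""Packaged reference tables: published cohort counts and gene panels.

``load_study_summary`` returns the 41-trio intellectual-disability cohort's
confirmed DNM class counts; ``load_control_cohorts`` the two published
control cohorts (54 control trios; 593-quartet unaffected ASD siblings)
used as nulls for the LoF excess test.  The per-trio DNM distribution of
the study cohort (38 trios with detectable DNMs, 3 without) is not printed
count-by-count in the source tables, so ``per_trio_counts`` is left empty
except for the documented zero bin.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .burden import CohortSummary, ControlCohort, NullRates
from .consequence import ConsequenceClass
from .io import read_gene_panel
from .types import GenePanel, GeneTier

_CLASS_COLUMNS = {
    "missense": ConsequenceClass.MISSENSE,
    "synonymous": ConsequenceClass.SYNONYMOUS,
    "nonsense": ConsequenceClass.NONSENSE,
    "canonical_splice": ConsequenceClass.CANONICAL_SPLICE,
    "consensus_splice": ConsequenceClass.CONSENSUS_SPLICE,
    "frameshift_insertion": ConsequenceClass.FRAMESHIFT_INSERTION,
    "frameshift_deletion": ConsequenceClass.FRAMESHIFT_DELETION,
    "inframe_insertion": ConsequenceClass.INFRAME_INSERTION,
    "inframe_deletion": ConsequenceClass.INFRAME_DELETION,
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("triodnm").joinpath("data", name)))


def _cohort_table() -> pd.DataFrame:
    return pd.read_csv(_data_path("cohort_counts.tsv"), sep="\t")


def _row_to_counts(row) -> dict[ConsequenceClass, int]:
    return {cls: int(row[col]) for col, cls in _CLASS_COLUMNS.items()}


def load_study_summary() -> CohortSummary:
    """The 41-trio study cohort: 81 DNMs, 66 coding SNVs, 7 LoF SNVs.

    ``ccds_snvs`` (64) is the coding-SNV count restricted to CCDS bases
    covered at >= 10x — the numerator of the published per-base rate; two
    of the 66 confirmed coding SNVs fell outside that callable denominator.
    """
    df = _cohort_table()
    row = df[df["cohort"] == "id_study"].iloc[0]
    return CohortSummary(
        name="id_study",
        n_trios=int(row["n_trios"]),
        class_counts=_row_to_counts(row),
        callable_bases=int(row["callable_bases"]),
        ccds_snvs=int(row["ccds_snvs"]),
    )


def load_control_cohorts() -> tuple[ControlCohort, ...]:
    df = _cohort_table()
    out = []
    for _, row in df.iterrows():
        if row["cohort"] == "id_study":
            continue
        out.append(
            ControlCohort(
                name=str(row["cohort"]),
                n_trios=int(row["n_trios"]),
                class_counts=_row_to_counts(row),
            )
        )
    return tuple(out)


def default_null_rates() -> NullRates:
    return NullRates(control_cohorts=load_control_cohorts())


def load_default_panels() -> list[GenePanel]:
    return [
        read_gene_panel(_data_path("known_id_genes.txt"), "known_id", GeneTier.KNOWN_ID),
        read_gene_panel(
            _data_path("candidate_id_genes.txt"), "candidate_id", GeneTier.CANDIDATE_ID
        ),
        read_gene_panel(
            _data_path("recessive_xlinked_id_genes.txt"),
            "recessive_xlinked_id",
            GeneTier.RECESSIVE_OR_XLINKED_ID,
        ),
    ]
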