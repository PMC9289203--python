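"""Bundled GWAS summary statistics for the cholesterol efflux capacity study.

The package ships, as plain TSV, the published per-SNP association tables
behind the analysis it implements:

* exposure — six SNPs associated with HDL cholesterol efflux capacity (CEC)
  in a GWAS of up to 5,293 French-Canadian individuals (effects in SD units
  of CEC per effect allele);
* outcomes — the same SNPs' log-odds associations with coronary artery
  disease (CAD) and myocardial infarction (MI) from CARDIoGRAMplusC4D, and
  with ischemic stroke (IS) and its subtypes (large artery, small vessel,
  cardioembolic) from MEGASTROKE;
* study descriptors — "up to N" totals and case/control counts per trait.

The outcome tables are published without allele frequencies; the loader
carries the exposure EAF onto each harmonized instrument, and harmonization
of these pre-aligned tables rests on allele letters alone.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .summary import (
    HarmonizedInstrument,
    StudyDescriptor,
    SummaryAssociation,
    harmonize_tables,
    read_summary_table,
)

#: Instrument used in the primary single-SNP analysis (APOE/C1/C2/C4 locus).
SINGLE_SNP = "rs141622900"

#: Five-locus instrument used in the sensitivity analyses
#: (LPL, LIPC, CETP, APOA1/C3/A4/A5, APOE/C1/C2/C4).
FIVE_SNP_SET = ("rs77069344", "rs2070895", "rs247616", "rs964184", "rs445925")

OUTCOME_TRAITS = ("CAD", "MI", "IS", "LAS", "SVS", "CES")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("cecmr").joinpath("data", name)))


def load_cec_gwas() -> dict[str, tuple[StudyDescriptor, list[SummaryAssociation]]]:
    """Load every bundled table.

    Returns a mapping from trait label (``"CEC"``, ``"CAD"``, ``"MI"``,
    ``"IS"``, ``"LAS"``, ``"SVS"``, ``"CES"``) to a
    ``(StudyDescriptor, associations)`` pair.  The CEC entry has six SNP
    rows; each outcome entry has the same six SNPs.
    """
    studies = pd.read_csv(_data_path("studies.tsv"), sep="\t")
    descriptors: dict[str, StudyDescriptor] = {}
    for row in studies.itertuples(index=False):
        descriptors[row.trait] = StudyDescriptor(
            trait=row.trait,
            n_total=int(row.n_total),
            n_cases=None if pd.isna(row.n_cases) else int(row.n_cases),
            n_controls=None if pd.isna(row.n_controls) else int(row.n_controls),
            ancestry=row.ancestry,
        )

    tables: dict[str, list[SummaryAssociation]] = {
        "CEC": read_summary_table(_data_path("cec_exposure.tsv"))
    }
    all_outcomes = read_summary_table(_data_path("outcomes.tsv"))
    for trait in OUTCOME_TRAITS:
        tables[trait] = [r for r in all_outcomes if r.trait == trait]

    return {trait: (descriptors[trait], tables[trait]) for trait in tables}


def instrument_for(
    outcome_trait: str,
    snps: tuple[str, ...] | str = FIVE_SNP_SET,
) -> list[HarmonizedInstrument]:
    """Harmonized instruments for one bundled outcome.

    ``snps`` selects the instrument: the default five-SNP set,
    :data:`SINGLE_SNP`, or any subset of the six bundled rsIDs.  Exposure
    EAFs are carried onto the instruments (the outcome tables print none).
    """
    if isinstance(snps, str):
        snps = (snps,)
    fixtures = load_cec_gwas()
    if outcome_trait not in OUTCOME_TRAITS:
        raise KeyError(
            f"unknown outcome {outcome_trait!r}; choose from {OUTCOME_TRAITS}"
        )
    exposure = [r for r in fixtures["CEC"][1] if r.snp_id in snps]
    missing = set(snps) - {r.snp_id for r in exposure}
    if missing:
        raise KeyError(f"rsIDs not in the bundled exposure table: {sorted(missing)}")
    return harmonize_tables(exposure, fixtures[outcome_trait][1])
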