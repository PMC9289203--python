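"""GWAS summary-statistic records, file I/O and allele harmonization.

Two-sample Mendelian randomization combines per-SNP association estimates
from an exposure GWAS and an outcome GWAS.  Before any estimator can be
applied the two tables must refer to the same effect allele at every SNP;
this module provides the record types, a tolerant delimited-text reader with
a documented column-alias table, and the harmonization step that reorients
outcome effects (sign flip, frequency complement), resolves strand flips and
drops strand-ambiguous palindromic variants.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from .exceptions import FormatError, HarmonizationError, ValidationError

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Accepted header spellings, lower-cased, for each canonical column.
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "snp": ("snp", "snp_id", "rsid", "rs_id", "markername", "variant_id", "id"),
    "effect_allele": ("effect_allele", "ea", "a1", "allele1", "alt"),
    "other_allele": ("other_allele", "oa", "a2", "allele2", "ref",
                     "non_effect_allele"),
    "eaf": ("eaf", "effect_allele_frequency", "freq", "af", "maf"),
    "beta": ("beta", "b", "effect", "effect_size"),
    "se": ("se", "stderr", "standard_error", "sebeta"),
    "pvalue": ("pvalue", "p", "pval", "p_value"),
    "trait": ("trait", "phenotype", "outcome"),
}

_MANDATORY = ("snp", "effect_allele", "other_allele", "beta", "se")

#: Default half-width of the EAF window around 0.5 inside which palindromic
#: (A/T, C/G) variants are considered strand-ambiguous and dropped.
DEFAULT_PALINDROMIC_EAF_WINDOW = 0.08


@dataclass(frozen=True)
class SummaryAssociation:
    """One SNP-trait association row from a GWAS summary table.

    ``beta`` is the per-allele effect of ``effect_allele`` — in SD units for
    a quantitative exposure, log-odds for a binary outcome.  ``eaf`` and
    ``pvalue`` are optional because published outcome tables often omit them.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    trait: str = ""

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("snp_id must be non-empty")
        if self.se <= 0 or not math.isfinite(self.se):
            raise ValidationError(
                f"{self.snp_id}: se must be positive and finite, got {self.se}"
            )
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: beta must be finite")
        ea, oa = self.effect_allele.upper(), self.other_allele.upper()
        if ea == oa:
            raise ValidationError(
                f"{self.snp_id}: effect and other allele are identical ({ea})"
            )
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise ValidationError(
                f"{self.snp_id}: eaf must lie in (0, 1), got {self.eaf}"
            )
        if self.pvalue is not None:
            if not 0 < self.pvalue <= 1:
                raise ValidationError(
                    f"{self.snp_id}: pvalue must lie in (0, 1], got {self.pvalue}"
                )
            self._check_pvalue_consistency()

    def _check_pvalue_consistency(self) -> None:
        # Printed p-values are rounded (sometimes to "0.000"); warn, never
        # fail, when the quoted p is irreconcilable with 2*Phi(-|beta/se|).
        computed = 2.0 * stats.norm.sf(abs(self.beta / self.se))
        quoted = self.pvalue
        assert quoted is not None
        if quoted < 5e-4 or computed < 5e-4:
            return  # both below plausible print resolution
        if abs(computed - quoted) > 5e-4 and not 0.5 < computed / quoted < 2.0:
            warnings.warn(
                f"{self.snp_id}: quoted p={quoted:g} disagrees with "
                f"p={computed:.3g} implied by beta/se",
                stacklevel=3,
            )

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, where strand cannot be inferred
        from allele letters alone."""
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass(frozen=True)
class StudyDescriptor:
    """Sample-size metadata for one GWAS ("up to N" totals, so ``n_total``
    need not equal cases + controls)."""

    trait: str
    n_total: int
    n_cases: int | None = None
    n_controls: int | None = None
    ancestry: str = ""

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValidationError(f"{self.trait}: n_total must be positive")

    @property
    def case_fraction(self) -> float | None:
        """Cases / total sample size, or None for a quantitative trait."""
        if self.n_cases is None:
            return None
        return self.n_cases / self.n_total


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Per-SNP exposure/outcome effect pair aligned to one effect allele.

    ``beta_exposure`` is in SD units of the exposure per allele;
    ``beta_outcome`` in log-odds per allele.  ``flipped`` records that the
    outcome row was reoriented; ``palindromic`` that the variant is A/T or
    C/G (kept only when frequency evidence resolves the strand, or when no
    frequencies are available to contradict letter-based alignment).
    """

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float | None = None
    palindromic: bool = False
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.se_exposure <= 0:
            raise ValidationError(f"{self.snp_id}: se_exposure must be > 0")
        if self.se_outcome <= 0:
            raise ValidationError(f"{self.snp_id}: se_outcome must be > 0")


def _open_reader(path: Path):
    text = path.read_text()
    try:
        dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters="\t,")
    except (csv.Error, IndexError) as exc:
        raise FormatError(f"{path}: cannot detect delimiter: {exc}") from exc
    return csv.DictReader(text.splitlines(), dialect=dialect)


def _resolve_columns(fieldnames: Sequence[str], path: Path) -> dict[str, str]:
    lower = {name.strip().lower(): name for name in fieldnames}
    mapping: dict[str, str] = {}
    for canonical, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                mapping[canonical] = lower[alias]
                break
    missing = [c for c in _MANDATORY if c not in mapping]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"recognised aliases: { {m: COLUMN_ALIASES[m] for m in missing} }"
        )
    return mapping


def read_summary_table(path: str | Path, trait: str | None = None
                       ) -> list[SummaryAssociation]:
    """Read a tab- or comma-delimited GWAS summary table.

    Column names are matched case-insensitively against
    :data:`COLUMN_ALIASES`; unknown extra columns are ignored.  ``trait``
    overrides any trait column in the file; rows violating record
    invariants raise :class:`~cecmr.exceptions.ValidationError` naming the
    1-based data row.  A p-value printed as exactly 0 (tables rounded to a
    fixed number of decimals) is stored as absent rather than rejected.
    """
    path = Path(path)
    reader = _open_reader(path)
    mapping = _resolve_columns(reader.fieldnames or [], path)
    records: list[SummaryAssociation] = []
    for i, row in enumerate(reader, start=1):
        def get(col: str) -> str | None:
            name = mapping.get(col)
            if name is None:
                return None
            value = (row.get(name) or "").strip()
            return value or None

        try:
            pstr = get("pvalue")
            pvalue = float(pstr) if pstr is not None else None
            if pvalue == 0.0:
                pvalue = None  # printed as 0.000: below print resolution
            records.append(SummaryAssociation(
                snp_id=get("snp") or "",
                effect_allele=get("effect_allele") or "",
                other_allele=get("other_allele") or "",
                beta=float(get("beta")),  # type: ignore[arg-type]
                se=float(get("se")),  # type: ignore[arg-type]
                eaf=float(get("eaf")) if get("eaf") is not None else None,
                pvalue=pvalue,
                trait=trait if trait is not None else (get("trait") or ""),
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path} row {i}: unparseable numeric field "
                              f"({exc})") from exc
    return records


def write_summary_table(records: Iterable[SummaryAssociation],
                        path: str | Path, delimiter: str = "\t") -> None:
    """Write records in the canonical column order (round-trips with
    :func:`read_summary_table` at full float precision)."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(["snp", "effect_allele", "other_allele", "eaf",
                         "beta", "se", "pvalue", "trait"])
        for rec in records:
            writer.writerow([
                rec.snp_id, rec.effect_allele, rec.other_allele,
                "" if rec.eaf is None else repr(rec.eaf),
                repr(rec.beta), repr(rec.se),
                "" if rec.pvalue is None else repr(rec.pvalue),
                rec.trait,
            ])


def _alleles(assoc: SummaryAssociation) -> tuple[str, str]:
    return assoc.effect_allele, assoc.other_allele


def _complemented(assoc: SummaryAssociation) -> tuple[str, str] | None:
    try:
        return (_COMPLEMENT[assoc.effect_allele],
                _COMPLEMENT[assoc.other_allele])
    except KeyError:
        return None  # indel alleles have no strand complement


def harmonize_pair(
    exposure: SummaryAssociation,
    outcome: SummaryAssociation,
    palindromic_eaf_window: float = DEFAULT_PALINDROMIC_EAF_WINDOW,
) -> HarmonizedInstrument | None:
    """Align one outcome association to the exposure's effect allele.

    Returns the harmonized instrument, or ``None`` when the variant is
    palindromic and both allele frequencies fall within
    ``palindromic_eaf_window`` of 0.5 (strand genuinely ambiguous; a log
    message records the drop).  When the outcome EAF is absent the check is
    allele-letter only and palindromic variants are kept, flagged.

    Raises :class:`~cecmr.exceptions.HarmonizationError` when the four
    alleles cannot be reconciled even after a strand flip, and
    ``ValueError`` on mismatched snp_ids.
    """
    if exposure.snp_id != outcome.snp_id:
        raise ValueError(
            f"snp_id mismatch: {exposure.snp_id!r} vs {outcome.snp_id!r}"
        )
    exp_al = _alleles(exposure)
    out_al = _alleles(outcome)
    palindromic = exposure.is_palindromic

    if palindromic:
        # For A/T and C/G pairs a strand flip is indistinguishable from an
        # allele swap; frequency is the only evidence.
        near_half = (
            exposure.eaf is not None and outcome.eaf is not None
            and abs(exposure.eaf - 0.5) < palindromic_eaf_window
            and abs(outcome.eaf - 0.5) < palindromic_eaf_window
        )
        if near_half:
            logger.info(
                "%s: palindromic %s/%s with EAFs %.3f/%.3f inside the "
                "ambiguity window (+/-%.2f around 0.5) -- dropped",
                exposure.snp_id, *exp_al, exposure.eaf, outcome.eaf,
                palindromic_eaf_window,
            )
            return None
        if out_al == exp_al:
            flipped = False
        elif out_al == exp_al[::-1]:
            flipped = True
        else:
            raise HarmonizationError(
                f"{exposure.snp_id}: exposure {exp_al[0]}/{exp_al[1]} vs "
                f"outcome {out_al[0]}/{out_al[1]} cannot be reconciled"
            )
        if (exposure.eaf is not None and outcome.eaf is not None
                and flipped == (abs(exposure.eaf - outcome.eaf)
                                < abs(exposure.eaf - (1 - outcome.eaf)))):
            # letter orientation contradicts the frequencies: trust frequency
            flipped = not flipped
            logger.info("%s: palindromic orientation resolved by EAF",
                        exposure.snp_id)
    else:
        out_comp = _complemented(outcome)
        if out_al == exp_al:
            flipped = False
        elif out_al == exp_al[::-1]:
            flipped = True
        elif out_comp == exp_al:
            flipped = False
            logger.info("%s: outcome alleles strand-flipped", exposure.snp_id)
        elif out_comp == exp_al[::-1]:
            flipped = True
            logger.info("%s: outcome alleles strand-flipped and swapped",
                        exposure.snp_id)
        else:
            raise HarmonizationError(
                f"{exposure.snp_id}: exposure {exp_al[0]}/{exp_al[1]} vs "
                f"outcome {out_al[0]}/{out_al[1]} cannot be reconciled"
            )

    beta_outcome = -outcome.beta if flipped else outcome.beta
    return HarmonizedInstrument(
        snp_id=exposure.snp_id,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=beta_outcome,
        se_outcome=outcome.se,
        eaf=exposure.eaf,
        palindromic=palindromic,
        flipped=flipped,
    )


def harmonize_tables(
    exposure: Sequence[SummaryAssociation],
    outcome: Sequence[SummaryAssociation],
    palindromic_eaf_window: float = DEFAULT_PALINDROMIC_EAF_WINDOW,
) -> list[HarmonizedInstrument]:
    """Harmonize every SNP present in both tables, preserving the exposure
    table's row order; palindromic drops are logged and skipped."""
    by_snp = {rec.snp_id: rec for rec in outcome}
    instruments: list[HarmonizedInstrument] = []
    for exp in exposure:
        out = by_snp.get(exp.snp_id)
        if out is None:
            logger.info("%s: absent from outcome table -- skipped", exp.snp_id)
            continue
        inst = harmonize_pair(exp, out, palindromic_eaf_window)
        if inst is not None:
            instruments.append(inst)
    return instruments
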