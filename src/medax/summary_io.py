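"""Reading, validation and harmonization of GWAS summary statistics.

Summary statistics arrive as delimited text with one row per SNP-trait
association.  The canonical column names are ``SNP, CHR, POS, EA, OA, EAF,
BETA, SE, P, N``; files using other headers are adapted through a
``column_map``.  Exposure and outcome files are merged onto a shared
effect-allele frame by :func:`harmonize` before any instrumental-variable
analysis: outcome effects reported for the opposite allele are sign-flipped,
strand-complement reports are reconciled, and strand-ambiguous (palindromic)
variants are either dropped (minor-allele frequency above a limit, 0.3 by
default) or oriented by allele-frequency agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical column order for summary-statistic TSV output.
CANONICAL_COLUMNS = ("SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N")

REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue", "n")

#: Default mapping from record fields to canonical file columns.
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos_bp": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association with one trait.

    Parameters
    ----------
    snp_id : str
        Variant identifier (typically an rsid).
    effect_allele, other_allele : str
        Single bases in ``{A, C, G, T}``; must differ.  ``beta`` is reported
        per copy of ``effect_allele``.
    eaf : float
        Effect-allele frequency, strictly inside (0, 1).
    beta : float
        Per-allele effect size; log odds ratio for binary traits.
    se : float
        Standard error of ``beta``; strictly positive.
    pvalue : float
        Association p-value in (0, 1].
    n : int
        Sample size, at least 2.
    chrom, pos_bp : optional
        Genomic coordinates (1-based position), required only for LD
        clumping.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int
    chrom: str | None = None
    pos_bp: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T, "
                f"got {self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical")
        if not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"{self.snp_id}: eaf must lie strictly in (0,1), got {self.eaf}")
        if not self.se > 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(f"{self.snp_id}: pvalue must lie in (0,1], got {self.pvalue}")
        if self.n < 2:
            raise ValidationError(f"{self.snp_id}: n must be >= 2, got {self.n}")
        if self.pos_bp is not None and self.pos_bp < 1:
            raise ValidationError(f"{self.snp_id}: pos_bp must be >= 1 (1-based), got {self.pos_bp}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is ambiguous."""
        return COMPLEMENT[self.effect_allele] == self.other_allele

    @property
    def maf(self) -> float:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``."""
        return min(self.eaf, 1.0 - self.eaf)


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP on a shared effect allele."""

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float
    is_palindromic: bool = False
    was_flipped: bool = False

    def __post_init__(self) -> None:
        if not self.se_exposure > 0:
            raise ValidationError(f"{self.snp_id}: se_exposure must be > 0")
        if not self.se_outcome > 0:
            raise ValidationError(f"{self.snp_id}: se_outcome must be > 0")


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SummaryRecord]:
    """Read a delimited summary-statistics file into validated records.

    Parameters
    ----------
    path : str or Path
        Tab- or comma-delimited text file with a header line; the delimiter
        is auto-detected from the header.
    column_map : mapping, optional
        Maps record field names (``snp_id``, ``eaf``, ``beta``, ...) to the
        column names used in the file.  Defaults to the canonical names
        (``SNP``, ``EAF``, ``BETA``, ...).  ``chrom`` / ``pos_bp`` are
        optional; all other fields are required.

    Returns
    -------
    list of SummaryRecord
        One record per row, in file order.  Duplicate ``snp_id`` rows are
        collapsed to the one with the smallest p-value (the rest logged).

    Raises
    ------
    ConfigurationError
        A required field is absent from ``column_map`` or the mapped column
        is missing from the file.
    ValidationError
        A row fails validation; the message cites the 1-based data row.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map is not None:
        cmap = {**{k: v for k, v in cmap.items() if k in ("chrom", "pos_bp")}, **dict(column_map)}
    for fld in REQUIRED_FIELDS:
        if fld not in cmap:
            raise ConfigurationError(f"column_map does not resolve required field {fld!r}")

    with path.open() as fh:
        header = fh.readline()
    sep = _detect_delimiter(header)
    df = pd.read_csv(path, sep=sep, dtype=str)

    for fld in REQUIRED_FIELDS:
        if cmap[fld] not in df.columns:
            raise ConfigurationError(
                f"required column {cmap[fld]!r} (field {fld!r}) missing from {path.name}"
            )
    has_chrom = cmap.get("chrom") in df.columns
    has_pos = cmap.get("pos_bp") in df.columns

    records: list[SummaryRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            records.append(
                SummaryRecord(
                    snp_id=str(rowd[cmap["snp_id"]]),
                    effect_allele=str(rowd[cmap["effect_allele"]]).upper(),
                    other_allele=str(rowd[cmap["other_allele"]]).upper(),
                    eaf=float(rowd[cmap["eaf"]]),
                    beta=float(rowd[cmap["beta"]]),
                    se=float(rowd[cmap["se"]]),
                    pvalue=float(rowd[cmap["pvalue"]]),
                    n=int(float(rowd[cmap["n"]])),
                    chrom=str(rowd[cmap["chrom"]]) if has_chrom else None,
                    pos_bp=int(float(rowd[cmap["pos_bp"]])) if has_pos else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path.name} row {i}: unparsable value ({exc})") from exc
        except ValidationError as exc:
            raise ValidationError(f"{path.name} row {i}: {exc}") from exc
    return deduplicate(records)


def deduplicate(records: Iterable[SummaryRecord]) -> list[SummaryRecord]:
    """Keep, per snp_id, the record with the smallest p-value (file order kept)."""
    best: dict[str, SummaryRecord] = {}
    order: list[str] = []
    n_dropped = 0
    for rec in records:
        if rec.snp_id not in best:
            best[rec.snp_id] = rec
            order.append(rec.snp_id)
        else:
            n_dropped += 1
            if rec.pvalue < best[rec.snp_id].pvalue:
                best[rec.snp_id] = rec
    if n_dropped:
        logger.info("deduplicate: dropped %d duplicate snp_id rows", n_dropped)
    return [best[s] for s in order]


def records_to_frame(records: Sequence[SummaryRecord]) -> pd.DataFrame:
    """Summary records as a DataFrame in canonical column order."""
    return pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "CHR": [r.chrom for r in records],
            "POS": [r.pos_bp for r in records],
            "EA": [r.effect_allele for r in records],
            "OA": [r.other_allele for r in records],
            "EAF": [r.eaf for r in records],
            "BETA": [r.beta for r in records],
            "SE": [r.se for r in records],
            "P": [r.pvalue for r in records],
            "N": [r.n for r in records],
        }
    )


def write_summary_stats(records: Sequence[SummaryRecord], path: str | Path) -> None:
    """Write records as TSV with the canonical column order."""
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def _orientation(exp: SummaryRecord, out: SummaryRecord) -> str | None:
    """Classify how the outcome record's alleles relate to the exposure's.

    Returns ``"same"``, ``"swap"``, ``"comp"``, ``"comp_swap"`` or None when
    the allele pairs cannot be reconciled.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    if (out.effect_allele, out.other_allele) == (ea, oa):
        return "same"
    if (out.effect_allele, out.other_allele) == (oa, ea):
        return "swap"
    cea, coa = COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele]
    if (cea, coa) == (ea, oa):
        return "comp"
    if (cea, coa) == (oa, ea):
        return "comp_swap"
    return None


def harmonize(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    palindrome_maf_limit: float = 0.3,
) -> list[HarmonizedPair]:
    """Merge exposure and outcome records onto the exposure effect allele.

    Only SNPs present in both inputs survive.  Non-palindromic variants are
    aligned by allele identity: a swapped outcome report has its beta negated
    and frequency complemented; strand-complement reports (A/G vs T/C) are
    reconciled the same way after complementing.  Palindromic variants (A/T,
    C/G) with exposure MAF above ``palindrome_maf_limit`` are dropped as
    strand-ambiguous; the rest are oriented by allele-frequency agreement:
    the outcome is flipped when its frequency is closer to ``1 - eaf_exp``
    than to ``eaf_exp``.

    Irreconcilable allele pairs are dropped and logged, never fatal.
    """
    out_by_id = {r.snp_id: r for r in outcome}
    pairs: list[HarmonizedPair] = []
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            continue
        if exp.is_palindromic:
            if exp.maf > palindrome_maf_limit:
                logger.info(
                    "harmonize: dropped palindromic %s (MAF %.3f > %.3f)",
                    exp.snp_id, exp.maf, palindrome_maf_limit,
                )
                continue
            if out.is_palindromic and {out.effect_allele, out.other_allele} != {
                exp.effect_allele, exp.other_allele
            }:
                logger.warning("harmonize: dropped %s (incompatible palindromic alleles)", exp.snp_id)
                continue
            # strand cannot disambiguate a palindrome; orient by frequency
            flip = abs(exp.eaf - out.eaf) > abs(exp.eaf - (1.0 - out.eaf))
        else:
            orient = _orientation(exp, out)
            if orient is None:
                logger.warning("harmonize: dropped %s (irreconcilable alleles)", exp.snp_id)
                continue
            flip = orient in ("swap", "comp_swap")
        pairs.append(
            HarmonizedPair(
                snp_id=exp.snp_id,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=-out.beta if flip else out.beta,
                se_outcome=out.se,
                eaf_exposure=exp.eaf,
                is_palindromic=exp.is_palindromic,
                was_flipped=flip,
            )
        )
    return pairs


def pairs_to_frame(pairs: Sequence[HarmonizedPair]) -> pd.DataFrame:
    """Harmonized pairs as a DataFrame (fixed column order, TSV-ready)."""
    return pd.DataFrame(
        {
            "SNP": [p.snp_id for p in pairs],
            "BETA_EXP": [p.beta_exposure for p in pairs],
            "SE_EXP": [p.se_exposure for p in pairs],
            "BETA_OUT": [p.beta_outcome for p in pairs],
            "SE_OUT": [p.se_outcome for p in pairs],
            "EAF_EXP": [p.eaf_exposure for p in pairs],
            "PALINDROMIC": [p.is_palindromic for p in pairs],
            "FLIPPED": [p.was_flipped for p in pairs],
        }
    )
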