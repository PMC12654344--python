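"""Instrumental-variable selection and quality control.

Candidate instruments pass, in order: a p-value tier (1e-5 for gut
microbiota exposures, 5e-6 for plasma metabolites, 5e-8 for disease
outcomes), greedy LD clumping (r² < 0.001 within a ±10,000 kb window),
a per-variant strength filter (F ≥ 10, with F = R²(N−2)/(1−R²) and
R² = 2·EAF(1−EAF)β² / (2·EAF(1−EAF)β² + 2·EAF(1−EAF)·SE²·N)), and a
confounder-association screen.  Every filter returns a subsequence of its
input, so stages compose freely.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .summary_io import HarmonizedPair, SummaryRecord

logger = logging.getLogger(__name__)

# p-value tiers used for instrument selection throughout the study design
MICROBIOTA_P = 1e-5
METABOLITE_P = 5e-6
GENOME_WIDE_P = 5e-8

F_MIN_DEFAULT = 10.0


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise squared-correlation (r²) matrix over an ordered SNP panel."""

    snp_ids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        object.__setattr__(self, "r2", r2)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        k = len(self.snp_ids)
        if r2.shape != (k, k):
            raise ValidationError(f"LD matrix shape {r2.shape} does not match {k} snp_ids")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
            raise ValidationError("LD matrix diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise ValidationError("LD r2 entries must lie in [0,1]")

    def lookup(self, a: str, b: str) -> float:
        """r² between two SNPs; pairs absent from the panel count as 0."""
        try:
            i = self.snp_ids.index(a)
            j = self.snp_ids.index(b)
        except ValueError:
            logger.info("LDMatrix: pair (%s, %s) not covered, treating r2 as 0", a, b)
            return 0.0
        return float(self.r2[i, j])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(snp_ids=tuple(df.columns), r2=df.to_numpy(dtype=float))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=list(self.snp_ids), columns=list(self.snp_ids)).to_csv(
            path, sep="\t"
        )


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome pairs that survived instrument QC.

    The unit every MR estimator consumes.  ``f_statistics`` carries the
    per-SNP instrument-strength F values when they were computed upstream.
    """

    exposure_name: str
    outcome_name: str
    pairs: list[HarmonizedPair]
    f_statistics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.snp_id for p in self.pairs]
        if len(ids) != len(set(ids)):
            raise ValidationError("InstrumentSet contains duplicate snp_ids")
        if any(f < 0 for f in self.f_statistics.values()):
            raise ValidationError("F statistics must be nonnegative")

    @property
    def n_snp(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exposure, se_exposure, beta_outcome, se_outcome) arrays."""
        bx = np.array([p.beta_exposure for p in self.pairs])
        sx = np.array([p.se_exposure for p in self.pairs])
        by = np.array([p.beta_outcome for p in self.pairs])
        sy = np.array([p.se_outcome for p in self.pairs])
        return bx, sx, by, sy

    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.pairs]

    def subset(self, keep: Sequence[str]) -> "InstrumentSet":
        keep_set = set(keep)
        return InstrumentSet(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            pairs=[p for p in self.pairs if p.snp_id in keep_set],
            f_statistics={k: v for k, v in self.f_statistics.items() if k in keep_set},
        )


def select_by_pvalue(
    records: Sequence[SummaryRecord], threshold: float
) -> list[SummaryRecord]:
    """Keep records with ``pvalue`` strictly below ``threshold`` (order kept)."""
    if not (0.0 < threshold <= 1.0):
        raise ValidationError(f"p-value threshold must lie in (0,1], got {threshold}")
    kept = [r for r in records if r.pvalue < threshold]
    if not kept:
        logger.info("select_by_pvalue: no records below %.3g", threshold)
    return kept


def compute_variance_explained(eaf: float, beta: float, se: float, n: int) -> float:
    """Proportion of exposure variance explained by one SNP.

    R² = 2·EAF(1−EAF)·β² / (2·EAF(1−EAF)·β² + 2·EAF(1−EAF)·SE²·N).
    """
    if not (0.0 < eaf < 1.0):
        raise ValidationError(f"eaf must lie in (0,1), got {eaf}")
    if not se > 0:
        raise ValidationError(f"se must be > 0, got {se}")
    if n < 2:
        raise ValidationError(f"n must be >= 2, got {n}")
    var_term = 2.0 * eaf * (1.0 - eaf)
    num = var_term * beta * beta
    return num / (num + var_term * se * se * n)


def compute_f(r2: float, n: int) -> float:
    """Instrument-strength F statistic, F = R²(N−2)/(1−R²)."""
    if not (0.0 <= r2 < 1.0):
        raise ValidationError(f"r2 must lie in [0,1), got {r2}")
    if n < 3:
        raise ValidationError(f"n must be >= 3, got {n}")
    return r2 * (n - 2) / (1.0 - r2)


def f_statistic(record: SummaryRecord) -> float:
    """Per-variant F from a summary record's EAF, beta, SE and N."""
    return compute_f(
        compute_variance_explained(record.eaf, record.beta, record.se, record.n), record.n
    )


def filter_weak_instruments(
    records: Sequence[SummaryRecord], f_min: float = F_MIN_DEFAULT
) -> tuple[list[SummaryRecord], dict[str, float]]:
    """Drop variants with F below ``f_min`` (F exactly at the limit is kept).

    Returns the surviving subsequence and the per-SNP F values of survivors.
    """
    kept: list[SummaryRecord] = []
    fstats: dict[str, float] = {}
    for rec in records:
        f = f_statistic(rec)
        if f < f_min:
            logger.info("filter_weak_instruments: dropped %s (F=%.2f < %.2f)", rec.snp_id, f, f_min)
            continue
        kept.append(rec)
        fstats[rec.snp_id] = f
    return kept, fstats


def clump(
    records: Sequence[SummaryRecord],
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> list[SummaryRecord]:
    """Greedy LD clumping: p-value-ordered index SNPs prune their neighbours.

    Repeatedly takes the remaining record with the smallest p-value as an
    index SNP and removes every other remaining record on the same
    chromosome within ``window_kb`` kilobases (inclusive) whose r² with the
    index is at or above ``r2_threshold``.  SNPs on other chromosomes, or
    outside the window, are never pruned regardless of recorded r².  Ties on
    p-value break by smaller position, then lexicographic snp_id.  Index
    SNPs are returned in selection order.
    """
    for rec in records:
        if rec.chrom is None or rec.pos_bp is None:
            raise ValidationError(f"clump: record {rec.snp_id} lacks chrom/pos")
    window_bp = window_kb * 1000.0
    remaining = list(records)
    selected: list[SummaryRecord] = []
    while remaining:
        idx = min(remaining, key=lambda r: (r.pvalue, r.pos_bp, r.snp_id))
        selected.append(idx)
        pruned: list[SummaryRecord] = []
        for rec in remaining:
            if rec is idx:
                continue
            in_window = rec.chrom == idx.chrom and abs(rec.pos_bp - idx.pos_bp) <= window_bp
            if in_window and ld.lookup(idx.snp_id, rec.snp_id) >= r2_threshold:
                logger.info("clump: %s pruned by index %s", rec.snp_id, idx.snp_id)
                continue
            pruned.append(rec)
        remaining = pruned
    return selected


def screen_confounders(
    instruments: Sequence[SummaryRecord],
    confounder_assoc: pd.DataFrame,
    threshold: float = 1e-5,
) -> list[SummaryRecord]:
    """Remove SNPs associated with a known confounder at p below ``threshold``.

    ``confounder_assoc`` has columns SNP, TRAIT, P (any case).  An empty
    table is a vacuous screen.  Removals are logged with the trait names.
    """
    if confounder_assoc is None or len(confounder_assoc) == 0:
        return list(instruments)
    tab = confounder_assoc.rename(columns={c: c.upper() for c in confounder_assoc.columns})
    for col in ("SNP", "TRAIT", "P"):
        if col not in tab.columns:
            raise ValidationError(f"confounder table lacks column {col}")
    hits = tab[tab["P"].astype(float) < threshold]
    flagged = hits.groupby("SNP")["TRAIT"].apply(list).to_dict()
    kept = []
    for rec in instruments:
        if rec.snp_id in flagged:
            logger.info(
                "screen_confounders: removed %s (associated with %s)",
                rec.snp_id, ", ".join(flagged[rec.snp_id]),
            )
        else:
            kept.append(rec)
    return kept


def read_confounder_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of (SNP, TRAIT, P) confounder associations."""
    return pd.read_csv(path, sep="\t")
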