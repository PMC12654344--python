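"""Seeded generators with known causal structure for every pipeline stage.

The two-sample generator draws, per SNP j, a minor-allele frequency and a
latent per-allele effect γ_j on a standardized exposure; observed summary
statistics add sampling noise with the closed-form standard error of a
per-allele regression on a unit-variance phenotype,

    se = 1 / sqrt(2·maf·(1−maf)·N).

The outcome effect is θ·γ_j plus an optional pleiotropic shift α_j (drawn
for a configured fraction of SNPs, directional when its mean is nonzero,
balanced when zero).  The mediation generator chains two such models —
exposure→mediator (θ₁) on one SNP panel and mediator→outcome (θ₂) on a
disjoint panel — so the implied total effect is direct + θ₁·θ₂.  The omics
generator plants latent-factor correlations between chosen taxon-metabolite
pairs on top of case/control group shifts.

All generators are pure functions of their configuration (seed included);
independent substreams are split from the root seed so each simulated trait
is separately reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .instruments import LDMatrix
from .summary_io import SummaryRecord

# Non-palindromic allele pairs only, so harmonization keeps every SNP;
# palindromes are injected explicitly by tests that exercise that rule.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-sample / mediation GWAS model.

    Sample sizes default to biobank scale (200k) and 50 instruments, with
    per-allele effects of sd 0.05 on standardized traits — strong
    instruments (F well above 10) like the real selection step produces.
    """

    seed: int = 0
    n_snps: int = 50
    n_exposure: int = 200_000
    n_outcome: int = 200_000
    n_mediator: int = 200_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.05
    true_theta: float = 0.0
    theta1: float = 0.0
    theta2: float = 0.0
    direct: float = 0.0
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    ld_block_size: int = 1
    ld_within_r2: float = 0.0

    def __post_init__(self) -> None:
        for name, n in (
            ("n_exposure", self.n_exposure),
            ("n_outcome", self.n_outcome),
            ("n_mediator", self.n_mediator),
        ):
            if n < 2:
                raise ValidationError(f"{name} must be >= 2")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.pleiotropy_frac <= 1.0):
            raise ValidationError("pleiotropy_frac must lie in [0,1]")
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        if self.ld_block_size < 1:
            raise ValidationError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_within_r2 <= 1.0):
            raise ValidationError("ld_within_r2 must lie in [0,1]")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators split from one root seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def _make_records(
    ids: Sequence[str],
    chrom: Sequence[str],
    pos: Sequence[int],
    alleles: Sequence[tuple[str, str]],
    maf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
) -> list[SummaryRecord]:
    p = _two_sided_p(beta, se)
    return [
        SummaryRecord(
            snp_id=ids[j], chrom=chrom[j], pos_bp=int(pos[j]),
            effect_allele=alleles[j][0], other_allele=alleles[j][1],
            eaf=float(maf[j]), beta=float(beta[j]), se=float(se[j]),
            pvalue=float(p[j]), n=n,
        )
        for j in range(len(ids))
    ]


def _panel(rng: np.random.Generator, cfg: SimulationConfig, prefix: str, chrom_offset: int = 0):
    """SNP ids, positions, alleles, MAFs and latent effects for one panel."""
    m = cfg.n_snps
    ids = [f"{prefix}{j + 1}" for j in range(m)]
    # one LD block per chromosome-chunk; blocks 1 Mb apart, SNPs 10 kb apart
    block = np.arange(m) // cfg.ld_block_size
    within = np.arange(m) % cfg.ld_block_size
    chrom = [str(1 + chrom_offset + (b % 22)) for b in block]
    pos = 1_000_000 * (block // 22 + 1) + 10_000 * within + 1
    alleles = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(m)]
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    # effects are reported for the trait-increasing allele (half-normal
    # magnitudes), the orientation instrument selection produces in practice;
    # directional pleiotropy is defined on this shared orientation
    gamma = np.abs(rng.normal(0.0, cfg.gamma_sd, size=m))
    return ids, chrom, pos, alleles, maf, gamma, block


def _block_ld(ids: Sequence[str], block: np.ndarray, within_r2: float) -> LDMatrix:
    m = len(ids)
    r2 = np.where(block[:, None] == block[None, :], within_r2, 0.0)
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(snp_ids=tuple(ids), r2=r2)


def simulate_two_sample(cfg: SimulationConfig):
    """Exposure and outcome summary statistics under a known causal effect.

    Returns ``(exposure_records, outcome_records, ld, truth)`` where
    ``truth`` stores every latent quantity (MAFs, γ_j, pleiotropy α_j, the
    causal θ and the noiseless conditional means of both beta vectors), so
    any generated observation's expectation can be recomputed exactly.
    """
    rng_panel, rng_x, rng_y, rng_pleio = _spawn(cfg.seed, 4)
    ids, chrom, pos, alleles, maf, gamma, block = _panel(rng_panel, cfg, "rs")

    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_outcome)
    beta_x = rng_x.normal(gamma, se_x)

    alpha = np.zeros(cfg.n_snps)
    if cfg.pleiotropy_frac > 0:
        n_pleio = int(round(cfg.pleiotropy_frac * cfg.n_snps))
        which = rng_pleio.choice(cfg.n_snps, size=n_pleio, replace=False)
        alpha[which] = rng_pleio.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_pleio)
    mu_y = cfg.true_theta * gamma + alpha
    beta_y = rng_y.normal(mu_y, se_y)

    exposure = _make_records(ids, chrom, pos, alleles, maf, beta_x, se_x, cfg.n_exposure)
    outcome = _make_records(ids, chrom, pos, alleles, maf, beta_y, se_y, cfg.n_outcome)
    ld = _block_ld(ids, block, cfg.ld_within_r2)
    truth = {
        "theta": cfg.true_theta,
        "maf": maf,
        "gamma": gamma,
        "alpha": alpha,
        "mu_x": gamma,
        "mu_y": mu_y,
        "se_x": se_x,
        "se_y": se_y,
    }
    return exposure, outcome, ld, truth


def simulate_mediation(cfg: SimulationConfig):
    """Exposure/mediator/outcome statistics with a known mediated fraction.

    Two disjoint SNP panels are generated: panel A instruments the exposure
    (effects γ_j), panel B instruments the mediator directly (effects δ_k).
    Effects propagate along the causal chain: at panel A the mediator shows
    θ₁·γ_j and the outcome (direct + θ₁·θ₂)·γ_j; at panel B the outcome
    shows θ₂·δ_k.  The implied total effect direct + θ₁·θ₂ and the true
    proportion mediated are stored in ``truth``.

    Returns a dict with per-panel record lists keyed
    ``exposure_A, mediator_A, outcome_A, mediator_B, outcome_B``, the two
    LD matrices, and ``truth``.
    """
    rng_pa, rng_pb, rng_xa, rng_ma, rng_ya, rng_mb, rng_yb = _spawn(cfg.seed, 7)
    ids_a, chrom_a, pos_a, all_a, maf_a, gamma, block_a = _panel(rng_pa, cfg, "rsA")
    ids_b, chrom_b, pos_b, all_b, maf_b, delta, block_b = _panel(rng_pb, cfg, "rsB")

    total = cfg.direct + cfg.theta1 * cfg.theta2

    se_xa = 1.0 / np.sqrt(2.0 * maf_a * (1.0 - maf_a) * cfg.n_exposure)
    se_ma = 1.0 / np.sqrt(2.0 * maf_a * (1.0 - maf_a) * cfg.n_mediator)
    se_ya = 1.0 / np.sqrt(2.0 * maf_a * (1.0 - maf_a) * cfg.n_outcome)
    se_mb = 1.0 / np.sqrt(2.0 * maf_b * (1.0 - maf_b) * cfg.n_mediator)
    se_yb = 1.0 / np.sqrt(2.0 * maf_b * (1.0 - maf_b) * cfg.n_outcome)

    beta_xa = rng_xa.normal(gamma, se_xa)
    beta_ma = rng_ma.normal(cfg.theta1 * gamma, se_ma)
    beta_ya = rng_ya.normal(total * gamma, se_ya)
    beta_mb = rng_mb.normal(delta, se_mb)
    beta_yb = rng_yb.normal(cfg.theta2 * delta, se_yb)

    data = {
        "exposure_A": _make_records(ids_a, chrom_a, pos_a, all_a, maf_a, beta_xa, se_xa, cfg.n_exposure),
        "mediator_A": _make_records(ids_a, chrom_a, pos_a, all_a, maf_a, beta_ma, se_ma, cfg.n_mediator),
        "outcome_A": _make_records(ids_a, chrom_a, pos_a, all_a, maf_a, beta_ya, se_ya, cfg.n_outcome),
        "mediator_B": _make_records(ids_b, chrom_b, pos_b, all_b, maf_b, beta_mb, se_mb, cfg.n_mediator),
        "outcome_B": _make_records(ids_b, chrom_b, pos_b, all_b, maf_b, beta_yb, se_yb, cfg.n_outcome),
    }
    ld = {
        "A": _block_ld(ids_a, block_a, cfg.ld_within_r2),
        "B": _block_ld(ids_b, block_b, cfg.ld_within_r2),
    }
    truth = {
        "theta1": cfg.theta1,
        "theta2": cfg.theta2,
        "direct": cfg.direct,
        "total": total,
        "indirect": cfg.theta1 * cfg.theta2,
        "proportion_pct": (100.0 * cfg.theta1 * cfg.theta2 / total) if total != 0 else None,
        "proportion_defined": total != 0,
        "gamma": gamma,
        "delta": delta,
    }
    return data, ld, truth


@dataclass(frozen=True)
class OmicsSimConfig:
    """Block-correlated taxon/metabolite tables with case/control shifts.

    ``planted_pairs`` lists (taxon_index, metabolite_index, target_r); each
    planted pair shares a latent factor scaled so its expected sample
    correlation equals target_r.  ``group_effect`` shifts planted features
    between the two groups (gallstone vs control), emulating
    disease-associated taxa and metabolites.
    """

    seed: int = 0
    n_per_group: int = 8
    n_taxa: int = 12
    n_metabolites: int = 15
    planted_pairs: tuple[tuple[int, int, float], ...] = ((0, 0, -0.85), (1, 1, 0.85))
    group_effect: float = 1.5

    def __post_init__(self) -> None:
        if self.n_per_group < 2 or self.n_taxa < 1 or self.n_metabolites < 1:
            raise ValidationError("omics sizes too small")
        for ti, mi, r in self.planted_pairs:
            if not (0 <= ti < self.n_taxa and 0 <= mi < self.n_metabolites):
                raise ValidationError(f"planted pair ({ti},{mi}) out of range")
            if abs(r) >= 1.0:
                raise ValidationError(f"target |r| must be < 1, got {r}")


def simulate_omics(cfg: OmicsSimConfig):
    """Two OmicsTables (taxa, metabolites) with planted correlations.

    A planted pair with target r shares a latent standard-normal factor z:
    taxon = sqrt(|r|)·z + sqrt(1−|r|)·e₁ and metabolite =
    sign(r)·sqrt(|r|)·z + sqrt(1−|r|)·e₂, giving expected correlation r.
    Non-planted features are independent noise.  Returns
    ``(taxa_table, metabolite_table, labels, truth)``.
    """
    from .integration import OmicsTable  # local import avoids a cycle at module load

    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_per_group
    labels = ["control"] * cfg.n_per_group + ["gallstone"] * cfg.n_per_group
    group = np.array([0] * cfg.n_per_group + [1] * cfg.n_per_group, dtype=float)

    taxa = rng.normal(size=(n, cfg.n_taxa))
    metab = rng.normal(size=(n, cfg.n_metabolites))
    shift = cfg.group_effect * (group - 0.5)
    for ti, mi, r in cfg.planted_pairs:
        z = rng.normal(size=n)
        a = np.sqrt(abs(r))
        b = np.sqrt(1.0 - abs(r))
        taxa[:, ti] = a * z + b * rng.normal(size=n)
        metab[:, mi] = np.sign(r) * a * z + b * rng.normal(size=n)
        # planted taxa are "protective" (lower in gallstone); the paired
        # metabolite shifts coherently with the planted correlation sign
        taxa[:, ti] -= shift
        metab[:, mi] -= np.sign(r) * shift

    sample_ids = [f"S{i + 1}" for i in range(n)]
    taxa_table = OmicsTable(
        sample_ids=sample_ids,
        feature_ids=[f"taxon_{j + 1}" for j in range(cfg.n_taxa)],
        values=taxa,
        feature_kind="taxon",
    )
    metab_table = OmicsTable(
        sample_ids=sample_ids,
        feature_ids=[f"metab_{j + 1}" for j in range(cfg.n_metabolites)],
        values=metab,
        feature_kind="metabolite",
    )
    truth = {
        "planted_pairs": [
            (taxa_table.feature_ids[ti], metab_table.feature_ids[mi], r)
            for ti, mi, r in cfg.planted_pairs
        ],
        "labels": labels,
        "group_effect": cfg.group_effect,
    }
    return taxa_table, metab_table, labels, truth
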