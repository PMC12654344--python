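"""Study-shaped workflow orchestration from a single declarative config.

``run_pipeline`` wires the library stages together the way the full
analysis runs: select instruments (p-value tier → LD clumping → F ≥ 10 →
confounder screen), harmonize onto the outcome, run the MR battery per
link, decompose mediation when a mediator is configured, and optionally
pool a study table (meta-analysis) and correlate omics tables
(integration).  Every filter records input/kept/removed counts in a
machine-readable run log, and all outputs are TSV/JSON files listed in the
returned manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import instruments as ivqc
from . import integration, mediation, meta_analysis, mr_engine, summary_io
from .errors import MedaxError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration; defaults mirror the study thresholds."""

    # input files (TSV); mediator/meta/omics stages run only when configured
    exposure: str | None = None
    outcome: str | None = None
    mediator: str | None = None
    ld_exposure: str | None = None
    ld_mediator: str | None = None
    ld_outcome: str | None = None
    confounders: str | None = None
    meta_table: str | None = None
    taxa_table: str | None = None
    metabolite_table: str | None = None

    # selection thresholds
    exposure_p: float = 1e-5
    mediator_p: float = 5e-6
    outcome_p: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    palindrome_maf: float = 0.3
    f_min: float = 10.0
    alpha: float = 0.05

    # estimator settings
    ivw_variant: str = "multiplicative_random"
    n_boot: int = 1000
    presso_sims: int = 1000
    tau2_method: str = "DL"
    correlation_method: str = "spearman"
    r_min: float = 0.7
    mantel_permutations: int = 999

    seed: int = 0
    output_dir: str = "medax_out"

    def validate(self) -> None:
        if not (0 < self.exposure_p <= 1 and 0 < self.mediator_p <= 1 and 0 < self.outcome_p <= 1):
            raise ValidationError("p-value thresholds must lie in (0,1]")
        if not (0 <= self.palindrome_maf <= 0.5):
            raise ValidationError("palindrome_maf must lie in [0,0.5]")
        if self.f_min < 0 or self.clump_r2 < 0 or self.clump_window_kb <= 0:
            raise ValidationError("thresholds out of range")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


class PipelineError(MedaxError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"pipeline aborted at stage {stage!r}: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


def _prepare_instruments(
    records, ld, confounders, p_threshold, cfg: PipelineConfig, run_log: list, stage: str
):
    """Selection → clumping → F filter → confounder screen, with counts."""

    def note(step, before, after):
        run_log.append(
            {"stage": f"{stage}:{step}", "in": len(before), "kept": len(after),
             "removed": len(before) - len(after)}
        )
        assert len(before) == len(after) + (len(before) - len(after))

    selected = ivqc.select_by_pvalue(records, p_threshold)
    note("select_by_pvalue", records, selected)
    if ld is not None:
        clumped = ivqc.clump(selected, ld, cfg.clump_r2, cfg.clump_window_kb)
    else:
        clumped = selected
    note("clump", selected, clumped)
    strong, fstats = ivqc.filter_weak_instruments(clumped, cfg.f_min)
    note("f_filter", clumped, strong)
    screened = ivqc.screen_confounders(strong, confounders) if confounders is not None else strong
    note("confounder_screen", strong, screened)
    fstats = {k: v for k, v in fstats.items() if k in {r.snp_id for r in screened}}
    return screened, fstats


def _harmonized_set(name_x, name_y, selected, fstats, outcome_records, cfg):
    pairs = summary_io.harmonize(selected, outcome_records, cfg.palindrome_maf)
    kept = {p.snp_id for p in pairs}
    return ivqc.InstrumentSet(
        exposure_name=name_x,
        outcome_name=name_y,
        pairs=pairs,
        f_statistics={k: v for k, v in fstats.items() if k in kept},
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every configured stage; returns a manifest of output files.

    Deterministic given the config (the seed covers all stochastic
    estimators).  Any stage failure raises :class:`PipelineError` carrying
    the partial manifest.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}
    run_log: list[dict] = []
    stage = "setup"

    def fail(exc: Exception):
        raise PipelineError(stage, manifest, exc) from exc

    battery_kwargs = dict(
        n_boot=cfg.n_boot, presso_sims=cfg.presso_sims, ivw_variant=cfg.ivw_variant
    )
    try:
        batteries: dict[str, mr_engine.BatteryReport] = {}

        if cfg.exposure and cfg.outcome:
            stage = "read_inputs"
            exposure = summary_io.read_summary_stats(cfg.exposure)
            outcome = summary_io.read_summary_stats(cfg.outcome)
            ld_exp = ivqc.LDMatrix.read_tsv(cfg.ld_exposure) if cfg.ld_exposure else None
            conf = ivqc.read_confounder_table(cfg.confounders) if cfg.confounders else None

            stage = "instruments_exposure"
            sel_x, f_x = _prepare_instruments(
                exposure, ld_exp, conf, cfg.exposure_p, cfg, run_log, stage
            )
            if not sel_x:
                fail(ValidationError("0 instruments survive exposure selection"))
            summary_io.write_summary_stats(sel_x, outdir / "instruments_exposure.tsv")
            manifest["instruments_exposure"] = str(outdir / "instruments_exposure.tsv")

            stage = "mr_exposure_outcome"
            iset = _harmonized_set("exposure", "outcome", sel_x, f_x, outcome, cfg)
            run_log.append(
                {"stage": f"{stage}:harmonize", "in": len(sel_x), "kept": iset.n_snp,
                 "removed": len(sel_x) - iset.n_snp}
            )
            if iset.n_snp == 0:
                fail(ValidationError("0 instruments survive harmonization"))
            rep = mr_engine.run_battery(iset, alpha=cfg.alpha, seed=cfg.seed, **battery_kwargs)
            batteries["exposure_outcome"] = rep
            rep.to_frame().to_csv(outdir / "mr_exposure_outcome.tsv", sep="\t", index=False)
            rep.to_json(outdir / "mr_exposure_outcome.json")
            manifest["mr_exposure_outcome"] = str(outdir / "mr_exposure_outcome.tsv")

            if cfg.ld_outcome:
                stage = "mr_reverse"
                ld_out = ivqc.LDMatrix.read_tsv(cfg.ld_outcome)
                sel_rev, f_rev = _prepare_instruments(
                    outcome, ld_out, conf, cfg.outcome_p, cfg, run_log, stage
                )
                rev_set = (
                    _harmonized_set("outcome", "exposure", sel_rev, f_rev, exposure, cfg)
                    if sel_rev
                    else None
                )
                bidir = mr_engine.bidirectional(
                    iset, rev_set, alpha=cfg.alpha, seed=cfg.seed, **battery_kwargs
                )
                with open(outdir / "bidirectional.json", "w") as fh:
                    json.dump(
                        {
                            "interpretation": bidir.interpretation,
                            "forward": bidir.forward.to_dict() if bidir.forward else None,
                            "reverse": bidir.reverse.to_dict() if bidir.reverse else None,
                        },
                        fh, indent=2,
                    )
                manifest["bidirectional"] = str(outdir / "bidirectional.json")

            if cfg.mediator:
                stage = "mediation"
                mediator = summary_io.read_summary_stats(cfg.mediator)
                m_set = _harmonized_set("exposure", "mediator", sel_x, f_x, mediator, cfg)
                rep1 = mr_engine.run_battery(
                    m_set, alpha=cfg.alpha, seed=cfg.seed + 1, **battery_kwargs
                )
                batteries["exposure_mediator"] = rep1

                ld_med = ivqc.LDMatrix.read_tsv(cfg.ld_mediator) if cfg.ld_mediator else None
                sel_m, f_m = _prepare_instruments(
                    mediator, ld_med, conf, cfg.mediator_p, cfg, run_log, stage
                )
                # keep the two steps' instruments disjoint: a SNP already
                # instrumenting the exposure would re-route the exposure's
                # direct path through the mediator link
                exposure_ids = {r.snp_id for r in sel_x}
                before = sel_m
                sel_m = [r for r in sel_m if r.snp_id not in exposure_ids]
                run_log.append(
                    {"stage": f"{stage}:disjoint_from_exposure", "in": len(before),
                     "kept": len(sel_m), "removed": len(before) - len(sel_m)}
                )
                if not sel_m:
                    fail(ValidationError("0 instruments survive mediator selection"))
                m_out = _harmonized_set("mediator", "outcome", sel_m, f_m, outcome, cfg)
                rep2 = mr_engine.run_battery(
                    m_out, alpha=cfg.alpha, seed=cfg.seed + 2, **battery_kwargs
                )
                batteries["mediator_outcome"] = rep2
                for key in ("exposure_mediator", "mediator_outcome"):
                    batteries[key].to_frame().to_csv(outdir / f"mr_{key}.tsv", sep="\t", index=False)
                    batteries[key].to_json(outdir / f"mr_{key}.json")
                    manifest[f"mr_{key}"] = str(outdir / f"mr_{key}.tsv")

                two = mediation.two_step(rep1, rep2, rep)
                rows = {}
                if two.result is not None:
                    rows["exposure->mediator->outcome"] = two.result
                table = mediation.mediation_table(rows) if rows else pd.DataFrame(
                    [{"PATHWAY": "exposure->mediator->outcome", "ELIGIBLE": False,
                      "STEP1_RELIABLE": two.step1_reliable, "STEP2_RELIABLE": two.step2_reliable}]
                )
                table.to_csv(outdir / "mediation.tsv", sep="\t", index=False)
                manifest["mediation"] = str(outdir / "mediation.tsv")

        if cfg.meta_table:
            stage = "meta_analysis"
            studies = meta_analysis.read_study_table(cfg.meta_table)
            res = meta_analysis.pool_random_effects(studies, cfg.tau2_method)
            meta_analysis.forest_table(studies, res).to_csv(
                outdir / "meta_forest.tsv", sep="\t", index=False
            )
            manifest["meta_forest"] = str(outdir / "meta_forest.tsv")
            run_log.append({"stage": "meta_analysis", "n_studies": res.n_studies,
                            "pooled_or": res.pooled_or, "i2_pct": res.i2})

        if cfg.taxa_table and cfg.metabolite_table:
            stage = "integration"
            taxa = integration.OmicsTable.from_frame(
                pd.read_csv(cfg.taxa_table, sep="\t", index_col=0), "taxon"
            )
            metab = integration.OmicsTable.from_frame(
                pd.read_csv(cfg.metabolite_table, sep="\t", index_col=0), "metabolite"
            )
            corr = integration.correlate(
                taxa, metab, method=cfg.correlation_method, r_min=cfg.r_min, alpha=cfg.alpha
            )
            corr.table.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
            manifest["correlations"] = str(outdir / "correlations.tsv")
            mres = integration.mantel(
                integration.euclidean_distance(taxa),
                integration.euclidean_distance(metab),
                n_perm=cfg.mantel_permutations,
                seed=cfg.seed,
            )
            with open(outdir / "mantel.json", "w") as fh:
                json.dump(dataclasses.asdict(mres), fh, indent=2)
            manifest["mantel"] = str(outdir / "mantel.json")

        stage = "finalize"
        with open(outdir / "run_log.json", "w") as fh:
            json.dump({"config": dataclasses.asdict(cfg), "filters": run_log}, fh, indent=2)
        manifest["run_log"] = str(outdir / "run_log.json")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - abort carries stage + manifest
        raise PipelineError(stage, manifest, exc) from exc
    return manifest
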