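"""Workflow orchestration: screen -> MVMR -> gated mediation, with report tables.

``run_univariable_screen`` runs, for every exposure trait against the
outcome: instrument selection (p-threshold, clumping, F filter), the five
univariable estimators, heterogeneity and pleiotropy diagnostics,
leave-one-out and the Steiger directionality test, flagging traits whose
primary IVW estimate is significant.  ``run_mvmr_mediation`` then pairs
each flagged trait with the mediator trait: univariable MR of trait ->
mediator, a two-exposure MVMR against the outcome, and the gated two-step
mediation decomposition.

The primary estimator is random-effects IVW (its multiplicative inflation
reduces to the fixed-effects model in the absence of excess heterogeneity);
when the Egger intercept is significant the Egger slope is flagged as the
preferred causal estimate.  Raw p < level across traits by default, with an
optional Benjamini-Hochberg flag.

All emitted numbers come straight from the module operations; the report
tables are views, never the place where anything is computed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimators import MREstimate, ivw, to_odds_ratio
from .instruments import InstrumentSet, LDMatrix, select_instruments
from .mediation import MediationCandidate, MediationResult, gate_models, two_step_mediation
from .model import FIVE_METHODS, MRModel, MVMRModel
from .mvmr import build_mvmr_input
from .sensitivity import HeterogeneityResult, PleiotropyResult, SteigerResult
from .simulate import SimulationConfig, simulate
from .sumstats import SumStatRecord, harmonize, read_sumstats

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, estimator settings and input locations for a full run."""

    exposure_paths: dict[str, str] = field(default_factory=dict)
    mediator_path: str | None = None
    mediator_label: str = "mediator"
    outcome_path: str | None = None
    outcome_label: str = "outcome"
    ld_path: str | None = None
    column_map: dict[str, str] | None = None
    synthetic: dict | None = None  # SimulationConfig fields; replaces file inputs
    p_threshold: float = 1e-5
    r2_threshold: float = 0.001
    window_kb: float = 10_000
    f_min: float = 10.0
    level: float = 0.05
    n_boot: int = 1000
    phi: float = 1.0
    seed: int = 0
    i2_convention: str = "standard"
    palindromic_eaf_window: float = 0.08
    fdr: bool = False
    out_dir: str = "medmr_output"

    def __post_init__(self):
        if not (0 < self.level < 1):
            raise ValueError("significance level must be in (0,1)")
        for name in ("p_threshold", "window_kb", "f_min"):
            if getattr(self, name) < 0 or (name != "f_min" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class TaxonScreenResult:
    """Everything the univariable screen produced for one exposure trait."""

    label: str
    instruments: InstrumentSet
    model: MRModel
    estimates: dict[str, MREstimate]
    primary: MREstimate
    heterogeneity: HeterogeneityResult
    pleiotropy: PleiotropyResult
    steiger: SteigerResult | None
    leave_one_out: object
    significant: bool
    egger_preferred: bool
    pval_adjusted: float | None = None
    error: str | None = None


@dataclass
class ScreenResults:
    taxa: list[TaxonScreenResult]
    failures: list[tuple[str, str]]

    @property
    def significant(self) -> list[TaxonScreenResult]:
        return [t for t in self.taxa if t.significant]


def _spawn_seed(base_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(base_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def load_inputs(config: PipelineConfig):
    """Resolve file or synthetic inputs into record lists (exposures, mediator, outcome, ld)."""
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        n_taxa = int(syn.pop("n_taxa", 1))
        n_causal = int(syn.pop("n_causal", n_taxa))
        base = SimulationConfig.from_dict({**syn, "seed": syn.get("seed", config.seed)})
        exposures, mediator, outcome = simulate_panel(base, n_taxa=n_taxa, n_causal=n_causal)
        return exposures, mediator, outcome, None
    exposures = {
        label: read_sumstats(p, config.column_map, trait_label=label)
        for label, p in config.exposure_paths.items()
    }
    mediator = (
        read_sumstats(config.mediator_path, config.column_map, trait_label=config.mediator_label)
        if config.mediator_path
        else None
    )
    if not config.outcome_path:
        raise ValueError("outcome_path is required for file-based runs")
    outcome = read_sumstats(config.outcome_path, config.column_map, trait_label=config.outcome_label)
    ld = LDMatrix.read_tsv(config.ld_path) if config.ld_path else None
    return exposures, mediator, outcome, ld


def simulate_panel(base: SimulationConfig, n_taxa: int, n_causal: int):
    """Simulate a multi-taxon exposure panel sharing one mediator and outcome.

    The first ``n_causal`` taxa carry the configured causal chain; the rest
    are null exposures (their instruments predict the taxon only).  Each
    taxon gets an independent SNP panel; the mediator/outcome tables are the
    union over panels, which keeps each taxon's screen independent while
    sharing the downstream traits.
    """
    exposures: dict[str, list[SumStatRecord]] = {}
    mediator: list[SumStatRecord] = []
    outcome: list[SumStatRecord] = []
    for i in range(n_taxa):
        causal = i < n_causal
        cfg = base.replace(
            seed=_spawn_seed(base.seed, 7, i),
            true_alpha=base.true_alpha if causal else 0.0,
            true_beta1=base.true_beta1 if causal else 0.0,
        )
        ds = simulate(cfg)
        prefix = f"t{i}_"
        for rec_list, sink in ((ds.mediator, mediator), (ds.outcome, outcome)):
            for r in rec_list:
                r.snp_id = prefix + r.snp_id
                sink.append(r)
        for r in ds.exposure:
            r.snp_id = prefix + r.snp_id
        exposures[f"taxon_{i}"] = ds.exposure
    return exposures, mediator, outcome


def screen_one(
    label: str,
    exposure_records: list[SumStatRecord],
    outcome_records: list[SumStatRecord],
    config: PipelineConfig,
    ld: LDMatrix | None = None,
    seed: int | None = None,
) -> TaxonScreenResult:
    """Instrument selection, five estimators and the diagnostic suite for one trait."""
    inst = select_instruments(
        exposure_records,
        p_threshold=config.p_threshold,
        ld=ld,
        r2_threshold=config.r2_threshold,
        window_kb=config.window_kb,
        f_min=config.f_min,
    )
    model = MRModel.from_records(
        inst.records,
        outcome_records,
        palindromic_eaf_window=config.palindromic_eaf_window,
        exposure=label,
        outcome=config.outcome_label,
    )
    seed = seed if seed is not None else config.seed
    fits = model.fit_all(n_boot=config.n_boot, seed=seed, phi=config.phi)
    estimates = {m: fits[m].estimate for m in FIVE_METHODS}
    primary = estimates["ivw_random"]
    het = model.heterogeneity(i2_convention=config.i2_convention)
    pleio = model.pleiotropy_test()
    try:
        st = model.steiger()
    except ValueError:
        st = None
    loo = model.leave_one_out()
    return TaxonScreenResult(
        label=label,
        instruments=inst,
        model=model,
        estimates=estimates,
        primary=primary,
        heterogeneity=het,
        pleiotropy=pleio,
        steiger=st,
        leave_one_out=loo,
        significant=bool(primary.pval < config.level),
        egger_preferred=bool(pleio.pval < config.level),
    )


def run_univariable_screen(
    exposures: dict[str, list[SumStatRecord]],
    outcome: list[SumStatRecord],
    config: PipelineConfig,
    ld: LDMatrix | None = None,
) -> ScreenResults:
    """Screen every exposure trait against the outcome; flag significant taxa."""
    taxa: list[TaxonScreenResult] = []
    failures: list[tuple[str, str]] = []
    for i, (label, records) in enumerate(exposures.items()):
        try:
            taxa.append(
                screen_one(label, records, outcome, config, ld=ld, seed=_spawn_seed(config.seed, 1, i))
            )
        except ValueError as exc:
            logger.warning("screen failed for %s: %s", label, exc)
            failures.append((label, str(exc)))
    if config.fdr and taxa:
        # Benjamini-Hochberg on the primary p-values (off by default)
        p = np.array([t.primary.pval for t in taxa])
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank, idx in enumerate(order[::-1]):
            running = min(running, p[idx] * m / (m - rank))
            adj[idx] = running
        for t, a in zip(taxa, adj):
            t.pval_adjusted = float(a)
            t.significant = bool(a < config.level)
    return ScreenResults(taxa=taxa, failures=failures)


@dataclass
class MediationRun:
    """MVMR + mediation outputs for the flagged taxa."""

    alpha_estimates: list[TaxonScreenResult]  # taxon -> mediator univariable runs
    mvmr_frames: list[pd.DataFrame]
    mediation_results: list[MediationResult]
    excluded: list[tuple[str, str]]
    skipped: list[tuple[str, str]]


def run_mvmr_mediation(
    screened: ScreenResults,
    exposures: dict[str, list[SumStatRecord]],
    mediator: list[SumStatRecord],
    config: PipelineConfig,
    mediator_selected: list[SumStatRecord] | None = None,
) -> MediationRun:
    """For each flagged taxon: taxon->mediator MR, two-exposure MVMR, gated mediation."""
    med_label = config.mediator_label
    if mediator_selected is None:
        mediator_selected = select_instruments(
            mediator,
            p_threshold=config.p_threshold,
            r2_threshold=config.r2_threshold,
            window_kb=config.window_kb,
            f_min=config.f_min,
        ).records

    alpha_runs: list[TaxonScreenResult] = []
    mvmr_frames: list[pd.DataFrame] = []
    candidates: list[MediationCandidate] = []
    skipped: list[tuple[str, str]] = []
    for i, taxon in enumerate(screened.significant):
        label = taxon.label
        try:
            # univariable taxon -> mediator MR (the alpha leg), own diagnostics
            alpha_cfg_seed = _spawn_seed(config.seed, 2, i)
            alpha_run = screen_one(
                label, exposures[label], mediator, config, seed=alpha_cfg_seed
            )
            alpha_run = _relabel_outcome(alpha_run, med_label)
            alpha_runs.append(alpha_run)
            # two-exposure MVMR against the outcome
            mv = MVMRModel.from_exposures(
                [
                    (label, taxon.instruments.records, exposures[label]),
                    (med_label, mediator_selected, mediator),
                ],
                outcome_records=_outcome_records_of(taxon),
                outcome=config.outcome_label,
                palindromic_eaf_window=config.palindromic_eaf_window,
            ).fit()
            frame = mv.to_frame()
            frame.insert(0, "model", f"model_{i + 1}")
            mvmr_frames.append(frame)
            candidates.append(
                MediationCandidate(
                    exposure=label,
                    mediator=med_label,
                    outcome=config.outcome_label,
                    total=taxon.primary,
                    exp_to_med=alpha_run.primary,
                    med_to_out=mv.effect(med_label),
                )
            )
        except (ValueError, KeyError) as exc:
            logger.warning("MVMR/mediation skipped for %s: %s", label, exc)
            skipped.append((label, str(exc)))
    results, excluded = gate_models(candidates, gate_level=config.level)
    return MediationRun(
        alpha_estimates=alpha_runs,
        mvmr_frames=mvmr_frames,
        mediation_results=results,
        excluded=excluded,
        skipped=skipped,
    )


def _relabel_outcome(run: TaxonScreenResult, outcome_label: str) -> TaxonScreenResult:
    run.model.outcome = outcome_label
    return run


_OUTCOME_CACHE_ATTR = "_outcome_records"


def _outcome_records_of(taxon: TaxonScreenResult):
    recs = getattr(taxon, _OUTCOME_CACHE_ATTR, None)
    if recs is None:
        raise KeyError("outcome records not attached to screen result")
    return recs


# ----------------------------------------------------------------------------
# Report tables (column layouts mirror the study's published tables)
# ----------------------------------------------------------------------------

def instrument_strength_table(results: ScreenResults) -> pd.DataFrame:
    rows = []
    for t in results.taxa:
        med, lo, hi = t.instruments.f_summary()
        rows.append(
            {"exposure": t.label, "nsnp": t.instruments.nsnp,
             "median_f": med, "min_f": lo, "max_f": hi}
        )
    return pd.DataFrame(rows)


def estimates_table(results: ScreenResults, outcome_label: str, methods=FIVE_METHODS) -> pd.DataFrame:
    rows = []
    for t in results.taxa:
        for m in methods:
            e = t.estimates[m]
            orv = to_odds_ratio(e)
            rows.append(
                {"exposure": t.label, "outcome": outcome_label, "method": m,
                 "nsnp": e.nsnp, "beta": e.beta, "se": e.se, "pval": e.pval,
                 "or": orv.or_point, "or_ci_low": orv.ci_low, "or_ci_high": orv.ci_high}
            )
    return pd.DataFrame(rows)


def steiger_table(results: ScreenResults, outcome_label: str) -> pd.DataFrame:
    rows = []
    for t in results.taxa:
        if t.steiger is None:
            continue
        rows.append(
            {"exposure": t.label, "outcome": outcome_label,
             "r2_exposure": t.steiger.r2_exposure, "r2_outcome": t.steiger.r2_outcome,
             "correct_direction": t.steiger.correct_direction, "steiger_pval": t.steiger.pval}
        )
    return pd.DataFrame(rows)


def heterogeneity_table(results: ScreenResults, outcome_label: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"exposure": t.label, "outcome": outcome_label, "q": t.heterogeneity.q,
             "q_df": t.heterogeneity.df, "q_pval": t.heterogeneity.pval,
             "i2_pct": t.heterogeneity.i2}
            for t in results.taxa
        ]
    )


def pleiotropy_table(results: ScreenResults, outcome_label: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"exposure": t.label, "outcome": outcome_label,
             "egger_intercept": t.pleiotropy.intercept, "se": t.pleiotropy.se,
             "pval": t.pleiotropy.pval}
            for t in results.taxa
        ]
    )


def leave_one_out_table(results: ScreenResults) -> pd.DataFrame:
    rows = []
    for t in results.taxa:
        for snp, e in t.leave_one_out.rows:
            rows.append(
                {"exposure": t.label, "excluded_snp": snp, "beta": e.beta,
                 "se": e.se, "pval": e.pval}
            )
        full = t.leave_one_out.full
        rows.append(
            {"exposure": t.label, "excluded_snp": "<none>", "beta": full.beta,
             "se": full.se, "pval": full.pval}
        )
    return pd.DataFrame(rows)


_MEDIATION_COLUMNS = [
    "model", "exposure", "mediator", "outcome",
    "alpha", "alpha_lo", "alpha_hi", "beta2", "beta2_lo", "beta2_hi",
    "indirect", "indirect_lo", "indirect_hi", "direct", "direct_lo", "direct_hi",
    "total", "total_lo", "total_hi",
    "proportion_pct", "proportion_lo", "proportion_hi", "sign_consistent",
]


def mediation_table(run: MediationRun) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(run.mediation_results):
        def _ci(name):
            c = r.ci[name]
            return (np.nan, np.nan) if c is None else c

        rows.append(
            {
                "model": f"model_{i + 1}",
                "exposure": r.exposure, "mediator": r.mediator, "outcome": r.outcome,
                "alpha": r.alpha, "alpha_lo": _ci("alpha")[0], "alpha_hi": _ci("alpha")[1],
                "beta2": r.beta2, "beta2_lo": _ci("beta2")[0], "beta2_hi": _ci("beta2")[1],
                "indirect": r.indirect, "indirect_lo": _ci("indirect")[0],
                "indirect_hi": _ci("indirect")[1],
                "direct": r.direct, "direct_lo": _ci("direct")[0], "direct_hi": _ci("direct")[1],
                "total": r.total_beta, "total_lo": _ci("total")[0], "total_hi": _ci("total")[1],
                "proportion_pct": np.nan if r.proportion_pct is None else r.proportion_pct,
                "proportion_lo": _ci("proportion")[0], "proportion_hi": _ci("proportion")[1],
                "sign_consistent": r.sign_consistent,
            }
        )
    return pd.DataFrame(rows, columns=_MEDIATION_COLUMNS)


def mediation_chain_run(
    sim_config: SimulationConfig,
    pipeline_config: PipelineConfig | None = None,
) -> MediationResult:
    """Run the full chain analysis on one synthetic dataset.

    Selects exposure instruments, estimates the total effect and the
    exposure -> mediator effect by random-effects IVW, fits the two-exposure
    MVMR for the mediator's conditional effect on the outcome, and returns
    the two-step mediation decomposition (its ``significant_gate`` flag says
    whether the pipeline would interpret it).
    """
    cfg = pipeline_config or PipelineConfig()
    ds = simulate(sim_config)
    ei = select_instruments(
        ds.exposure, p_threshold=cfg.p_threshold, r2_threshold=cfg.r2_threshold,
        window_kb=cfg.window_kb, f_min=cfg.f_min,
    )
    total = ivw(harmonize(ei.records, ds.outcome, cfg.palindromic_eaf_window), "random")
    alpha = ivw(harmonize(ei.records, ds.mediator, cfg.palindromic_eaf_window), "random")
    mi = select_instruments(
        ds.mediator, p_threshold=cfg.p_threshold, r2_threshold=cfg.r2_threshold,
        window_kb=cfg.window_kb, f_min=cfg.f_min,
    )
    mv = MVMRModel(
        build_mvmr_input(
            [("exposure", ei.records, ds.exposure), ("mediator", mi.records, ds.mediator)],
            ds.outcome,
            cfg.palindromic_eaf_window,
        ),
        outcome="outcome",
    ).fit()
    return two_step_mediation(
        total, alpha, mv.effect("mediator"), gate_level=cfg.level,
        exposure="exposure", mediator="mediator", outcome="outcome",
    )


def run_all(config: PipelineConfig) -> dict:
    """Full workflow; writes report TSVs and a JSON manifest, returns the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exposures, mediator, outcome, ld = load_inputs(config)

    screened = run_univariable_screen(exposures, outcome, config, ld=ld)
    for t in screened.taxa:  # attach outcome records for the MVMR stage
        setattr(t, _OUTCOME_CACHE_ATTR, outcome)

    tables = {
        "instrument_strength": instrument_strength_table(screened),
        "estimates": estimates_table(screened, config.outcome_label),
        "steiger": steiger_table(screened, config.outcome_label),
        "heterogeneity": heterogeneity_table(screened, config.outcome_label),
        "pleiotropy": pleiotropy_table(screened, config.outcome_label),
        "leave_one_out": leave_one_out_table(screened),
    }
    mediation_run = None
    if mediator is not None and screened.significant:
        mediation_run = run_mvmr_mediation(screened, exposures, mediator, config)
        alpha_screen = ScreenResults(taxa=mediation_run.alpha_estimates, failures=[])
        tables["exposure_mediator_estimates"] = estimates_table(
            alpha_screen, config.mediator_label, methods=("ivw_random",)
        )
        tables["exposure_mediator_steiger"] = steiger_table(alpha_screen, config.mediator_label)
        tables["mvmr"] = (
            pd.concat(mediation_run.mvmr_frames, ignore_index=True)
            if mediation_run.mvmr_frames
            else pd.DataFrame(columns=["model", "exposure", "outcome", "beta", "se", "pval", "nsnp"])
        )
        tables["mediation"] = mediation_table(mediation_run)
    elif mediator is not None:
        logger.warning("no significant taxa: MVMR/mediation stage produced empty tables")
        tables["mvmr"] = pd.DataFrame(columns=["model", "exposure", "outcome", "beta", "se", "pval", "nsnp"])
        tables["mediation"] = mediation_table(MediationRun([], [], [], [], []))

    manifest = {
        "seed": config.seed,
        "significance_level": config.level,
        "n_exposures": len(exposures),
        "n_significant": len(screened.significant),
        "significant": [t.label for t in screened.significant],
        "failures": screened.failures,
        "tables": {},
    }
    if mediation_run is not None:
        manifest["mediation_models"] = len(mediation_run.mediation_results)
        manifest["mediation_excluded"] = mediation_run.excluded
        manifest["mediation_skipped"] = mediation_run.skipped
    for name, frame in tables.items():
        path = out_dir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.6f")
        manifest["tables"][name] = str(path)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
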