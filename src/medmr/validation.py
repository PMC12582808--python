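"""Replicate studies of the pipeline's statistical operating characteristics.

These functions re-run the full analysis path (simulate -> instrument
selection -> harmonization -> estimation) many times under named study
conditions with known ground truth, and summarise frequentist behaviour:
type-I error of the IVW test under the global null, type-I error of the
Egger intercept test under balanced pleiotropy, confidence-interval
coverage under a true effect, recovery of the mediated proportion, and the
Steiger direction rate.  They back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from .estimators import ivw, mr_egger
from .instruments import select_instruments
from .pipeline import mediation_chain_run
from .sensitivity import steiger
from .simulate import (
    SimulationConfig,
    balanced_pleiotropy_null_config,
    null_config,
    paper_scale_effect_config,
    simulate,
    strong_chain_config,
)
from .sumstats import harmonize


def _rep_seeds(seed: int, block: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed, spawn_key=(block,))
    return ss.generate_state(n) % (2**31)


def _screen_ivw(cfg: SimulationConfig):
    ds = simulate(cfg)
    inst = select_instruments(ds.exposure)
    h = harmonize(inst.records, ds.outcome)
    return h, ivw(h, "random")


def ivw_null_rejection(n_reps: int = 500, seed: int = 0, level: float = 0.05):
    """IVW rejection rate when every true causal effect is zero."""
    rej = used = 0
    for s in _rep_seeds(seed, 1, n_reps):
        try:
            _, est = _screen_ivw(null_config(seed=int(s)))
        except ValueError:
            continue
        used += 1
        rej += est.pval < level
    return rej / used, used


def egger_balanced_rejection(n_reps: int = 500, seed: int = 0, level: float = 0.05):
    """Egger-intercept rejection rate under balanced (zero-mean) pleiotropy."""
    rej = used = 0
    for s in _rep_seeds(seed, 2, n_reps):
        ds = simulate(balanced_pleiotropy_null_config(seed=int(s)))
        try:
            inst = select_instruments(ds.exposure)
            h = harmonize(inst.records, ds.outcome)
            if h.nsnp < 3:
                continue
            fit = mr_egger(h)
        except ValueError:
            continue
        used += 1
        rej += fit.intercept_p < level
    return rej / used, used


def ivw_coverage(n_reps: int = 500, seed: int = 0, level: float = 0.95):
    """Coverage of the IVW confidence interval for a true nonzero total effect."""
    from scipy import stats

    z = stats.norm.ppf(0.5 * (1 + level))
    cover = used = 0
    for s in _rep_seeds(seed, 3, n_reps):
        cfg = strong_chain_config(seed=int(s))
        try:
            _, est = _screen_ivw(cfg)
        except ValueError:
            continue
        used += 1
        cover += (est.beta - z * est.se) <= cfg.total_effect <= (est.beta + z * est.se)
    return cover / used, used


def mediation_recovery(n_reps: int = 300, seed: int = 0):
    """Mean mediated proportion the pipeline reports on the true chain.

    Averages the proportions of replicates passing the significance gate
    (the pipeline only interprets mediation for those); also returns the
    worst decomposition-identity error across all replicates.
    """
    props = []
    max_err = 0.0
    used = 0
    for s in _rep_seeds(seed, 4, n_reps):
        cfg = strong_chain_config(seed=int(s))
        try:
            res = mediation_chain_run(cfg)
        except ValueError:
            continue
        used += 1
        err = abs(res.direct + res.indirect - res.total_beta)
        max_err = max(max_err, err / max(1.0, abs(res.total_beta)))
        if res.significant_gate and res.proportion_pct is not None:
            props.append(res.proportion_pct)
    true_prop = 100 * cfg.true_alpha * cfg.true_beta2 / cfg.total_effect
    return {
        "mean_proportion_pct": float(np.mean(props)),
        "true_proportion_pct": float(true_prop),
        "max_identity_error": float(max_err),
        "n_gated": len(props),
        "n_run": used,
    }


def steiger_direction_rate(n_reps: int = 300, seed: int = 0):
    """Fraction of replicates whose Steiger test points exposure -> outcome.

    Uses comparable exposure/outcome sample sizes so the test cannot lean
    on a sample-size imbalance.
    """
    ok = used = 0
    for s in _rep_seeds(seed, 5, n_reps):
        cfg = SimulationConfig(seed=int(s), n_out=18_340)
        ds = simulate(cfg)
        try:
            inst = select_instruments(ds.exposure)
            h = harmonize(inst.records, ds.outcome)
            res = steiger(h)
        except ValueError:
            continue
        used += 1
        ok += res.correct_direction
    return ok / used, used


def steiger_variance_pattern(seed: int = 0):
    """One screen at realistic effect sizes: exposure r2 ~ 1e-2, outcome ~ 1e-5."""
    ds = simulate(paper_scale_effect_config(seed=seed))
    inst = select_instruments(ds.exposure)
    h = harmonize(inst.records, ds.outcome)
    return steiger(h)
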