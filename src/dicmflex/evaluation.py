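"""End-to-end evaluation experiments on synthetic recordings.

These routines wire the generator, the windowed pipeline and the
aggregation/modeling layers into the standard checks of the method:
planted-mode recovery, null calibration of the statistical filtering,
flexibility versus regime-switching rate, and cohort-level model and
classifier recovery.  They are used by the test suite and by the
reproduction script; sizes default to desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .age_modeling import classify_age_groups, compare_groups, fit_fi_age
from .aggregation import flexibility
from .codes import cross_code
from .preprocessing import filterbank, make_windows
from .surrogate_stats import dicm_pipeline
from .synthetic_data import (
    CohortPlan,
    CouplingEntry,
    CouplingPlan,
    feature_columns,
    gen_cohort,
    gen_recording,
    gen_switching_recording,
)


@dataclass
class RecoveryResult:
    recovery_all: float      # fraction of windows with the planted mode retained
    recovery_full: float     # same, over untruncated windows only
    n_windows: int
    n_full_windows: int


def planted_pac_recovery(
    seed: int = 0,
    fs: float = 170.0,
    duration_s: float = 36.0,
    n_surr: int = 200,
    estimators: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> RecoveryResult:
    """Recover a depth-1.0 theta->gamma PAC pair as a retained coupling mode.

    A two-channel recording carries the planted modulation over its whole
    duration; recovery counts the windows whose retained records include
    the (PAC, theta->gamma) mode.
    """
    entry = CouplingEntry((0, 1), "pac", "theta", "gamma", strength=1.0)
    rec = gen_recording(2, fs, duration_s, [entry], seed=seed)
    banded = filterbank(rec)
    scheme = make_windows(rec)
    tensor, _ = dicm_pipeline(banded, scheme, estimators=estimators,
                              n_surr=n_surr, seed=seed + 1)
    code = cross_code("theta", "gamma")
    hit = ((tensor.est == 3) & (tensor.code == code)).any(axis=0)[:, 0]
    full = np.array([s.stop - s.start == int(round(2.0 * fs))
                     for s in scheme.slices()])
    return RecoveryResult(
        recovery_all=float(hit.mean()),
        recovery_full=float(hit[full].mean()),
        n_windows=int(len(hit)),
        n_full_windows=int(full.sum()),
    )


@dataclass
class NullCalibrationResult:
    fdr_retained_fraction: float
    n_window_pairs: int
    n_candidates: int


def null_fdr_calibration(
    seed: int = 0,
    n_channels: int = 3,
    fs: float = 170.0,
    duration_s: float = 36.0,
    n_surr: int = 200,
    q: float = 0.01,
    estimators: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> NullCalibrationResult:
    """FDR retention on channels with no planted coupling.

    Every channel carries an independent background mixture; the returned
    fraction is the share of all surrogate-tested candidates retained by
    Benjamini-Hochberg at level ``q``.
    """
    rec = gen_recording(n_channels, fs, duration_s, None, seed=seed)
    banded = filterbank(rec)
    scheme = make_windows(rec)
    _, diag = dicm_pipeline(banded, scheme, estimators=estimators,
                            n_surr=n_surr, q=q, seed=seed + 1,
                            apply_omst=False)
    n_pairs = n_channels * (n_channels - 1) // 2
    return NullCalibrationResult(
        fdr_retained_fraction=float(diag.fdr_retained_fraction),
        n_window_pairs=scheme.T * n_pairs,
        n_candidates=diag.n_candidates,
    )


def fi_vs_switching_rate(
    seed: int = 0,
    dwells_s: tuple[float, ...] = (12.0, 6.0, 3.0),
    n_reps: int = 10,
    fs: float = 170.0,
    duration_s: float = 24.0,
    n_surr: int = 200,
) -> dict[float, float]:
    """Mean planted-pair flexibility at increasing regime-switching rates.

    Two iPLV regimes (alpha1 vs beta3, constant lag) alternate on one
    channel pair every ``dwell_s`` seconds; the pipeline runs with the
    same-frequency phase estimator and the flexibility of the planted pair
    is averaged over ``n_reps`` replicate recordings per rate.
    """
    modes = [
        CouplingPlan([CouplingEntry((0, 1), "iplv", "alpha1", strength=0.9)]),
        CouplingPlan([CouplingEntry((0, 1), "iplv", "beta3", strength=0.9)]),
    ]
    out: dict[float, float] = {}
    for dwell in dwells_s:
        fis = []
        for rep in range(n_reps):
            rec = gen_switching_recording(
                2, fs, duration_s, modes, dwell_s=dwell,
                seed=seed + 1000 * rep + int(dwell),
            )
            banded = filterbank(rec)
            scheme = make_windows(rec)
            tensor, _ = dicm_pipeline(banded, scheme, estimators=(2,),
                                      n_surr=n_surr, seed=seed + rep)
            fis.append(flexibility(tensor).fi_pairs[0])
        out[float(dwell)] = float(np.mean(fis))
    return out


@dataclass
class CurveRecoveryResult:
    quadratic_win_fraction: float
    n_replicates: int
    noiseless_params: tuple[float, float, float]
    noiseless_max_error: float


def quadratic_age_curve_recovery(
    seed: int = 0,
    n_replicates: int = 100,
    n: int = 178,
) -> CurveRecoveryResult:
    """How often the quadratic family wins AIC on quadratic-curve cohorts.

    Each replicate draws a fresh cohort at the default curve and noise; a
    noiseless cohort checks exact parameter recovery.
    """
    wins = 0
    for rep in range(n_replicates):
        table = gen_cohort(CohortPlan(n=n, n_features=0), seed=seed + rep)
        fits = fit_fi_age(table["age"].to_numpy(), table["fi"].to_numpy())
        wins += fits[0].family == "quadratic"
    clean = gen_cohort(CohortPlan(n=n, noise_sd=0.0, n_features=0), seed=seed)
    fits = fit_fi_age(clean["age"].to_numpy(), clean["fi"].to_numpy())
    quad = next(f for f in fits if f.family == "quadratic")
    truth = np.array(CohortPlan().fi_curve)
    err = float(np.max(np.abs(np.array(quad.params) - truth)))
    return CurveRecoveryResult(
        quadratic_win_fraction=wins / n_replicates,
        n_replicates=n_replicates,
        noiseless_params=tuple(quad.params),
        noiseless_max_error=err,
    )


def age_group_classification(
    seed: int = 0,
    feature_shift: float = 2.0,
    n: int = 178,
    n_repeats: int = 100,
):
    """5-fold multi-class SVM accuracy on a cohort with group-shifted
    features (``feature_shift`` standard deviations between neighbouring
    age groups; 0 gives the chance-level control)."""
    table = gen_cohort(CohortPlan(n=n, feature_shift=feature_shift), seed=seed)
    X = table[feature_columns(table)].to_numpy()
    y = table["age_group"].to_numpy()
    return classify_age_groups(X, y, scheme="5fold", n_repeats=n_repeats,
                               seed=seed)


def clinical_group_power(
    seed: int = 0,
    offset: float = -0.1,
    n_per_group: int = 25,
    noise_sd: float = 0.02,
    n_replicates: int = 100,
    alpha: float = 0.01,
) -> float:
    """Fraction of replicates where a rank-sum test detects a group FI
    deficit of ``offset`` at significance ``alpha``."""
    ages = lambda rng, size: rng.uniform(8, 16, size)
    detected = 0
    for rep in range(n_replicates):
        hp = gen_cohort(CohortPlan(n=n_per_group, noise_sd=noise_sd,
                                   n_features=0, age_sampler=ages),
                        seed=seed + 2 * rep)
        rd = gen_cohort(CohortPlan(n=n_per_group, noise_sd=noise_sd,
                                   n_features=0, fi_offset=offset,
                                   group="RD", age_sampler=ages),
                        seed=seed + 2 * rep + 1)
        _, p = compare_groups(hp["fi"].to_numpy(), rd["fi"].to_numpy())
        detected += p < alpha
    return detected / n_replicates
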