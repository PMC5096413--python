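"""Desk-scale replication of the characterization analyses.

Each function generates synthetic data from the reference
parameterizations in :mod:`lightplate.synthetic` at the published
sampling designs (24-intensity triplicate dose responses, triplicate
staggered step time courses, 5% multiplicative noise), refits the models,
and reports the recovered quantities. Everything is a pure function of
the base seed: seed streams are derived with ``numpy.random.SeedSequence``
so replicate experiments are independent but reproducible.

These studies answer "does the analysis pipeline recover the parameters
the instruments were characterized with, from data of the quality those
experiments produced?" — they are recovery studies on synthetic data, not
re-measurements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic as syn
from .device import DC_MAX, N_CHANNELS
from .errors import FitError
from .kinetics import (
    LN2,
    HillModel,
    RedShiftModel,
    CcasStepModel,
    Cry2StepModel,
    generate_function,
)


def _seed_stream(base_seed: int, n: int, tag: int) -> np.ndarray:
    """Deterministic stream of 31-bit seeds for one study."""
    ss = np.random.SeedSequence([int(base_seed), int(tag)])
    return (ss.generate_state(n) >> 1).astype(np.int64)  # 31-bit


def hill_recovery_ccas(n_seeds: int = 200, base_seed: int = 1) -> pd.DataFrame:
    """Refit the green-light Hill transfer function from synthetic data.

    Returns one row per replicate: fitted n_hill, k_half, dynamic range,
    and whether each true value fell inside the fit's 95% CI.
    """
    seeds = _seed_stream(base_seed, n_seeds, tag=1)
    intensities = syn.ccas_dose_intensities()
    rows = []
    for s in seeds:
        df = syn.gen_dose_response(
            syn.CCAS_TRANSFER, intensities, 3, syn.NoiseSpec(0.05, seed=int(s))
        )
        res = HillModel(df).fit(seed=int(s))
        ci = res.conf_int()
        dr = res.dynamic_range
        dr_bse = res.dynamic_range_bse
        rows.append(
            {
                "n_hill": res.params["n_hill"],
                "k_half": res.params["k_half"],
                "dynamic_range": dr,
                "n_hill_in_ci": ci.loc["n_hill", "lower"] <= 2.6 <= ci.loc["n_hill", "upper"],
                "k_half_in_ci": ci.loc["k_half", "lower"] <= 0.22 <= ci.loc["k_half", "upper"],
                "range_in_ci": (dr - 1.96 * dr_bse) <= 5.3 <= (dr + 1.96 * dr_bse),
            }
        )
    return pd.DataFrame(rows)


def red_shift_recovery(n_seeds: int = 50, base_seed: int = 1) -> pd.DataFrame:
    """Joint shared-shape fit across red intensities 0-12; returns slopes."""
    seeds = _seed_stream(base_seed, n_seeds, tag=2)
    intensities = syn.ccas_dose_intensities()
    reds = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    rows = []
    for s in seeds:
        sub = np.random.SeedSequence([int(s)]).generate_state(len(reds)) >> 1
        datasets = [
            (
                r,
                syn.gen_dose_response(
                    syn.CCAS_TRANSFER, intensities, 3,
                    syn.NoiseSpec(0.05, seed=int(sub[i])),
                    red_intensity=r, shift=syn.CCAS_RED_SHIFT,
                ),
            )
            for i, r in enumerate(reds)
        ]
        res = RedShiftModel(datasets).fit(seed=int(s))
        rows.append({"slope": res.slope, "n_hill": res.params["n_hill"]})
    return pd.DataFrame(rows)


def ccas_step_recovery(n_seeds: int = 200, base_seed: int = 1) -> pd.DataFrame:
    """Shared-parameter two-stage step fit; returns delay and half-times."""
    seeds = _seed_stream(base_seed, 2 * n_seeds, tag=3)
    model = syn.ccas_model()
    t = syn.ccas_step_times()
    rows = []
    for i in range(n_seeds):
        on = syn.gen_step_response(model, "on", t, syn.NoiseSpec(0.05, seed=int(seeds[2 * i])))
        off = syn.gen_step_response(model, "off", t, syn.NoiseSpec(0.05, seed=int(seeds[2 * i + 1])))
        try:
            res = CcasStepModel(on, off).fit(seed=int(seeds[2 * i]))
        except FitError:
            continue
        rows.append(
            {
                "tau_delay": res.tau_delay,
                "switching_half_time": res.switching_half_time,
                "dilution_half_time": LN2 / res.k_g,
            }
        )
    return pd.DataFrame(rows)


def cry2_hill_recovery(n_seeds: int = 200, base_seed: int = 1) -> pd.DataFrame:
    """Refit the blue-light Hill function over the validated dose range."""
    seeds = _seed_stream(base_seed, n_seeds, tag=4)
    intensities = syn.cry2_dose_intensities()
    rows = []
    for s in seeds:
        df = syn.gen_dose_response(
            syn.CRY2_TRANSFER, intensities, 3, syn.NoiseSpec(0.05, seed=int(s))
        )
        res = HillModel(df).fit(seed=int(s))
        rows.append(
            {
                "k_half": res.params["k_half"],
                "n_hill": res.params["n_hill"],
                "dynamic_range": res.dynamic_range,
            }
        )
    return pd.DataFrame(rows)


def cry2_step_recovery(n_seeds: int = 200, base_seed: int = 1) -> pd.DataFrame:
    """Shared-parameter delayed-exponential step fit; delay and half-time."""
    seeds = _seed_stream(base_seed, 2 * n_seeds, tag=5)
    model = syn.cry2_model()
    t = syn.cry2_step_times()
    rows = []
    for i in range(n_seeds):
        on = syn.gen_step_response(model, "on", t, syn.NoiseSpec(0.05, seed=int(seeds[2 * i])))
        off = syn.gen_step_response(model, "off", t, syn.NoiseSpec(0.05, seed=int(seeds[2 * i + 1])))
        try:
            res = Cry2StepModel(on, off).fit(seed=int(seeds[2 * i]))
        except FitError:
            continue
        rows.append({"tau_delay": res.tau_delay, "half_time": res.half_time})
    return pd.DataFrame(rows)


def calibration_cv_percent(base_seed: int = 1, cv: float = 0.15) -> float:
    """Post-calibration CV (%) of predicted outputs at full command for a
    simulated 48-LED population with the given uncalibrated CV."""
    from .device import compute_calibration

    seed = int(_seed_stream(base_seed, 1, tag=6)[0])
    measured = syn.gen_led_population(N_CHANNELS, cv=cv, seed=seed)
    calib = compute_calibration(measured)
    post = measured * np.asarray(calib.dc) / DC_MAX * np.asarray(calib.gcal)
    return float(np.std(post) / np.mean(post) * 100.0)


def funcgen_tracking(timestep: float = 1.0) -> float:
    """Tracking RMSE of the ramp/hold/sine reference as a fraction of its
    dynamic range (deterministic; no noise enters function generation)."""
    import warnings

    model = syn.ccas_model()
    ref, duration = syn.funcgen_reference()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = generate_function(model, ref, duration, timestep, (0.0, syn.CCAS_GREEN_MAX))
    return float(res.rmse_fraction)
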