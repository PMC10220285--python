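import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gpxscreen.plates import Assay, build_dose_series
from gpxscreen.simulate import (
    NoiseModel,
    default_assay_config,
    make_truth_panel,
    simulate_screen,
)


@pytest.fixture(scope="session")
def dose7():
    return build_dose_series(49.8e-6, 7, 3.0)


@pytest.fixture(scope="session")
def dose11():
    return build_dose_series(49.8e-6, 11, 3.0)


@pytest.fixture(scope="session")
def gpx1_config():
    return default_assay_config(Assay.gpx1)


@pytest.fixture(scope="session")
def small_screen(dose7):
    """One seeded GPX1 plate with a small mixed panel; reused across tests."""
    ledger = make_truth_panel(2, rng=7)
    plates, planted = simulate_screen(
        list(ledger.truths.values()),
        dose7,
        [Assay.gpx1],
        NoiseModel(seed=7),
    )
    return plates, planted, ledger


def euler_course(config, residual=None, dt=0.01):
    """Fixed-step explicit-Euler integration of the coupled assay kinetics.

    Deliberately independent of the package solver: re-derives the rate
    laws from their definitions at a 10 ms step, for use as a numerical
    oracle.
    """
    residual = dict(residual or {})
    f_gpx = residual.get("gpx", 1.0)
    f_gr = residual.get("gr", 1.0)
    e_gpx = config.enzyme_conc * f_gpx
    if config.assay.value == "gr_counter":
        e_gpx = 0.0
    e_gr = config.gr_conc * f_gr
    chp, gsh, gssg, nadph = config.chp0, config.gsh0, config.gssg0, config.nadph0
    t_end = config.read_schedule[-1]
    times = np.asarray(config.read_schedule)
    out = {"chp": [], "gsh": [], "gssg": [], "nadph": []}
    n_steps = int(round(t_end / dt))
    next_sample = 0
    t = 0.0
    for step in range(n_steps + 1):
        while next_sample < times.size and t >= times[next_sample] - dt / 2:
            out["chp"].append(chp)
            out["gsh"].append(gsh)
            out["gssg"].append(gssg)
            out["nadph"].append(nadph)
            next_sample += 1
        if e_gpx > 0 and chp > 0 and gsh > 0:
            v_gpx = e_gpx / (config.phi1 / chp + config.phi2 / gsh)
        else:
            v_gpx = 0.0
        if e_gr > 0 and gssg > 0 and nadph > 0:
            v_gr = (
                e_gr
                * config.gr_kcat
                * gssg
                * nadph
                / ((config.gr_km_gssg + gssg) * (config.gr_km_nadph + nadph))
            )
        else:
            v_gr = 0.0
        chp = max(0.0, chp - v_gpx * dt)
        gsh = max(0.0, gsh + (-2 * v_gpx + 2 * v_gr) * dt)
        gssg = max(0.0, gssg + (v_gpx - v_gr) * dt)
        nadph = max(0.0, nadph - v_gr * dt)
        t += dt
    while next_sample < times.size:
        out["chp"].append(chp)
        out["gsh"].append(gsh)
        out["gssg"].append(gssg)
        out["nadph"].append(nadph)
        next_sample += 1
    return {k: np.asarray(v) for k, v in out.items()}
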