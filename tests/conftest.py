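import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methanotype import simulate, sniffer

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def trace_params() -> simulate.TraceParams:
    return simulate.TraceParams()


@pytest.fixture(scope="session")
def calibration(trace_params) -> sniffer.CalibrationModel:
    phi = trace_params.dilution_factor
    records = [("base", 10_000.0, 10_000.0 / phi)] * 5 + [
        ("center", 10_000.0, 10_000.0 / phi)
    ] * 5
    return sniffer.calibrate_dilution(records, station_gain=trace_params.station_gain)


@pytest.fixture(scope="session")
def small_herd() -> simulate.HerdConfig:
    return simulate.make_herd(n_cows=9, n_periods=2, seed=11)


def analyse_trace(trace, calibration, min_height=200.0, min_peaks=3):
    """Run the full sniffer chain on one trace; returns (summary, rate or nan)."""
    baseline = sniffer.estimate_baseline(trace)
    peaks = sniffer.detect_peaks(trace, baseline, min_height=min_height)
    summ = sniffer.summarize_milking(
        peaks, trace.duration_min, min_peaks=min_peaks,
        cow_id=trace.cow_id, session_id=trace.session_id,
    )
    rate = sniffer.index_to_rate(summ, calibration) if summ.valid else float("nan")
    return summ, rate


def recover_herd_rates(herd, trace_params, calibration, seed, n_sessions=35,
                       duration=480.0) -> pd.Series:
    """Estimate each cow's emission rate from simulated milkings (all periods)."""
    est = {}
    for cow in herd.cows:
        rates = []
        for period in herd.periods:
            for s in range(n_sessions):
                tr = simulate.gen_gas_trace(
                    float(herd.true_rates[cow]), trace_params, duration, seed,
                    cow_id=cow, session_id=f"p{period}s{s}",
                )
                _, rate = analyse_trace(tr, calibration)
                if not np.isnan(rate):
                    rates.append(rate)
        est[cow] = float(np.mean(rates)) if rates else float("nan")
    return pd.Series(est)
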