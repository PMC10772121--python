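import math

import numpy as np
import pytest

from epifoot.kinetics import (
    BLITrace,
    IdentifiabilityError,
    KineticsError,
    KineticsParams,
    fit_langmuir_global,
    fit_steady_state,
    model_response,
    read_manifest,
    simulate_trace,
)

WT = KineticsParams(kon=1e5, koff=2.8e-4, rmax=1.0)  # KD = 2.8 nM
WEAK = KineticsParams(kon=1e5, koff=1e5 * 1650e-9, rmax=1.0)  # KD = 1650 nM


def dilution_series(params, top=250e-9, n=6, noise_sd=0.0, seed=1):
    return [
        simulate_trace(params, top / 2**k, t_assoc=300.0, t_dissoc=600.0, dt=1.0,
                       noise_sd=noise_sd, seed=seed * 100 + k)
        for k in range(n)
    ]


def test_half_saturation_plateau():
    c = WT.kd
    tr = simulate_trace(WT, c, t_assoc=500_000.0, t_dissoc=200.0, dt=100.0)
    assoc_end = tr.responses[tr.times <= tr.t_assoc_end][-1]
    assert assoc_end == pytest.approx(WT.rmax / 2, rel=1e-6)


def test_fast_off_rate_kills_the_plateau():
    p = KineticsParams(kon=1e3, koff=10.0, rmax=1.0)
    tr = simulate_trace(p, 1e-9, t_assoc=300.0, t_dissoc=10.0, dt=1.0)
    assert np.max(tr.responses) < 1e-6


def test_association_endpoint_matches_closed_form():
    c, t = 250e-9, 300.0
    tr = simulate_trace(WT, c, t_assoc=t, t_dissoc=600.0, dt=1.0)
    kobs = WT.kon * c + WT.koff
    req = WT.rmax * c / (c + WT.kd)
    expected = req * (1.0 - math.exp(-kobs * t))  # independent double-precision eval
    assert tr.responses[int(t)] == pytest.approx(expected, rel=1e-12)


def test_dissociation_is_continuous_and_exponential():
    tr = simulate_trace(WT, 250e-9)
    i_end = int(np.searchsorted(tr.times, tr.t_assoc_end, side="right")) - 1
    r_end = tr.responses[i_end]
    # one dissociation step later the response is r_end * exp(-koff*dt)
    assert tr.responses[i_end + 1] == pytest.approx(r_end * math.exp(-WT.koff), rel=1e-9)


def test_noise_free_global_fit_recovers_parameters():
    fit = fit_langmuir_global(dilution_series(WT))
    assert fit.converged
    assert fit.kd == pytest.approx(WT.kd, rel=0.01)
    assert fit.params.kon == pytest.approx(WT.kon, rel=0.01)
    assert fit.params.koff == pytest.approx(WT.koff, rel=0.01)
    assert fit.rmax == pytest.approx(WT.rmax, rel=0.01)


@pytest.mark.parametrize("seed", [11, 22, 33])
def test_noisy_global_fit_recovers_kd_within_15_percent(seed):
    traces = dilution_series(WT, noise_sd=0.02 * WT.rmax, seed=seed)
    fit = fit_langmuir_global(traces)
    assert fit.kd == pytest.approx(WT.kd, rel=0.15)


def test_single_concentration_is_unidentifiable():
    traces = [simulate_trace(WT, 250e-9, seed=s) for s in (1, 2)]
    with pytest.raises(IdentifiabilityError):
        fit_langmuir_global(traces)


def test_flat_traces_raise_no_signal():
    t = np.arange(0.0, 900.0)
    traces = [
        BLITrace(concentration=c, times=t, responses=np.zeros_like(t), t_assoc_end=300.0)
        for c in (1e-9, 2e-9)
    ]
    with pytest.raises(IdentifiabilityError, match="flat"):
        fit_langmuir_global(traces)


def test_steady_state_exact_on_equilibrium_data():
    kd, rmax = 5e-8, 1.7
    times = np.arange(0.0, 101.0)
    traces = []
    for c in (kd / 4, kd, 4 * kd):
        req = rmax * c / (c + kd)
        traces.append(BLITrace(c, times, np.full_like(times, req), t_assoc_end=100.0))
    fit = fit_steady_state(traces)
    assert fit.kd == pytest.approx(kd, rel=1e-6)
    assert fit.rmax == pytest.approx(rmax, rel=1e-6)
    assert fit.params is None  # kon/koff undefined for this model
    assert not fit.non_saturating  # Cmax = 4*kd saturates


def test_steady_state_weak_binder_flags_non_saturating():
    traces = dilution_series(WEAK, top=500e-9)
    fit = fit_steady_state(traces)
    assert fit.kd == pytest.approx(WEAK.kd, rel=0.20)
    assert fit.non_saturating  # KD 1650 nM >> 500 nM top concentration


def test_steady_state_agrees_with_global_fit_on_good_data():
    # moderate-affinity binder sampled into saturation, association long
    # enough that every trace reaches its equilibrium plateau
    p = KineticsParams(kon=1e5, koff=5e-3, rmax=1.2)  # KD 50 nM
    traces = [
        simulate_trace(p, 800e-9 / 2**k, t_assoc=2000.0, t_dissoc=200.0, dt=2.0)
        for k in range(6)
    ]
    kd_global = fit_langmuir_global(traces).kd
    kd_ss = fit_steady_state(traces).kd
    assert kd_ss == pytest.approx(kd_global, rel=0.05)


def test_steady_state_needs_three_concentrations():
    traces = dilution_series(WT)[:2]
    with pytest.raises(IdentifiabilityError):
        fit_steady_state(traces)


def test_response_scale_equivariance():
    traces = dilution_series(WT)
    scaled = [
        BLITrace(tr.concentration, tr.times, tr.responses * 3.7, tr.t_assoc_end)
        for tr in traces
    ]
    f1, f2 = fit_langmuir_global(traces), fit_langmuir_global(scaled)
    assert f2.rmax == pytest.approx(3.7 * f1.rmax, rel=1e-6)
    assert f2.params.kon == pytest.approx(f1.params.kon, rel=1e-6)
    assert f2.params.koff == pytest.approx(f1.params.koff, rel=1e-6)


def test_fitted_model_curves_monotone_in_concentration():
    fit = fit_langmuir_global(dilution_series(WT))
    p = fit.params
    t = np.arange(0.0, 301.0)
    concs = [250e-9 / 2**k for k in range(6)]
    plateaus = [model_response(p, c, t, 300.0)[-1] for c in concs]
    kobs = [p.kon * c + p.koff for c in concs]
    assert all(a > b for a, b in zip(plateaus, plateaus[1:]))
    assert all(a > b for a, b in zip(kobs, kobs[1:]))


def test_invalid_parameters_rejected():
    with pytest.raises(KineticsError):
        KineticsParams(kon=-1.0, koff=1e-3, rmax=1.0)
    with pytest.raises(KineticsError):
        simulate_trace(WT, concentration=-1e-9)
    with pytest.raises(KineticsError):
        simulate_trace(WT, 1e-9, t_assoc=10.0, t_dissoc=10.0, dt=20.0)
    with pytest.raises(KineticsError):
        BLITrace(1e-9, np.array([0.0, 1.0]), np.array([0.0, 0.1]), t_assoc_end=5.0)


def test_kd_identity():
    assert WT.kd == pytest.approx(WT.koff / WT.kon, rel=1e-12)


def test_trace_csv_round_trip(tmp_path):
    from epifoot.synthetic import make_bli_dataset

    meta = make_bli_dataset(WT, tmp_path / "bli", noise_sd=0.0, seed=1)
    traces = read_manifest(meta["manifest"])
    assert len(traces) == 6
    fit = fit_langmuir_global(traces)
    assert fit.kd == pytest.approx(WT.kd, rel=0.01)
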