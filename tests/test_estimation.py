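"""Per-timepoint contractility estimation against forward-model oracles."""

import numpy as np
import pytest

from lvmech.cohort import make_tmax_truth, make_volume_waveform
from lvmech.estimation import (
    TmaxEstimationError,
    TmaxWaveform,
    Waveform,
    estimate_tmax_at_point,
    estimate_tmax_waveform,
    resample_to_common_grid,
    summarize_fit,
    waveform_from_csv,
    waveform_to_csv,
)
from lvmech.mechanics import cavity_pressure, mmhg_to_kpa


@pytest.fixture(scope="module")
def forward_case(wall, passive, active):
    """Noiseless forward-simulated cycle on a known wall (15-point grid)."""
    vol = make_volume_waveform(110.0, 0.5, 0.6, 15)
    tm = make_tmax_truth(80.0, 0.0, 0.6, 0.6)
    truth = tm(vol.times_s)
    p = np.array(
        [cavity_pressure(wall, v, passive, float(t), active) for v, t in zip(vol.values, truth)]
    )
    return vol.times_s, p, vol.values, truth


# ------------------------------------------------------------- waveforms ---

def test_waveform_validation():
    t = np.linspace(0, 1, 10)
    with pytest.raises(ValueError):
        Waveform(t[:5], np.ones(5), "volume")  # too few samples
    with pytest.raises(ValueError):
        Waveform(t[::-1], np.ones(10), "pressure")  # decreasing times
    with pytest.raises(ValueError):
        Waveform(t, -np.ones(10), "volume")  # negative volume
    with pytest.raises(ValueError):
        Waveform(t, np.ones(10), "flow")  # unknown kind


def test_waveform_csv_roundtrip_and_mmhg_conversion(tmp_path):
    w = Waveform(np.linspace(0, 1, 12), np.linspace(50, 110, 12), "volume")
    waveform_to_csv(w, tmp_path / "v.csv")
    w2 = waveform_from_csv(tmp_path / "v.csv")
    assert w2.kind == "volume" and np.allclose(w2.values, w.values)
    (tmp_path / "p.csv").write_text(
        "time_s,pressure_mmHg\n" + "\n".join(f"{t},{10 + t}" for t in np.linspace(0, 1, 9))
    )
    p = waveform_from_csv(tmp_path / "p.csv")
    assert p.kind == "pressure"
    assert p.values[0] == pytest.approx(mmhg_to_kpa(10.0))


def test_resample_identity_and_counts():
    t = np.linspace(0.0, 0.6, 15, endpoint=False)
    pw = Waveform(np.linspace(0.0, 0.6, 160), np.linspace(1.0, 2.0, 160), "pressure")
    vw = Waveform(t, np.linspace(100, 60, 15), "volume")
    tt, pp, vv = resample_to_common_grid(pw, vw)
    assert len(tt) == len(pp) == len(vv) == 15  # volume grid is kept
    same = Waveform(t, np.linspace(1.0, 2.0, 15), "pressure")
    _, pp2, _ = resample_to_common_grid(same, vw)
    assert np.array_equal(pp2, same.values)  # identical grids: identity


def test_resample_constant_pressure_stays_constant():
    pw = Waveform(np.linspace(0, 0.6, 40), np.full(40, 1.7), "pressure")
    vw = Waveform(np.linspace(0.01, 0.55, 15), np.linspace(100, 60, 15), "volume")
    _, pp, _ = resample_to_common_grid(pw, vw)
    assert np.allclose(pp, 1.7)


def test_resample_rejects_disjoint_spans():
    pw = Waveform(np.linspace(0, 0.5, 20), np.ones(20), "pressure")
    vw = Waveform(np.linspace(1.0, 1.5, 10), np.ones(10) * 80, "volume")
    with pytest.raises(ValueError):
        resample_to_common_grid(pw, vw)


# --------------------------------------------------------- single points ---

def test_tmax_zero_when_passive_pressure_matches(wall, passive, active):
    v = 1.4 * wall.cavity_volume_ml
    p_passive = cavity_pressure(wall, v, passive)
    tmax, err = estimate_tmax_at_point(wall, passive, active, v, p_passive)
    assert tmax == 0.0 and err < 1e-12


def test_tmax_forward_oracle_recovery(wall, passive, active):
    v = 1.1 * wall.cavity_volume_ml
    p = cavity_pressure(wall, v, passive, 60.0, active)
    tmax, err = estimate_tmax_at_point(wall, passive, active, v, p)
    assert abs(tmax - 60.0) < 1e-6
    assert err < 1e-10


def test_tmax_floor_on_subpassive_pressure(wall, passive, active):
    v = 1.4 * wall.cavity_volume_ml
    p_passive = cavity_pressure(wall, v, passive)
    tmax, err = estimate_tmax_at_point(wall, passive, active, v, 0.95 * p_passive)
    assert tmax == 0.0 and err > 0.0  # non-negativity floor, not negative Tmax


def test_tmax_bracket_exhaustion_reports_residual(wall, passive, active):
    # deep compression: sarcomeres below slack everywhere, no active response
    v = 0.2 * wall.cavity_volume_ml
    with pytest.raises(TmaxEstimationError) as exc:
        estimate_tmax_at_point(wall, passive, active, v, 5.0)
    assert exc.value.residual is not None and exc.value.residual > 0


# ------------------------------------------------------ waveform recovery ---

def test_waveform_recovery_noiseless(forward_case, wall, passive, active):
    t, p, v, truth = forward_case
    tw, summary = estimate_tmax_waveform(wall, passive, active, t, p, v)
    keep = ~tw.masked
    assert summary.converged
    assert summary.max_rel_error < 1e-6
    assert np.max(np.abs(tw.tmax_kpa[keep] - truth[keep])) < 0.1
    assert np.all(tw.tmax_kpa >= 0.0)


def test_waveform_estimation_point_independence(forward_case, wall, passive, active):
    t, p, v, _ = forward_case
    tw, _ = estimate_tmax_waveform(wall, passive, active, t, p, v)
    perm = np.random.default_rng(7).permutation(len(t))
    order = np.argsort(t[perm])  # Waveform wants increasing times
    tw2, _ = estimate_tmax_waveform(
        wall, passive, active, t[perm][order], p[perm][order], v[perm][order]
    )
    assert np.allclose(tw2.tmax_kpa, tw.tmax_kpa)


def test_waveform_time_reversal_mirrors_peak(forward_case, wall, passive, active):
    t, p, v, _ = forward_case
    _, fwd = estimate_tmax_waveform(wall, passive, active, t, p, v)
    _, rev = estimate_tmax_waveform(wall, passive, active, t, p[::-1], v[::-1])
    assert rev.peak_tmax_kpa == pytest.approx(fwd.peak_tmax_kpa, rel=1e-9)
    # peak time maps to the mirrored sample (one-sample slack covers the
    # tie-break flip of the symmetric activation waveform)
    mirrored = t[0] + t[-1] - fwd.time_to_peak_s
    dt = t[1] - t[0]
    assert abs(rev.time_to_peak_s - mirrored) <= dt + 1e-12


def test_all_diastolic_input_gives_zero_tmax(wall, passive, active):
    t = np.linspace(0.0, 0.6, 12, endpoint=False)
    v = np.full(12, 1.5 * wall.cavity_volume_ml)
    p = np.full(12, cavity_pressure(wall, v[0], passive))
    tw, summary = estimate_tmax_waveform(wall, passive, active, t, p, v)
    assert np.all(tw.tmax_kpa == 0.0)
    assert summary.peak_tmax_kpa == 0.0


def test_waveform_masking_floor_and_overmasking_error(wall, passive, active):
    t = np.linspace(0.0, 0.6, 10, endpoint=False)
    v = np.full(10, 1.2 * wall.cavity_volume_ml)
    p = np.full(10, 0.1)  # below the 0.25 kPa floor everywhere
    with pytest.raises(TmaxEstimationError):
        estimate_tmax_waveform(wall, passive, active, t, p, v)
    p2 = p.copy()
    p2[:6] = 1.0  # 40% masked: allowed, masked points carry NaN error
    tw, _ = estimate_tmax_waveform(wall, passive, active, t, p2, v)
    assert tw.masked.sum() == 4
    assert np.all(np.isnan(tw.rel_error[tw.masked]))
    assert np.all(tw.tmax_kpa[tw.masked] == 0.0)


# ---------------------------------------------------------------- summary ---

def _tw(times, tmax, masked=None):
    times = np.asarray(times, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    masked = np.zeros(len(times), dtype=bool) if masked is None else np.asarray(masked)
    rel = np.where(masked, np.nan, 0.01)
    return TmaxWaveform(times, tmax, rel, masked)


def test_summary_single_nonzero_sample():
    s = summarize_fit(_tw([0.0, 0.1, 0.2], [0.0, 42.0, 0.0]))
    assert s.peak_tmax_kpa == 42.0 and s.time_to_peak_s == 0.1


def test_summary_tie_takes_earliest():
    s = summarize_fit(_tw([0.0, 0.1, 0.2, 0.3], [1.0, 7.0, 7.0, 2.0]))
    assert s.time_to_peak_s == 0.1


def test_summary_scale_equivariance():
    a = summarize_fit(_tw([0.0, 0.1, 0.2], [1.0, 3.0, 2.0]))
    b = summarize_fit(_tw([0.0, 0.1, 0.2], [3.0, 9.0, 6.0]))
    assert b.peak_tmax_kpa == pytest.approx(3.0 * a.peak_tmax_kpa)
    assert b.time_to_peak_s == a.time_to_peak_s


def test_summary_convergence_flag_threshold():
    tw = _tw([0.0, 0.1], [1.0, 2.0])
    good = summarize_fit(tw)
    assert good.converged  # rel errors 0.01 < 0.05
    bad = TmaxWaveform(tw.times_s, tw.tmax_kpa, np.array([0.01, 0.2]), tw.masked)
    assert not summarize_fit(bad).converged


def test_summary_empty_unmasked_rejected():
    with pytest.raises(ValueError):
        summarize_fit(_tw([0.0, 0.1], [1.0, 1.0], masked=[True, True]))


def test_tmax_waveform_rejects_negative_values():
    with pytest.raises(ValueError):
        _tw([0.0, 0.1], [-1.0, 1.0])


def test_synchronized_csv_input(tmp_path):
    from lvmech.estimation import synchronized_from_csv

    (tmp_path / "sync.csv").write_text(
        "time_s,pressure_mmHg,volume_mL\n0.0,10.0,120\n0.1,12.0,110\n"
    )
    t, p, v = synchronized_from_csv(tmp_path / "sync.csv")
    assert p[0] == pytest.approx(mmhg_to_kpa(10.0))
    assert list(v) == [120.0, 110.0]
    (tmp_path / "bad.csv").write_text("time_s,volume_mL\n0.0,120\n")
    with pytest.raises(ValueError):
        synchronized_from_csv(tmp_path / "bad.csv")
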