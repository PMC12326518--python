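import numpy as np
import pandas as pd
import pytest

from aasarray import (
    SimulationConfig,
    distance_corr_matrix,
    haversine_matrix,
    make_geometry,
    simulate_all,
    simulate_classifier,
    simulate_fsa_trajectory,
    simulate_hour_counts,
    simulate_minute_stream,
    true_parameters,
)
from aasarray.simulate import simulate_minute_table, validate_correlation


# ----------------------------------------------------------------------
# trajectory and proximity
# ----------------------------------------------------------------------
def test_static_mass_at_station_gives_category_2_there_and_0_far():
    k = 1
    cfg = SimulationConfig(
        n_stations=4, traj_start_m=150.0 * k, traj_walk_sd_m=0.0, traj_shift_m=0.0, n_hours=24,
        first_spawn_hour=12,
    )
    traj = simulate_fsa_trajectory(cfg, make_geometry(cfg))
    at_k = traj[traj["station_id"] == cfg.station_ids[k]]
    assert (at_k["FP_index"] == 2).all()
    far = traj[traj["station_id"] == cfg.station_ids[3]]  # 300 m away
    assert (far["FP_index"] == 0).all()


def test_categories_match_brute_force_distance_thresholds(small_config):
    traj = simulate_fsa_trajectory(small_config, make_geometry(small_config))
    dist = (traj["mass_position_m"] - traj["station_position_m"]).abs()
    expect = np.where(dist <= 20, 2, np.where(dist <= 100, 1, 0))
    assert (traj["FP_index"].to_numpy() == expect).all()


def test_shift_episode_moves_nearest_station():
    cfg = SimulationConfig(
        n_stations=6, traj_start_m=150.0, traj_walk_sd_m=0.0, traj_shift_m=450.0,
        traj_shift_hour=10, n_hours=20, first_spawn_hour=10,
    )
    traj = simulate_fsa_trajectory(cfg, make_geometry(cfg))
    wide = traj.pivot(index="hour", columns="station_id", values="FP_index")
    # before the shift the mass sits on station 2 (150 m); afterwards on 600 m
    assert wide.loc[5].idxmax() == cfg.station_ids[1]
    assert wide.loc[15].idxmax() == cfg.station_ids[4]


# ----------------------------------------------------------------------
# correlation structure
# ----------------------------------------------------------------------
def test_distance_kernel_is_valid_and_monotone():
    cfg = SimulationConfig(n_stations=6)
    D = haversine_matrix(make_geometry(cfg))
    R = distance_corr_matrix(D, decay_m=350.0)
    validate_correlation(R)
    d = D[np.triu_indices(6, 1)]
    r = R[np.triu_indices(6, 1)]
    order = np.argsort(d)
    assert (np.diff(r[order]) <= 1e-12).all()


# ----------------------------------------------------------------------
# hourly counts: moment oracles
# ----------------------------------------------------------------------
def _flat_design(J, H, tau=1.0, T_index=0, D_index=0, FP_index=0):
    t0 = pd.Timestamp("2020-02-08T10:00:00")
    rows = []
    for j in range(J):
        for i in range(H):
            rows.append(
                {
                    "station_id": f"s{j}",
                    "hour": i,
                    "hour_start": t0 + pd.Timedelta(hours=i),
                    "tau": tau,
                    "T_index": T_index,
                    "D_index": D_index,
                    "FP_index": FP_index,
                }
            )
    return pd.DataFrame(rows)


def _null_params(J, sigma=0.0, R=None):
    from aasarray import TrueParameters

    return TrueParameters(
        T=np.zeros(24), D=np.zeros(7), FP=np.zeros(3),
        sigma_h=np.full(J, sigma), R=np.eye(J) if R is None else R,
    )


def test_null_process_is_unit_poisson():
    design = _flat_design(J=2, H=5000)
    cells = simulate_hour_counts(_null_params(2), design, seed=0)
    v = cells["V"].to_numpy()
    se = v.std(ddof=1) / np.sqrt(len(v))
    assert abs(v.mean() - 1.0) < 3 * se
    assert v.min() >= 0


def test_lognormal_moment_correction():
    # E[V / tau] = exp(eta + sigma^2 / 2) for lognormal random effects
    sigma = 0.6
    eta = 1.0
    params = _null_params(1, sigma=sigma)
    params.T[0] = eta
    design = _flat_design(J=1, H=12000, tau=0.8)
    cells = simulate_hour_counts(params, design, seed=1)
    x = cells["V"].to_numpy() / cells["tau"].to_numpy()
    expect = np.exp(eta + sigma**2 / 2)
    se = x.std(ddof=1) / np.sqrt(len(x))
    assert abs(x.mean() - expect) < 3 * se


def test_correlated_stations_recover_r12():
    R = np.array([[1.0, 0.9], [0.9, 1.0]])
    params = _null_params(2, sigma=1.0, R=R)
    params.T[0] = 5.0  # enough counts that Poisson noise barely attenuates
    design = _flat_design(J=2, H=6000)
    cells = simulate_hour_counts(params, design, seed=2)
    wide = cells.pivot(index="hour", columns="station_id", values="V")
    logr = np.log(wide.clip(lower=0.5))
    r = np.corrcoef(logr["s0"], logr["s1"])[0, 1]
    assert r == pytest.approx(0.9, abs=0.05)


def test_rejects_nonpositive_tau():
    design = _flat_design(J=1, H=2)
    design.loc[0, "tau"] = 0.0
    with pytest.raises(ValueError, match="tau"):
        simulate_hour_counts(_null_params(1), design, seed=0)


# ----------------------------------------------------------------------
# minute streams, interference, classifier
# ----------------------------------------------------------------------
def test_event_counts_conserved_per_station_hour(small_sim):
    events = small_sim["events"]
    hc = small_sim["hourcells"]
    counted = (
        events.assign(hour_start=events["minute_start"].dt.floor("h"))
        .groupby(["station_id", "hour_start"])
        .size()
    )
    for row in hc.itertuples(index=False):
        assert counted.get((row.station_id, row.hour_start), 0) == row.V


def test_zero_counts_give_empty_event_table(small_config):
    cfg = small_config
    geo = make_geometry(cfg)
    minutes = simulate_minute_table(cfg, geo)
    hc = pd.DataFrame(
        {
            "station_id": [g.station_id for g in geo],
            "hour_start": pd.Timestamp(cfg.start_time),
            "V": 0,
        }
    )
    events = simulate_minute_stream(hc, minutes, cfg)
    assert events.empty


def test_events_never_fall_in_excluded_minutes(small_sim):
    events = small_sim["events"]
    minutes = small_sim["minutes"]
    bad = minutes.loc[~minutes["observed"], ["station_id", "minute_start"]]
    hit = events.merge(bad, on=["station_id", "minute_start"], how="inner")
    assert hit.empty


def test_infeasible_density_raises(small_config):
    cfg = small_config
    geo = make_geometry(cfg)[:1]
    minutes = simulate_minute_table(cfg, geo)
    hc = pd.DataFrame(
        {
            "station_id": [geo[0].station_id],
            "hour_start": [pd.Timestamp(cfg.start_time)],
            "V": [60 * 30 + 1],
        }
    )
    with pytest.raises(ValueError, match="2-s bins"):
        simulate_minute_stream(hc, minutes, cfg)


def test_interference_exclusion_share_near_configured_fraction():
    cfg = SimulationConfig(n_stations=6, n_hours=158, interference_frac=0.044, seed=3)
    minutes = simulate_minute_table(cfg, make_geometry(cfg))
    share = 1.0 - minutes["observed"].mean()
    # each flagged sampled minute excludes its 5-minute block
    n_sampled = int(minutes["sampled"].sum())
    se = np.sqrt(0.044 * 0.956 / n_sampled)
    assert abs(share - 0.044) < 4 * se + 0.002  # small deficit from record edges


def test_perfect_classifier_reproduces_true_stream(small_sim, small_config):
    cfg = SimulationConfig(**{**small_config.to_dict(), "classifier_tpr": 1.0, "classifier_fp_per_min": 0.0})
    t, p = simulate_classifier(small_sim["events"], small_sim["minutes"], cfg)
    pd.testing.assert_frame_equal(t, p)


def test_zero_tpr_recovers_no_true_positives(small_sim, small_config):
    cfg = SimulationConfig(**{**small_config.to_dict(), "classifier_tpr": 0.0, "classifier_fp_per_min": 0.0})
    _, p = simulate_classifier(small_sim["events"], small_sim["minutes"], cfg)
    assert p.empty


def test_tpr_recovered_within_binomial_interval(small_sim, small_config):
    cfg = SimulationConfig(**{**small_config.to_dict(), "classifier_tpr": 0.7, "classifier_fp_per_min": 0.0})
    t, p = simulate_classifier(small_sim["events"], small_sim["minutes"], cfg)
    n = len(t)
    assert n >= 1000
    phat = len(p) / n
    se = np.sqrt(0.7 * 0.3 / n)
    assert abs(phat - 0.7) < 1.96 * se + 1e-9


# ----------------------------------------------------------------------
# reproducibility
# ----------------------------------------------------------------------
def test_generator_is_bit_reproducible(small_config):
    a = simulate_all(small_config)
    b = simulate_all(SimulationConfig(**small_config.to_dict()))
    for key in ("minutes", "hourcells", "events", "predicted_events", "trajectory"):
        pd.testing.assert_frame_equal(a[key], b[key])
    assert np.array_equal(a["params"].R, b["params"].R)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(interference_frac=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(effects_T=[0.0] * 23)
    with pytest.raises(ValueError):
        SimulationConfig(classifier_tpr=1.2)


def test_user_correlation_matrix_is_projected_to_psd():
    bad = np.array([[1.0, 0.95, -0.9], [0.95, 1.0, 0.8], [-0.9, 0.8, 1.0]])
    cfg = SimulationConfig(n_stations=3, corr_matrix=bad.tolist())
    params = true_parameters(cfg)
    validate_correlation(params.R)
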