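import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aasarray import TrueParameters, encode_design, log_joint
from aasarray import model as mdl
from aasarray.lkj import sample_lkj

from conftest import make_hourcells


# ----------------------------------------------------------------------
# independent brute-force oracle for the joint density
# ----------------------------------------------------------------------
def oracle_log_joint(params, design):
    """Term-by-term naive summation with scipy.stats, sharing no code
    with the implementation (LKJ(1) constant taken as 0 in both)."""
    total = 0.0
    for c in range(len(design.V)):
        eta = (
            design.log_tau[c]
            + params.T[design.T_index[c]]
            + params.D[design.D_index[c]]
            + params.FP[design.FP_index[c]]
            + params.h[design.hour_index[c], design.station_index[c]]
        )
        total += stats.poisson.logpmf(design.V[c], np.exp(eta))
    cov = np.diag(params.sigma_h) @ params.R @ np.diag(params.sigma_h)
    for i in range(design.H):
        total += stats.multivariate_normal.logpdf(params.h[i], mean=np.zeros(design.J), cov=cov)
    for block in (params.T, params.D, params.FP):
        for x in block:
            total += stats.norm.logpdf(x)
    for s in params.sigma_h:
        total += stats.expon.logpdf(s)
    return float(total)


def _random_instance(rng, J=3, H=6):
    hc = make_hourcells(rng, J=J, H=H)
    design = encode_design(hc)
    params = TrueParameters(
        T=rng.normal(size=24) * 0.5,
        D=rng.normal(size=7) * 0.5,
        FP=rng.normal(size=3) * 0.5,
        sigma_h=rng.uniform(0.2, 1.5, J),
        R=sample_lkj(J, 1.0, rng),
    )
    params.h = rng.normal(size=(design.H, design.J)) * 0.5
    return params, design


def test_log_joint_matches_bruteforce_oracle():
    rng = np.random.default_rng(10)
    for _ in range(25):
        params, design = _random_instance(rng)
        got = log_joint(params, design)
        want = oracle_log_joint(params, design)
        assert got == pytest.approx(want, rel=1e-8)


def test_unit_mean_cell_poisson_term_is_minus_one():
    # one station, one hour, V=1, tau=1, all effects and h zero: the
    # Poisson term is log(e^-1 * 1 / 1!) = -1 exactly
    hc = pd.DataFrame(
        [{"station_id": "s0", "hour_start": pd.Timestamp("2020-02-08T10:00:00"),
          "V": 1, "tau": 1.0, "rate": 1.0, "T_index": 10, "D_index": 0, "FP_index": 0}]
    )
    design = encode_design(hc)
    params = TrueParameters(
        T=np.zeros(24), D=np.zeros(7), FP=np.zeros(3), sigma_h=np.ones(1), R=np.eye(1)
    )
    params.h = np.zeros((1, 1))
    closed_priors = (
        stats.multivariate_normal.logpdf(0.0, cov=1.0)
        + 34 * stats.norm.logpdf(0.0)
        + stats.expon.logpdf(1.0)
    )
    assert log_joint(params, design) - closed_priors == pytest.approx(-1.0, abs=1e-12)


def test_hour_permutation_leaves_log_joint_unchanged():
    rng = np.random.default_rng(3)
    params, design = _random_instance(rng, J=2, H=8)
    base = log_joint(params, design)
    perm = rng.permutation(design.H)
    design2 = mdl.DesignArrays(
        V=design.V, log_tau=design.log_tau, T_index=design.T_index,
        D_index=design.D_index, FP_index=design.FP_index,
        station_index=design.station_index,
        hour_index=np.argsort(perm)[design.hour_index],
        J=design.J, H=design.H, station_ids=design.station_ids,
    )
    params2 = TrueParameters(
        T=params.T, D=params.D, FP=params.FP, sigma_h=params.sigma_h, R=params.R
    )
    params2.h = params.h[perm]
    # reordering hours relabels the exchangeable h rows only
    assert log_joint(params2, design2) == pytest.approx(base, rel=1e-12)


def test_log_joint_rejects_invalid_inputs():
    rng = np.random.default_rng(4)
    params, design = _random_instance(rng)
    bad = TrueParameters(T=params.T, D=params.D, FP=params.FP,
                         sigma_h=params.sigma_h, R=params.R)
    bad.h = params.h
    bad.sigma_h = -np.abs(params.sigma_h)
    with pytest.raises(ValueError):
        log_joint(bad, design)
    with pytest.raises(ValueError):  # non-PSD R caught at construction
        TrueParameters(T=params.T, D=params.D, FP=params.FP, sigma_h=np.ones(3),
                       R=np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1.0]]))


# ----------------------------------------------------------------------
# design encoding
# ----------------------------------------------------------------------
def test_encode_design_index_mappings():
    t0 = pd.Timestamp("2020-02-08T19:00:00")
    hc = pd.DataFrame(
        [
            {"station_id": "s0", "hour_start": t0, "V": 2, "tau": 0.5, "rate": 4.0,
             "T_index": 19, "D_index": 0, "FP_index": 2},
            {"station_id": "s0", "hour_start": t0 + pd.Timedelta(hours=1), "V": 0, "tau": 1.0,
             "rate": 0.0, "T_index": 20, "D_index": 6, "FP_index": 0},
        ]
    )
    d = encode_design(hc)
    assert d.T_index.tolist() == [19, 20]
    assert d.D_index.tolist() == [0, 6]  # DAFS -4 and +2
    assert d.FP_index.tolist() == [2, 0]  # "present" is category 2
    assert np.allclose(d.log_tau, [np.log(0.5), 0.0])


def test_encode_design_restricts_to_hours_seen_by_all_stations():
    rng = np.random.default_rng(5)
    hc = make_hourcells(rng, J=3, H=6)
    hc = hc.drop(hc[(hc["station_id"] == "s1")].index[2:3])  # s1 misses hour 2
    d = encode_design(hc, complete_hours=True)
    assert d.H == 5
    d_all = encode_design(hc, complete_hours=False)
    assert d_all.H == 6 and len(d_all.V) == 17


def test_encode_design_rejects_duplicates_and_bad_tau():
    rng = np.random.default_rng(6)
    hc = make_hourcells(rng, J=2, H=3)
    with pytest.raises(ValueError, match="duplicate"):
        encode_design(pd.concat([hc, hc.iloc[:1]]))
    hc.loc[0, "tau"] = 0.0
    with pytest.raises(ValueError, match="tau"):
        encode_design(hc)


# ----------------------------------------------------------------------
# potential: gradient and Poisson MLE limit
# ----------------------------------------------------------------------
def test_potential_gradient_matches_finite_differences():
    rng = np.random.default_rng(7)
    hc = make_hourcells(rng, J=3, H=5)
    pot = mdl._Potential(encode_design(hc))
    theta = 0.4 * rng.standard_normal(pot.dim)
    lp, g = pot(theta)
    eps = 1e-6
    idx = rng.choice(pot.dim, size=40, replace=False)
    for k in idx:
        tp, tm = theta.copy(), theta.copy()
        tp[k] += eps
        tm[k] -= eps
        fd = (pot(tp)[0] - pot(tm)[0]) / (2 * eps)
        assert g[k] == pytest.approx(fd, rel=1e-4, abs=1e-6)


def test_flat_intercept_mle_is_total_rate():
    # with all other effects and h fixed at zero, the Poisson term is
    # maximized over a single intercept at log(sum V / sum tau)
    rng = np.random.default_rng(8)
    hc = make_hourcells(rng, J=2, H=10)
    hc["T_index"] = 0
    hc["D_index"] = 0
    hc["FP_index"] = 0
    design = encode_design(hc)
    c_star = np.log(design.V.sum() / np.exp(design.log_tau).sum())

    def pois(c):
        T = np.zeros(24)
        T[0] = c
        return mdl._poisson_loglik(T, np.zeros(7), np.zeros(3), np.zeros(len(design.V)), design)

    for delta in (1e-3, 0.1, 0.5):
        assert pois(c_star) > pois(c_star + delta)
        assert pois(c_star) > pois(c_star - delta)


# ----------------------------------------------------------------------
# sampler correctness against the exact prior
# ----------------------------------------------------------------------
def test_hmc_recovers_prior_with_no_data():
    # an empty design leaves only the priors: T ~ N(0,1),
    # sigma_h ~ Exp(1), and for J=2 the single correlation is
    # uniform on (-1, 1) (variance 1/3)
    J, H = 2, 3
    design = mdl.DesignArrays(
        V=np.empty(0, dtype=np.int64),
        log_tau=np.empty(0),
        T_index=np.empty(0, dtype=np.int64),
        D_index=np.empty(0, dtype=np.int64),
        FP_index=np.empty(0, dtype=np.int64),
        station_index=np.empty(0, dtype=np.int64),
        hour_index=np.empty(0, dtype=np.int64),
        J=J, H=H, station_ids=["a", "b"],
    )
    post = mdl.fit(design, chains=2, iterations=1500, seed=0)
    tdraws = post.stacked("T")
    assert abs(tdraws.mean()) < 0.05
    assert tdraws.std() == pytest.approx(1.0, abs=0.05)
    sig = post.stacked("sigma_h")
    assert sig.mean() == pytest.approx(1.0, abs=0.1)
    rho = post.stacked("R")[:, 1, 0]
    assert abs(rho.mean()) < 0.1
    assert rho.var() == pytest.approx(1.0 / 3.0, abs=0.06)
    z = post.stacked("h")  # prior h: sd sigma per station, mean 0
    assert abs(z.mean()) < 0.15


def test_posterior_r_draws_are_valid_correlations(small_sim):
    hc = small_sim["hourcells"].rename(columns={})
    design = encode_design(hc)
    post = mdl.fit(design, chains=2, iterations=200, seed=1)
    R = post.stacked("R")
    assert np.allclose(R, np.swapaxes(R, 1, 2), atol=1e-8)
    assert np.allclose(R[:, range(design.J), range(design.J)], 1.0)
    eig = np.linalg.eigvalsh(R)
    assert eig.min() > -1e-8
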