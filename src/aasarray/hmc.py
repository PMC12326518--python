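"""Hamiltonian Monte Carlo with dual-averaging step-size adaptation
and diagonal mass-matrix estimation.

A deliberately small, dependency-free sampler: leapfrog trajectories
with jittered length, a Metropolis correction using the exact joint
density (so approximate gradients would bias only efficiency, never
the stationary distribution), windowed variance estimation for the
diagonal metric during warmup, and divergence accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: energy error beyond which a trajectory is declared divergent
DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class DualAveraging:
    """Nesterov dual averaging of log step size toward a target
    acceptance statistic (the standard warmup controller)."""

    target: float = 0.8
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    mu: float = 0.0
    _t: int = 0
    _h_bar: float = 0.0
    _log_eps_bar: float = 0.0

    def restart(self, eps: float) -> None:
        self.mu = np.log(10.0 * eps)
        self._t = 0
        self._h_bar = 0.0
        self._log_eps_bar = 0.0

    def update(self, accept_stat: float) -> float:
        self._t += 1
        eta = 1.0 / (self._t + self.t0)
        self._h_bar = (1.0 - eta) * self._h_bar + eta * (self.target - accept_stat)
        log_eps = self.mu - np.sqrt(self._t) / self.gamma * self._h_bar
        w = self._t ** (-self.kappa)
        self._log_eps_bar = w * log_eps + (1.0 - w) * self._log_eps_bar
        return float(np.exp(log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self._log_eps_bar))


@dataclass
class HMCResult:
    samples: np.ndarray  # (n_samples, dim)
    logp: np.ndarray  # (n_samples,)
    accept_stat: np.ndarray
    step_size: float
    inv_mass: np.ndarray
    n_divergent: int = 0
    n_leapfrog: int = 0


def _leapfrog(logp_and_grad, theta, p, eps, n_steps, inv_mass):
    lp, grad = logp_and_grad(theta)
    for _ in range(n_steps):
        p = p + 0.5 * eps * grad
        theta = theta + eps * (inv_mass * p)
        lp, grad = logp_and_grad(theta)
        if not np.isfinite(lp):
            return theta, p, lp
        p = p + 0.5 * eps * grad
    return theta, p, lp


def sample(
    logp_and_grad,
    theta0: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    init_step: float = 0.1,
    traj_length: float = 14.0,
    max_leapfrog: int = 512,
) -> HMCResult:
    """Run one HMC chain.

    ``logp_and_grad(theta) -> (float, ndarray)`` is the unnormalized
    log density and its gradient.  The trajectory uses roughly
    ``traj_length / step_size`` leapfrog steps (jittered uniformly
    over the upper half of that range, capped at ``max_leapfrog``).
    Warmup adapts the step size throughout and re-estimates a diagonal
    inverse mass matrix in doubling windows; sampling runs with both
    frozen.
    """
    theta = np.array(theta0, dtype=float)
    dim = theta.size
    inv_mass = np.ones(dim)
    eps = float(init_step)
    da = DualAveraging(target=target_accept)
    da.restart(eps)

    # doubling mass windows inside [0.15, 0.9] of warmup
    w_start = int(0.15 * n_warmup)
    w_end = int(0.9 * n_warmup)
    window_edges = []
    w = 25
    pos = w_start
    while pos + w < w_end:
        pos += w
        window_edges.append(pos)
        w *= 2
    window_edges.append(w_end)

    acc_buf = []
    lp_cur, _ = logp_and_grad(theta)
    n_div = 0
    n_frog = 0
    win_sum = np.zeros(dim)
    win_sq = np.zeros(dim)
    win_n = 0
    samples = np.empty((n_samples, dim))
    logps = np.empty(n_samples)
    accs = np.empty(n_samples)

    total = n_warmup + n_samples
    for it in range(total):
        warming = it < n_warmup
        n_base = int(np.clip(np.round(traj_length / eps), 1, max_leapfrog))
        lo = max(1, n_base // 2)
        n_steps = int(rng.integers(lo, n_base + 1))
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        ham0 = -lp_cur + 0.5 * np.sum(inv_mass * p0**2)
        theta_new, p_new, lp_new = _leapfrog(logp_and_grad, theta, p0, eps, n_steps, inv_mass)
        n_frog += n_steps
        if np.isfinite(lp_new):
            ham1 = -lp_new + 0.5 * np.sum(inv_mass * p_new**2)
            d_energy = ham1 - ham0
        else:
            d_energy = np.inf
        if not np.isfinite(d_energy) or d_energy > DIVERGENCE_THRESHOLD:
            accept_stat = 0.0
            if not warming:
                n_div += 1
        else:
            accept_stat = float(min(1.0, np.exp(-d_energy)))
            if np.log(rng.random()) < -d_energy:
                theta, lp_cur = theta_new, lp_new

        if warming:
            eps = da.update(accept_stat)
            if w_start <= it < w_end:
                win_sum += theta
                win_sq += theta**2
                win_n += 1
                if it + 1 in window_edges and win_n > 4:
                    var = win_sq / win_n - (win_sum / win_n) ** 2
                    reg = win_n / (win_n + 5.0)
                    inv_mass = reg * np.clip(var, 1e-10, None) + (1.0 - reg) * 1e-3
                    win_sum[:] = 0.0
                    win_sq[:] = 0.0
                    win_n = 0
                    eps = da.adapted
                    da.restart(eps)
            if it == n_warmup - 1:
                eps = da.adapted
        else:
            k = it - n_warmup
            samples[k] = theta
            logps[k] = lp_cur
            accs[k] = accept_stat

    return HMCResult(
        samples=samples,
        logp=logps,
        accept_stat=accs,
        step_size=eps,
        inv_mass=inv_mass,
        n_divergent=n_div,
        n_leapfrog=n_frog,
    )
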