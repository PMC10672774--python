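"""No-U-Turn sampler on a generic log-density-with-gradient callable.

Implements slice-variant NUTS (doubling trajectories) with dual-averaging
step-size adaptation and diagonal mass-matrix estimation in expanding
warm-up windows.  Depends only on numpy; the model supplies
``logp_grad(theta) -> (float, ndarray)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NutsStats", "sample_nuts"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NutsStats:
    """Per-chain sampler statistics."""

    accept_prob: np.ndarray  # mean Metropolis acceptance per retained iteration
    n_divergent: int
    treedepth: np.ndarray
    step_size: float
    inv_mass: np.ndarray


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r_half = r + 0.5 * eps * grad
    theta_new = theta + eps * inv_mass * r_half
    logp_new, grad_new = logp_grad(theta_new)
    if not np.all(np.isfinite(grad_new)):
        logp_new, grad_new = -np.inf, np.zeros_like(grad_new)
    r_new = r_half + 0.5 * eps * grad_new
    return theta_new, r_new, logp_new, grad_new


def _find_reasonable_epsilon(logp_grad, theta, logp, grad, inv_mass, rng):
    """Double/halve the step size until the one-step accept prob crosses 0.5."""
    eps = 1.0
    r = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    joint0 = logp - 0.5 * np.sum(inv_mass * r * r)
    _, r1, logp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
    joint1 = logp1 - 0.5 * np.sum(inv_mass * r1 * r1)
    if not np.isfinite(joint1):
        joint1 = -np.inf
    direction = 1.0 if (joint1 - joint0) > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        _, r1, logp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
        joint1 = logp1 - 0.5 * np.sum(inv_mass * r1 * r1)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction * (joint1 - joint0) <= direction * np.log(0.5):
            break
    return float(max(min(eps, 10.0), 1e-10))


def _no_uturn(theta_minus, r_minus, theta_plus, r_plus, inv_mass):
    dtheta = theta_plus - theta_minus
    return int(
        np.dot(dtheta, inv_mass * r_minus) >= 0 and np.dot(dtheta, inv_mass * r_plus) >= 0
    )


class _Tree:
    """Recursive doubling of one NUTS trajectory (slice variant)."""

    __slots__ = (
        "logp_grad", "inv_mass", "logu", "joint0", "eps", "rng",
        "alpha_sum", "n_alpha", "divergent",
    )

    def __init__(self, logp_grad, inv_mass, logu, joint0, eps, rng):
        self.logp_grad = logp_grad
        self.inv_mass = inv_mass
        self.logu = logu
        self.joint0 = joint0
        self.eps = eps
        self.rng = rng
        self.alpha_sum = 0.0
        self.n_alpha = 0
        self.divergent = False

    def build(self, theta, r, grad, v, depth):
        """Returns (theta-, r-, grad-, theta+, r+, grad+, theta', logp', n', s')."""
        if depth == 0:
            theta1, r1, logp1, grad1 = _leapfrog(
                self.logp_grad, theta, r, grad, v * self.eps, self.inv_mass
            )
            joint = logp1 - 0.5 * np.sum(self.inv_mass * r1 * r1)
            n1 = int(self.logu <= joint)
            s1 = int(self.logu < joint + _DIVERGENCE_THRESHOLD)
            if not s1:
                self.divergent = True
            self.alpha_sum += min(1.0, float(np.exp(min(joint - self.joint0, 0.0))))
            self.n_alpha += 1
            return theta1, r1, grad1, theta1, r1, grad1, theta1, logp1, n1, s1
        tm, rm, gm, tp, rp, gp, t1, logp1, n1, s1 = self.build(theta, r, grad, v, depth - 1)
        if s1:
            if v == -1:
                tm, rm, gm, _, _, _, t2, logp2, n2, s2 = self.build(tm, rm, gm, v, depth - 1)
            else:
                _, _, _, tp, rp, gp, t2, logp2, n2, s2 = self.build(tp, rp, gp, v, depth - 1)
            if n2 > 0 and self.rng.random() < n2 / (n1 + n2):
                t1, logp1 = t2, logp2
            n1 += n2
            s1 = s2 * _no_uturn(tm, rm, tp, rp, self.inv_mass)
        return tm, rm, gm, tp, rp, gp, t1, logp1, n1, s1


def _transition(logp_grad, theta, logp, grad, eps, inv_mass, rng, max_treedepth):
    """One NUTS update; returns (theta, logp, grad, accept_stat, depth, divergent)."""
    r0 = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    joint0 = logp - 0.5 * np.sum(inv_mass * r0 * r0)
    logu = joint0 - rng.exponential()
    tree = _Tree(logp_grad, inv_mass, logu, joint0, eps, rng)
    tm, rm, gm = theta, r0, grad
    tp, rp, gp = theta, r0, grad
    theta_new, logp_new = theta, logp
    moved = False
    n, s, depth = 1, 1, 0
    while s and depth < max_treedepth:
        v = 1 if rng.random() < 0.5 else -1
        if v == -1:
            tm, rm, gm, _, _, _, t1, logp1, n1, s1 = tree.build(tm, rm, gm, v, depth)
        else:
            _, _, _, tp, rp, gp, t1, logp1, n1, s1 = tree.build(tp, rp, gp, v, depth)
        if s1 and n1 > 0 and rng.random() < min(1.0, n1 / n):
            theta_new, logp_new = t1, logp1
            moved = True
        n += n1
        s = s1 * _no_uturn(tm, rm, tp, rp, inv_mass)
        depth += 1
    grad_new = grad
    if moved:
        _, grad_new = logp_grad(theta_new)
    accept = tree.alpha_sum / max(tree.n_alpha, 1)
    return theta_new, logp_new, grad_new, accept, depth, tree.divergent


def _adaptation_schedule(warmup: int) -> list[tuple[int, int]]:
    """Slow-window boundaries (start, end) for mass adaptation, Stan-style."""
    if warmup < 40:
        return []
    init_buffer = max(int(0.15 * warmup), 10)
    term_buffer = max(int(0.10 * warmup), 10)
    windows = []
    start = init_buffer
    size = max(int(0.0625 * warmup), 25)
    while start + size < warmup - term_buffer:
        end = start + size
        if start + 3 * size >= warmup - term_buffer:
            end = warmup - term_buffer  # absorb the remainder into the last window
        windows.append((start, end))
        start = end
        size *= 2
    return windows


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    init: np.ndarray,
    n_iter: int,
    warmup: int,
    rng: np.random.Generator,
    max_treedepth: int = 10,
    target_accept: float = 0.8,
    thin: int = 1,
) -> tuple[np.ndarray, NutsStats]:
    """Run one NUTS chain; returns retained post-warm-up draws and stats.

    ``n_iter`` counts all iterations including warm-up; draws are thinned
    post-warm-up, giving ``ceil((n_iter - warmup) / thin)`` retained draws.
    """
    if warmup >= n_iter:
        raise ValueError(f"warmup ({warmup}) must be < n_iter ({n_iter})")
    if thin < 1:
        raise ValueError(f"thin must be >= 1, got {thin}")
    theta = np.asarray(init, dtype=float).copy()
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    inv_mass = np.ones(theta.size)
    eps = _find_reasonable_epsilon(logp_grad, theta, logp, grad, inv_mass, rng)

    # dual averaging state (standard defaults)
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    windows = _adaptation_schedule(warmup)
    window_idx = 0
    w_n, w_mean, w_m2 = 0, np.zeros(theta.size), np.zeros(theta.size)

    n_post = n_iter - warmup
    n_keep = (n_post + thin - 1) // thin
    draws = np.empty((n_keep, theta.size))
    accept_hist = np.empty(n_post)
    depth_hist = np.empty(n_post, dtype=int)
    n_divergent = 0
    kept = 0

    for m in range(n_iter):
        theta, logp, grad, accept, depth, divergent = _transition(
            logp_grad, theta, logp, grad, eps, inv_mass, rng, max_treedepth
        )
        if m < warmup:
            da_count += 1
            h_bar = (1 - 1 / (da_count + t0)) * h_bar + (target_accept - accept) / (da_count + t0)
            log_eps = mu_da - np.sqrt(da_count) / gamma * h_bar
            eta = da_count**-kappa
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if window_idx < len(windows):
                w_start, w_end = windows[window_idx]
                if w_start <= m < w_end:
                    w_n += 1
                    delta = theta - w_mean
                    w_mean += delta / w_n
                    w_m2 += delta * (theta - w_mean)
                if m == w_end - 1:
                    var = w_m2 / max(w_n - 1, 1)
                    inv_mass = (w_n / (w_n + 5.0)) * var + 1e-3 * (5.0 / (w_n + 5.0))
                    inv_mass = np.maximum(inv_mass, 1e-10)
                    window_idx += 1
                    w_n, w_mean, w_m2 = 0, np.zeros(theta.size), np.zeros(theta.size)
                    eps = _find_reasonable_epsilon(logp_grad, theta, logp, grad, inv_mass, rng)
                    mu_da = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if m == warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            post = m - warmup
            accept_hist[post] = accept
            depth_hist[post] = depth
            n_divergent += int(divergent)
            if post % thin == 0:
                draws[kept] = theta
                kept += 1

    stats = NutsStats(
        accept_prob=accept_hist,
        n_divergent=n_divergent,
        treedepth=depth_hist,
        step_size=eps,
        inv_mass=inv_mass,
    )
    return draws, stats
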