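"""No-U-Turn Hamiltonian Monte Carlo sampler.

A self-contained NUTS implementation (multinomial state selection,
dual-averaging step-size adaptation, windowed diagonal mass-matrix
adaptation) operating on an unconstrained log density with analytic
gradient.  Divergences are flagged when the Hamiltonian error exceeds a
large threshold; non-finite log densities are treated as divergent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MAX_ENERGY_ERROR = 1000.0


@dataclass
class SamplerStats:
    step_size: float
    depths: np.ndarray
    divergences: int
    accept_mean: float
    inv_mass: np.ndarray


class _Tree:
    __slots__ = (
        "u_minus",
        "p_minus",
        "u_plus",
        "p_plus",
        "u_prop",
        "g_prop",
        "logp_prop",
        "log_weight",
        "sum_accept",
        "n_accept",
        "turning",
        "diverging",
        "_g_minus",
        "_g_plus",
    )


def _leapfrog(logp_grad, u, p, g, eps, inv_mass):
    with np.errstate(over="ignore", invalid="ignore"):
        p = p + 0.5 * eps * g
        u = u + eps * inv_mass * p
        logp, g_new = logp_grad(u)
        p = p + 0.5 * eps * g_new
    return u, p, g_new, logp


def _kinetic(p, inv_mass):
    with np.errstate(over="ignore", invalid="ignore"):
        return 0.5 * float(np.dot(p, inv_mass * p))


def _uturn(u_plus, u_minus, p_plus, p_minus, inv_mass):
    du = u_plus - u_minus
    return (
        float(np.dot(du, inv_mass * p_minus)) < 0.0
        or float(np.dot(du, inv_mass * p_plus)) < 0.0
    )


def _build_tree(logp_grad, u, p, g, logp, direction, depth, eps, inv_mass, h0, rng):
    tree = _Tree()
    if depth == 0:
        u1, p1, g1, logp1 = _leapfrog(logp_grad, u, p, g, direction * eps, inv_mass)
        h1 = -logp1 + _kinetic(p1, inv_mass) if np.isfinite(logp1) else np.inf
        energy_error = h1 - h0
        tree.diverging = not np.isfinite(energy_error) or energy_error > _MAX_ENERGY_ERROR
        tree.turning = False
        tree.u_minus = tree.u_plus = tree.u_prop = u1
        tree.p_minus = tree.p_plus = p1
        tree.g_prop = g1
        tree.logp_prop = logp1
        tree.log_weight = -np.inf if tree.diverging else -energy_error
        with np.errstate(over="ignore"):
            accept = 0.0 if tree.diverging else min(1.0, float(np.exp(-energy_error)))
        tree.sum_accept = accept
        tree.n_accept = 1
        # stash endpoint gradient for continuation
        tree._g_minus = tree._g_plus = g1
        return tree

    first = _build_tree(
        logp_grad, u, p, g, logp, direction, depth - 1, eps, inv_mass, h0, rng
    )
    if first.diverging or first.turning:
        return first
    if direction == 1:
        u_edge, p_edge, g_edge = first.u_plus, first.p_plus, first._g_plus
    else:
        u_edge, p_edge, g_edge = first.u_minus, first.p_minus, first._g_minus
    second = _build_tree(
        logp_grad,
        u_edge,
        p_edge,
        g_edge,
        None,
        direction,
        depth - 1,
        eps,
        inv_mass,
        h0,
        rng,
    )
    tree = _Tree()
    tree.diverging = second.diverging
    tree.sum_accept = first.sum_accept + second.sum_accept
    tree.n_accept = first.n_accept + second.n_accept
    if direction == 1:
        tree.u_minus, tree.p_minus = first.u_minus, first.p_minus
        tree._g_minus = first._g_minus
        tree.u_plus, tree.p_plus = second.u_plus, second.p_plus
        tree._g_plus = second._g_plus
    else:
        tree.u_minus, tree.p_minus = second.u_minus, second.p_minus
        tree._g_minus = second._g_minus
        tree.u_plus, tree.p_plus = first.u_plus, first.p_plus
        tree._g_plus = first._g_plus
    tree.log_weight = np.logaddexp(first.log_weight, second.log_weight)
    # multinomial choice between the two halves
    if np.isfinite(second.log_weight) and np.log(rng.uniform()) < (
        second.log_weight - tree.log_weight
    ):
        tree.u_prop, tree.g_prop, tree.logp_prop = (
            second.u_prop,
            second.g_prop,
            second.logp_prop,
        )
    else:
        tree.u_prop, tree.g_prop, tree.logp_prop = (
            first.u_prop,
            first.g_prop,
            first.logp_prop,
        )
    tree.turning = second.turning or _uturn(
        tree.u_plus, tree.u_minus, tree.p_plus, tree.p_minus, inv_mass
    )
    return tree


def _nuts_step(logp_grad, u, g, logp, eps, inv_mass, max_depth, rng):
    p0 = rng.standard_normal(u.size) / np.sqrt(inv_mass)
    h0 = -logp + _kinetic(p0, inv_mass)
    u_minus = u_plus = u
    p_minus = p_plus = p0
    g_minus = g_plus = g
    u_curr, g_curr, logp_curr = u, g, logp
    log_weight = 0.0  # weight of the initial point
    sum_accept = 0.0
    n_accept = 0
    divergent = False
    depth = 0
    while depth < max_depth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            tree = _build_tree(
                logp_grad, u_plus, p_plus, g_plus, None, direction, depth, eps,
                inv_mass, h0, rng,
            )
        else:
            tree = _build_tree(
                logp_grad, u_minus, p_minus, g_minus, None, direction, depth, eps,
                inv_mass, h0, rng,
            )
        sum_accept += tree.sum_accept
        n_accept += tree.n_accept
        if tree.diverging:
            divergent = True
            break
        if tree.turning:
            # subtree with an internal U-turn is invalid: discard it whole
            break
        # biased progressive sampling: take the new subtree's proposal with
        # probability min(1, w_new / w_old)
        if np.isfinite(tree.log_weight) and np.log(rng.uniform()) < (
            tree.log_weight - log_weight
        ):
            u_curr, g_curr, logp_curr = tree.u_prop, tree.g_prop, tree.logp_prop
        log_weight = np.logaddexp(log_weight, tree.log_weight)
        if direction == 1:
            u_plus, p_plus, g_plus = tree.u_plus, tree.p_plus, tree._g_plus
        else:
            u_minus, p_minus, g_minus = tree.u_minus, tree.p_minus, tree._g_minus
        depth += 1
        if _uturn(u_plus, u_minus, p_plus, p_minus, inv_mass):
            break
    accept_stat = sum_accept / max(n_accept, 1)
    return u_curr, g_curr, logp_curr, depth, divergent, accept_stat


def _find_initial_step(logp_grad, u, g, logp, inv_mass, rng):
    eps = 1.0
    p0 = rng.standard_normal(u.size) / np.sqrt(inv_mass)
    h0 = -logp + _kinetic(p0, inv_mass)
    _, p1, _, logp1 = _leapfrog(logp_grad, u, p0, g, eps, inv_mass)
    h1 = -logp1 + _kinetic(p1, inv_mass) if np.isfinite(logp1) else np.inf
    direction = 1.0 if (h0 - h1) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, _, logp1 = _leapfrog(logp_grad, u, p0, g, eps, inv_mass)
        h1 = -logp1 + _kinetic(p1, inv_mass) if np.isfinite(logp1) else np.inf
        crossed = (h0 - h1) * direction < np.log(0.5) * direction
        if crossed:
            break
    return eps


def _adaptation_windows(n_warmup):
    """Stan-style warmup schedule: fast start, doubling slow windows, fast
    end.  Returns [(start, end), ...] windows over which the posterior
    variance is estimated; the mass matrix is refreshed at each window end."""
    if n_warmup < 60:
        return [(max(n_warmup // 3, 1), max(2 * n_warmup // 3, 2))]
    init = max(int(0.15 * n_warmup), 10)
    term = max(int(0.2 * n_warmup), 20)
    windows = []
    start = init
    size = 25
    while start + size <= n_warmup - term:
        if start + 3 * size > n_warmup - term:
            size = (n_warmup - term) - start
        windows.append((start, start + size))
        start += size
        size *= 2
    if not windows:
        windows.append((init, n_warmup - term))
    return windows


def nuts_sample(
    logp_grad,
    u0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    max_depth: int = 8,
    target_accept: float = 0.8,
    post_step=None,
) -> tuple[np.ndarray, SamplerStats]:
    """Run one NUTS chain; returns (draws, stats) with draws (n_draws, dim).

    post_step(u, rng) -> u, if given, is applied after every iteration; it
    must be a posterior-invariant update (e.g. a Gibbs move on a subspace).
    """
    u = np.array(u0, dtype=float)
    logp, g = logp_grad(u)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    dim = u.size
    inv_mass = np.ones(dim)

    eps = _find_initial_step(logp_grad, u, g, logp, inv_mass, rng)
    # dual averaging state
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma_da, t0_da, kappa_da = 0.05, 10.0, 0.75

    windows = _adaptation_windows(n_warmup)
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    depths = np.empty(n_warmup + n_draws, dtype=int)
    divergences = 0
    accept_sum = 0.0

    da_iter = 0
    for it in range(n_warmup + n_draws):
        u, g, logp, depth, divergent, accept = _nuts_step(
            logp_grad, u, g, logp, eps, inv_mass, max_depth, rng
        )
        if post_step is not None:
            u_new = post_step(u, rng)
            if u_new is not u:
                u = u_new
                logp, g = logp_grad(u)
        depths[it] = depth
        if divergent and it >= n_warmup:
            divergences += 1
        if it < n_warmup:
            da_iter += 1
            h_bar = (1.0 - 1.0 / (da_iter + t0_da)) * h_bar + (
                target_accept - accept
            ) / (da_iter + t0_da)
            log_eps = mu_da - np.sqrt(da_iter) / gamma_da * h_bar
            w = da_iter**-kappa_da
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if windows and windows[0][0] <= it + 1 <= windows[0][1]:
                welford_n += 1
                delta = u - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (u - welford_mean)
            if windows and (it + 1) == windows[0][1]:
                if welford_n > 4:
                    var = welford_m2 / max(welford_n - 1, 1)
                    inv_mass = (welford_n / (welford_n + 5.0)) * var + 1e-3 * (
                        5.0 / (welford_n + 5.0)
                    )
                welford_n = 0
                welford_mean[:] = 0.0
                welford_m2[:] = 0.0
                windows.pop(0)
                # restart step-size adaptation around the refreshed metric
                eps = _find_initial_step(logp_grad, u, g, logp, inv_mass, rng)
                mu_da = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0
            if it + 1 == n_warmup:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = u
            accept_sum += accept

    stats = SamplerStats(
        step_size=eps,
        depths=depths[n_warmup:],
        divergences=divergences,
        accept_mean=accept_sum / max(n_draws, 1),
        inv_mass=inv_mass,
    )
    return draws, stats
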