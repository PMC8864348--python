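"""No-U-Turn sampler with dual-averaging step size and diagonal mass.

A self-contained gradient-based MCMC kernel used by :mod:`.inference`.
The implementation follows the recursive tree-doubling construction
with a slice variable, doubling until the trajectory makes a U-turn or
the maximum tree depth is reached.  During warmup the step size is
adapted by dual averaging toward a target acceptance statistic and a
diagonal mass matrix is estimated from the warmup draws in doubling
windows.  Trajectories whose energy error exceeds 1000 are counted as
divergent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NutsResult", "nuts"]

_DIVERGENCE = 1000.0


@dataclass
class NutsResult:
    draws: np.ndarray        # (n_draws, dim) post-warmup draws
    logps: np.ndarray        # (n_draws,) log-density at each draw
    accept_stat: np.ndarray  # (n_draws,) mean Metropolis statistic
    treedepths: np.ndarray   # (n_draws,) tree depth reached
    divergences: int         # divergent transitions after warmup
    step_size: float
    inv_mass: np.ndarray     # (dim,) estimated posterior variances


def _joint(logp, r, inv_mass):
    return logp - 0.5 * float(np.dot(r * r, inv_mass))


class _Tree:
    """State bundle for the recursive doubling (mutated in place)."""

    __slots__ = ("f", "eps", "inv_mass", "logu", "joint0", "rng",
                 "diverged", "alpha_sum", "n_alpha")

    def __init__(self, f, eps, inv_mass, logu, joint0, rng):
        self.f = f
        self.eps = eps
        self.inv_mass = inv_mass
        self.logu = logu
        self.joint0 = joint0
        self.rng = rng
        self.diverged = False
        self.alpha_sum = 0.0
        self.n_alpha = 0

    def leapfrog(self, theta, r, grad, direction):
        eps = direction * self.eps
        r1 = r + 0.5 * eps * grad
        theta1 = theta + eps * self.inv_mass * r1
        logp1, grad1 = self.f(theta1)
        r1 = r1 + 0.5 * eps * grad1
        return theta1, r1, logp1, grad1

    def build(self, theta, r, grad, logp, direction, depth):
        if depth == 0:
            theta1, r1, logp1, grad1 = self.leapfrog(theta, r, grad,
                                                     direction)
            joint = _joint(logp1, r1, self.inv_mass)
            if not np.isfinite(joint) or self.logu - joint > _DIVERGENCE:
                self.diverged = True
                n_ok, s_ok = 0, 0
                alpha = 0.0
            else:
                n_ok = int(self.logu <= joint)
                s_ok = 1
                alpha = min(1.0, np.exp(joint - self.joint0))
            self.alpha_sum += alpha
            self.n_alpha += 1
            return (theta1, r1, grad1, logp1, theta1, r1, grad1, logp1,
                    theta1, logp1, n_ok, s_ok)
        # recursive doubling
        (tm, rm, gm, lpm, tp, rp, gp, lpp,
         tprop, lprop, n1, s1) = self.build(theta, r, grad, logp,
                                            direction, depth - 1)
        if s1 == 1:
            if direction == -1:
                (tm, rm, gm, lpm, _, _, _, _,
                 tprop2, lprop2, n2, s2) = self.build(tm, rm, gm, lpm,
                                                      direction, depth - 1)
            else:
                (_, _, _, _, tp, rp, gp, lpp,
                 tprop2, lprop2, n2, s2) = self.build(tp, rp, gp, lpp,
                                                      direction, depth - 1)
            if n1 + n2 > 0 and self.rng.random() < n2 / (n1 + n2):
                tprop, lprop = tprop2, lprop2
            n1 += n2
            s1 = s2 * self._no_uturn(tm, rm, tp, rp)
        return tm, rm, gm, lpm, tp, rp, gp, lpp, tprop, lprop, n1, s1

    def _no_uturn(self, tm, rm, tp, rp):
        dt = tp - tm
        return int((dt @ (self.inv_mass * rm) >= 0)
                   and (dt @ (self.inv_mass * rp) >= 0))


def _find_reasonable_eps(f, theta, logp, grad, inv_mass, rng):
    eps = 1.0
    r = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    joint0 = _joint(logp, r, inv_mass)
    tree = _Tree(f, eps, inv_mass, 0.0, joint0, rng)
    _, r1, logp1, _ = tree.leapfrog(theta, r, grad, 1)
    joint1 = _joint(logp1, r1, inv_mass)
    if not np.isfinite(joint1):
        joint1 = -np.inf
    direction = 1.0 if joint1 - joint0 > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        tree.eps = eps
        _, r1, logp1, _ = tree.leapfrog(theta, r, grad, 1)
        joint1 = _joint(logp1, r1, inv_mass)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction * (joint1 - joint0) <= direction * np.log(0.5):
            break
    return eps


def _mass_windows(n_warmup):
    """(start, end) iteration ranges of the mass-adaptation windows."""
    init = max(1, int(round(0.15 * n_warmup)))
    term = max(1, int(round(0.10 * n_warmup)))
    lo, hi = init, n_warmup - term
    if hi - lo < 10:
        return []
    windows = []
    size = max(10, (hi - lo) // 7)
    start = lo
    while start < hi:
        end = min(hi, start + size)
        if hi - end < size:  # fold the remainder into the last window
            end = hi
        windows.append((start, end))
        size *= 2
        start = end
    return windows


def nuts(logp_grad, theta0, n_warmup, n_draws, rng, *,
         target_accept=0.8, max_treedepth=10, thin=1) -> NutsResult:
    """Run one NUTS chain.

    Parameters
    ----------
    logp_grad : callable
        theta -> (log density, gradient).
    theta0 : initial position
    n_warmup : adaptation iterations (discarded)
    n_draws : post-warmup iterations to run
    rng : numpy Generator or seed
    thin : keep every ``thin``-th post-warmup draw
    """
    rng = np.random.default_rng(rng)
    theta = np.array(theta0, dtype=float)
    dim = theta.size
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    inv_mass = np.ones(dim)
    eps = _find_reasonable_eps(logp_grad, theta, logp, grad, inv_mass, rng)

    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    windows = _mass_windows(n_warmup)
    win_idx = 0
    win_sum = np.zeros(dim)
    win_sq = np.zeros(dim)
    win_n = 0

    n_total = n_warmup + n_draws
    kept = []
    kept_logp = []
    kept_accept = []
    kept_depth = []
    divergences = 0

    for it in range(n_total):
        adapting = it < n_warmup
        r = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = _joint(logp, r, inv_mass)
        logu = joint0 + np.log1p(-rng.random())  # log U(0,1) + joint0
        tree = _Tree(logp_grad, eps, inv_mass, logu, joint0, rng)

        tm, rm, gm, lpm = theta, r, grad, logp
        tp, rp, gp, lpp = theta, r, grad, logp
        n_kept, s, depth = 1, 1, 0
        while s == 1 and depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == -1:
                (tm, rm, gm, lpm, _, _, _, _,
                 tprop, lprop, n1, s1) = tree.build(tm, rm, gm, lpm,
                                                    -1, depth)
            else:
                (_, _, _, _, tp, rp, gp, lpp,
                 tprop, lprop, n1, s1) = tree.build(tp, rp, gp, lpp,
                                                    1, depth)
            if s1 == 1 and n1 > 0 and rng.random() < min(1.0, n1 / n_kept):
                theta, logp = tprop, lprop
                _, grad = logp_grad(theta)
            n_kept += n1
            s = s1 * tree._no_uturn(tm, rm, tp, rp)
            depth += 1

        accept = tree.alpha_sum / max(tree.n_alpha, 1)
        if tree.diverged and not adapting:
            divergences += 1

        if adapting:
            da_count += 1
            h_bar = ((1.0 - 1.0 / (da_count + t0)) * h_bar
                     + (target_accept - accept) / (da_count + t0))
            log_eps = mu - np.sqrt(da_count) / gamma * h_bar
            w = da_count ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))

            if win_idx < len(windows):
                lo, hi = windows[win_idx]
                if lo <= it < hi:
                    win_sum += theta
                    win_sq += theta * theta
                    win_n += 1
                if it == hi - 1 and win_n > 1:
                    var = win_sq / win_n - (win_sum / win_n) ** 2
                    inv_mass = (win_n / (win_n + 5.0)) * np.maximum(var, 0.0) \
                        + 1e-3 * (5.0 / (win_n + 5.0))
                    win_sum[:] = 0.0
                    win_sq[:] = 0.0
                    win_n = 0
                    win_idx += 1
                    # re-initialize step size for the new metric
                    eps = _find_reasonable_eps(logp_grad, theta, logp,
                                               grad, inv_mass, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            if (it - n_warmup) % thin == 0:
                kept.append(theta.copy())
                kept_logp.append(logp)
                kept_accept.append(accept)
                kept_depth.append(depth)

    return NutsResult(
        draws=np.array(kept),
        logps=np.array(kept_logp),
        accept_stat=np.array(kept_accept),
        treedepths=np.array(kept_depth, dtype=int),
        divergences=divergences,
        step_size=eps,
        inv_mass=inv_mass,
    )
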