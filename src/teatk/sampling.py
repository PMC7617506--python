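"""Adaptive random-walk Metropolis primitives.

The population fit uses Metropolis-within-Gibbs built from the scalar
update in :func:`mh_accept`; :func:`run_mh` is the same kernel packaged
as a stand-alone coordinate-wise sampler for low-dimensional targets
(used, e.g., to validate the likelihood against dense grid
integration).  Step sizes adapt in batches during burn-in only, so the
post-burn-in chain is a fixed-kernel Markov chain.
"""

from __future__ import annotations

import numpy as np

__all__ = ["StepAdapter", "mh_accept", "run_mh"]

#: target acceptance rate for scalar (single-coordinate) updates
TARGET_ACCEPT = 0.44


class StepAdapter:
    """Batch step-size adaptation for a bank of scalar MH steps.

    Every ``batch`` iterations during burn-in the log step of each
    coordinate moves toward the target acceptance rate with a
    diminishing Robbins–Monro gain; after ``freeze()`` steps are fixed.
    """

    def __init__(self, shape, step0=0.5, batch=50, target=TARGET_ACCEPT):
        self.log_step = np.full(shape, np.log(step0))
        self.accepts = np.zeros(shape)
        self.counts = np.zeros(shape)
        self.batch = batch
        self.target = target
        self.batch_no = np.zeros(shape)
        self.frozen = False

    @property
    def step(self) -> np.ndarray:
        return np.exp(self.log_step)

    def record(self, accepted, active=None) -> None:
        """Record accept indicators; ``active`` masks coordinates that
        were actually proposed this iteration (default: all)."""
        if self.frozen:
            return
        if active is None:
            self.accepts += accepted
            self.counts += 1.0
        else:
            self.accepts[active] += np.asarray(accepted)[active] \
                if np.ndim(accepted) else accepted
            self.counts[active] += 1.0
        ready = self.counts >= self.batch
        if ready.any():
            self.batch_no[ready] += 1.0
            rate = self.accepts[ready] / self.counts[ready]
            gain = 1.0 / np.sqrt(self.batch_no[ready])
            self.log_step[ready] += gain * (rate - self.target)
            np.clip(self.log_step, -12.0, 4.0, out=self.log_step)
            self.accepts[ready] = 0.0
            self.counts[ready] = 0.0

    def freeze(self) -> None:
        self.frozen = True


def mh_accept(rng: np.random.Generator, log_ratio) -> np.ndarray:
    """Vector of Metropolis accept decisions for log posterior ratios."""
    log_ratio = np.asarray(log_ratio, dtype=float)
    u = rng.random(log_ratio.shape)
    with np.errstate(invalid="ignore"):
        return np.log(u) < log_ratio


def run_mh(logpost, x0, n_iter, seed=None, step0=0.5, burn_frac=0.5):
    """Coordinate-wise adaptive random-walk Metropolis sampler.

    Parameters
    ----------
    logpost : callable
        Log target density on R^d (may return -inf outside support).
    x0 : array-like
        Starting point, shape (d,).
    n_iter : int
        Total iterations; the first ``burn_frac`` fraction is discarded
        (adaptation happens only there).

    Returns
    -------
    draws : ndarray, shape (n_kept, d)
    accept_rate : float
        Post-burn-in acceptance rate, averaged over coordinates.
    """
    rng = np.random.default_rng(seed)
    x = np.array(x0, dtype=float)
    d = x.size
    lp = float(logpost(x))
    if not np.isfinite(lp):
        raise ValueError("logpost(x0) must be finite")
    n_burn = int(n_iter * burn_frac)
    adapter = StepAdapter(d, step0=step0)
    kept = np.empty((n_iter - n_burn, d))
    acc_post = 0
    n_post = 0
    for it in range(n_iter):
        if it == n_burn:
            adapter.freeze()
        accepted = np.zeros(d)
        for j in range(d):
            prop = x.copy()
            prop[j] += adapter.step[j] * rng.standard_normal()
            lp_prop = float(logpost(prop))
            if mh_accept(rng, lp_prop - lp):
                x, lp = prop, lp_prop
                accepted[j] = 1.0
        adapter.record(accepted)
        if it >= n_burn:
            kept[it - n_burn] = x
            acc_post += accepted.sum()
            n_post += d
    return kept, acc_post / max(n_post, 1)
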