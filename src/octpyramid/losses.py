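"""Robust reconstruction losses for the scale-adaptation autoencoder.

Two losses are used. The pseudo-Huber loss

    PH_delta(x) = delta^2 * (sqrt(1 + (x/delta)^2) - 1)

is a smooth robust penalty: quadratic (~x^2/2) for |x| << delta and linear
(~delta*|x|) for |x| >> delta, which keeps outlier pixels (specular
reflections, speckle spikes) from dominating the reconstruction. The log-cosh
loss log(cosh(x)) behaves similarly but is twice differentiable everywhere.

The combined autoencoder objective puts two pseudo-Huber terms on the
high-resolution side (the 224x224 output branch and the latent map F_AE, both
compared against the 224x224 target) and one log-cosh term on the
low-resolution branch (the reconstruction at the original input size,
compared against the original image). All reductions are means.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pseudo_huber", "log_cosh", "combined_ae_loss", "pseudo_huber_grad", "log_cosh_grad"]

_LOG2 = float(np.log(2.0))


def pseudo_huber(x, delta: float = 1.0):
    """Elementwise pseudo-Huber loss ``delta^2 (sqrt(1 + (x/delta)^2) - 1)``.

    Parameters
    ----------
    x : array_like
        Residuals (any shape); the result has the same shape.
    delta : float
        Transition scale between the quadratic and linear regimes; must be
        positive.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    x = np.asarray(x)
    z = x / delta
    return delta * delta * (np.sqrt(1.0 + z * z) - 1.0)


def pseudo_huber_grad(x, delta: float = 1.0):
    """d/dx of :func:`pseudo_huber`: ``x / sqrt(1 + (x/delta)^2)``."""
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    x = np.asarray(x)
    z = x / delta
    return x / np.sqrt(1.0 + z * z)


def log_cosh(x):
    """Elementwise ``log(cosh(x))``, overflow-safe.

    For large |x| the direct form overflows, so the identity
    ``log(cosh(x)) = |x| - log 2 + log1p(exp(-2|x|))`` is used instead; it is
    exact and stable for |x| up to the float range.
    """
    ax = np.abs(np.asarray(x, dtype=float))
    return ax - _LOG2 + np.log1p(np.exp(-2.0 * ax))


def log_cosh_grad(x):
    """d/dx of :func:`log_cosh`: ``tanh(x)``."""
    return np.tanh(np.asarray(x, dtype=float))


def combined_ae_loss(high_res, f_ae, low_res, target_hi, original,
                     w_hi: float = 1.0, w_lo: float = 1.0,
                     delta: float = 1.0) -> float:
    """Combined autoencoder objective.

    ``w_hi * [mean PH(high_res - target_hi) + mean PH(f_ae - target_hi)]
    + w_lo * mean logcosh(low_res - original)``

    Shapes of each compared pair must match; weights must be nonnegative and
    not both zero. Returns a nonnegative scalar that is zero iff every
    residual is zero.
    """
    if w_hi < 0 or w_lo < 0 or (w_hi == 0 and w_lo == 0):
        raise ValueError("loss weights must be nonnegative and not both zero")
    high_res, f_ae = np.asarray(high_res), np.asarray(f_ae)
    low_res, original = np.asarray(low_res), np.asarray(original)
    target_hi = np.asarray(target_hi)
    for got, want, nm in ((high_res, target_hi, "high_res"),
                          (f_ae, target_hi, "f_ae"),
                          (low_res, original, "low_res")):
        if got.shape != want.shape:
            raise ValueError(f"{nm} shape {got.shape} != target shape {want.shape}")
    hi = pseudo_huber(high_res - target_hi, delta).mean() + \
        pseudo_huber(f_ae - target_hi, delta).mean()
    lo = log_cosh(low_res - original).mean()
    return float(w_hi * hi + w_lo * lo)
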