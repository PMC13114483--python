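"""Adversarial and pixel losses of the conditional translation network.

The composite objective is ``L_total = L_GAN + lambda * L1`` with the
regularization weight lambda = 60.  The adversarial term is the
natural-log GAN value ``E[log D(x, y)] + E[log(1 - D(x, G(x)))]`` averaged
over batch and patches; discriminator outputs are clamped away from {0, 1}
by a small epsilon before the logarithm.
"""

from __future__ import annotations

from .autograd import Tensor

__all__ = ["gan_loss", "l1_loss", "total_loss", "LAMBDA_L1", "EPS"]

#: Default L1 regularization weight.
LAMBDA_L1 = 60.0
#: Clamp on discriminator probabilities before the log.
EPS = 1e-7


def gan_loss(d_real: Tensor, d_fake: Tensor) -> Tensor:
    """Adversarial value E[log D(x,y)] + E[log(1 - D(x,G(x)))].

    ``d_real`` and ``d_fake`` are discriminator patch-probability grids for
    (input, ground truth) and (input, generated) pairs respectively.
    """
    d_real = d_real.clamp(EPS, 1.0 - EPS)
    d_fake = d_fake.clamp(EPS, 1.0 - EPS)
    return d_real.log().mean() + (1.0 - d_fake).log().mean()


def l1_loss(y: Tensor, y_hat: Tensor) -> Tensor:
    """Mean absolute deviation between label and generated image."""
    if y.shape != y_hat.shape:
        raise ValueError("shape mismatch")
    return (y - y_hat).abs().mean()


def total_loss(gan: Tensor, l1: Tensor, lambda_l1: float = LAMBDA_L1) -> Tensor:
    """Composite objective: adversarial value plus lambda-weighted L1."""
    return gan + lambda_l1 * l1
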