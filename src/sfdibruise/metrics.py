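"""Image-quality metrics and paired significance testing.

NMAE, PSNR and SSIM quantify agreement between predicted and reference
optical-coefficient maps; a two-tailed paired Student's t-test compares the
per-image error vectors of two models.  PSNR and SSIM follow the 8-bit
convention: coefficient maps are first rescaled to 0-255 through the label
normalization ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import NORM_RANGES

__all__ = [
    "nmae",
    "psnr",
    "ssim",
    "paired_ttest",
    "rescale_to_255",
    "metric_table",
    "TTestResult",
]

#: SSIM stabilizing constants on the 0-255 scale.
SSIM_C1 = (0.01 * 255.0) ** 2
SSIM_C2 = (0.03 * 255.0) ** 2


def nmae(pred, ref) -> float:
    """Normalized mean absolute error: sum |p - r| / sum r."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("shape mismatch")
    denom = ref.sum()
    if denom <= 0:
        raise ValueError("reference sums to zero; NMAE undefined")
    return float(np.abs(pred - ref).sum() / denom)


def rescale_to_255(x, value_max: float) -> np.ndarray:
    """Map a coefficient map in [0, value_max] to the 0-255 gray scale."""
    return np.asarray(x, dtype=float) * (255.0 / value_max)


def psnr(pred, ref) -> float:
    """Peak signal-to-noise ratio in dB on 0-255-scaled inputs.

    Identical images yield ``inf``.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((pred - ref) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(255.0**2 / mse))


def ssim(pred, ref, windowed: bool = False) -> float:
    """Structural similarity on 0-255-scaled inputs.

    The default uses global image statistics (one mean, variance and
    covariance per image); ``windowed=True`` switches to the 11x11
    Gaussian-windowed mean SSIM.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("shape mismatch")
    if windowed:
        from skimage.metrics import structural_similarity

        return float(
            structural_similarity(
                pred, ref, data_range=255.0, gaussian_weights=True,
                sigma=1.5, use_sample_covariance=False,
            )
        )
    mu_p, mu_r = pred.mean(), ref.mean()
    var_p, var_r = pred.var(), ref.var()
    cov = float(np.mean((pred - mu_p) * (ref - mu_r)))
    return float(
        (2 * mu_p * mu_r + SSIM_C1) * (2 * cov + SSIM_C2)
        / ((mu_p**2 + mu_r**2 + SSIM_C1) * (var_p + var_r + SSIM_C2))
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    n: int
    degenerate: bool

    @property
    def significance(self) -> str:
        """Band label at the conventional 0.05 / 0.01 / 0.001 levels."""
        if self.degenerate:
            return "degenerate"
        if self.p < 0.001:
            return "p<0.001"
        if self.p < 0.01:
            return "p<0.01"
        if self.p < 0.05:
            return "p<0.05"
        return "ns"


def paired_ttest(errors_a, errors_b) -> TTestResult:
    """Two-tailed paired Student's t-test on per-sample error vectors."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D paired vectors")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return TTestResult(t=0.0, p=1.0, n=a.size, degenerate=True)
        return TTestResult(
            t=float(np.sign(d[0]) * np.inf), p=0.0, n=a.size, degenerate=True
        )
    res = stats.ttest_rel(a, b, alternative="two-sided")
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), n=a.size,
                       degenerate=False)


def metric_table(records) -> pd.DataFrame:
    """Aggregate per-image metrics into a model x bruise-level x coefficient
    summary (mean +/- sd per metric).

    ``records`` is an iterable of dicts with keys ``model``, ``bruise_level``,
    ``coefficient``, ``nmae``, ``psnr``, ``ssim``.
    """
    df = pd.DataFrame(list(records))
    grouped = df.groupby(["model", "bruise_level", "coefficient"])
    out = grouped[["nmae", "psnr", "ssim"]].agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()


def evaluate_pair(pred_map, ref_map, norm_ranges=NORM_RANGES) -> dict:
    """Per-coefficient NMAE/PSNR/SSIM for one predicted/reference map pair."""
    out = {}
    for name, pred, ref, vmax in (
        ("mu_a", pred_map.mu_a, ref_map.mu_a, norm_ranges[0]),
        ("mu_s_prime", pred_map.mu_s_prime, ref_map.mu_s_prime, norm_ranges[1]),
    ):
        p255 = rescale_to_255(pred, vmax)
        r255 = rescale_to_255(ref, vmax)
        out[name] = {
            "nmae": nmae(pred, ref),
            "psnr": psnr(p255, r255),
            "ssim": ssim(p255, r255),
        }
    return out
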