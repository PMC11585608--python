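"""Image-quality metrics (PSNR, SSIM) and their paired comparison.

Metrics are computed on normalized [0, 1] intensities with
``data_range = 1`` — the model's training space — so the closed forms in
the tests are exact.  SSIM is computed in 2-D per axial slice with the
standard 11x11 Gaussian window (sigma 1.5, K1=0.01, K2=0.03) and averaged
over slices.  Cohorts of per-case scores are compared with the Wilcoxon
signed-rank test with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .stats import wilcoxon_signed_rank
from .volume_io import NormalizedVolume


def _values(v) -> np.ndarray:
    return v.values if isinstance(v, NormalizedVolume) else np.asarray(v)


def psnr_arrays(ref: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """PSNR in dB: ``10 log10(data_range^2 / MSE)``; +inf if identical."""
    ref, test = np.asarray(ref, dtype=np.float64), np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {test.shape}")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


def psnr(ref, test, data_range: float = 1.0) -> float:
    """PSNR between two volumes (NormalizedVolume or arrays)."""
    return psnr_arrays(_values(ref), _values(test), data_range)


def ssim(ref, test, data_range: float = 1.0) -> float:
    """Mean 2-D SSIM over axial slices (Gaussian window, sigma 1.5)."""
    a, b = _values(ref), _values(test)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if a.ndim != 3:
        raise ValueError("ssim expects rank-3 volumes")
    scores = [
        structural_similarity(
            a[z],
            b[z],
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
        for z in range(a.shape[0])
    ]
    return float(np.mean(scores))


def compare_paired_metrics(a, b, n_comparisons: int = 1) -> dict:
    """Two-sided Wilcoxon signed-rank on paired per-case scores with
    Bonferroni correction (p multiplied by ``n_comparisons``, capped at 1).

    Zero differences are dropped; ties get average ranks.  Returns a dict
    with ``p`` (corrected), ``p_raw`` and ``degenerate`` (True when every
    difference is zero, in which case p = 1).
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    res = wilcoxon_signed_rank(b - a, alternative="two-sided")
    if res["degenerate"]:
        return {"p": 1.0, "p_raw": 1.0, "degenerate": True}
    p_raw = res["p"]
    return {"p": min(1.0, p_raw * n_comparisons), "p_raw": p_raw, "degenerate": False}


@dataclass
class QualityReport:
    """Per-case PSNR/SSIM for two synthesis methods plus summary stats."""

    psnr_a: list[float]
    psnr_b: list[float]
    ssim_a: list[float]
    ssim_b: list[float]
    label_a: str = "BIS"
    label_b: str = "DLS"
    n_comparisons: int = 1

    def summary(self) -> dict:
        def med_iqr(x):
            x = np.asarray(x, dtype=float)
            return {
                "median": float(np.median(x)),
                "iqr": [float(np.percentile(x, 25)), float(np.percentile(x, 75))],
            }

        return {
            self.label_a: {"psnr": med_iqr(self.psnr_a), "ssim": med_iqr(self.ssim_a)},
            self.label_b: {"psnr": med_iqr(self.psnr_b), "ssim": med_iqr(self.ssim_b)},
            "p_psnr": compare_paired_metrics(
                self.psnr_a, self.psnr_b, self.n_comparisons
            )["p"],
            "p_ssim": compare_paired_metrics(
                self.ssim_a, self.ssim_b, self.n_comparisons
            )["p"],
        }
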