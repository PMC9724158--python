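"""Quality assessment: RMSE, MAE, PSNR, SSIM, dataset-level aggregation and
1-D profile extraction.

All metrics are computed on de-normalised 12-bit intensities ([0, 4095]),
never on network-range tensors; ``evaluate_dataset`` guards this with an
explicit scale check. PSNR uses the 12-bit peak, 20*log10(peak / RMSE).

The ``as_printed`` flags reproduce two formula variants that circulate in
the literature for exact-formula comparison — an MAE with a nested square
root and a PSNR dividing by MSE instead of RMSE; the standard textbook
forms are the defaults because published magnitudes (PSNR around 17-23 dB
for this task family) are only consistent with the standard definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantoms import INTENSITY_MAX, Image2D, SampleSet

PSNR_CAP_DB = 200.0  # sentinel for identical images


@dataclass
class SSIMParams:
    """Gaussian-windowed SSIM parameters (the cited reference's defaults)."""

    window: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    intensity_max: float = INTENSITY_MAX

    def __post_init__(self):
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("stabilisation constants must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.intensity_max) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.intensity_max) ** 2

    def gaussian_window(self) -> np.ndarray:
        half = self.window // 2
        ax = np.arange(-half, half + 1, dtype=np.float64)
        g = np.exp(-(ax ** 2) / (2 * self.sigma ** 2))
        w = np.outer(g, g)
        return w / w.sum()


def _pix(img) -> np.ndarray:
    arr = img.pixels if isinstance(img, Image2D) else np.asarray(img, dtype=np.float64)
    return np.asarray(arr, dtype=np.float64)


def _check_pair(g_e, g_r) -> tuple[np.ndarray, np.ndarray]:
    a, b = _pix(g_e), _pix(g_r)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return a, b


def rmse(g_e, g_r) -> float:
    """Root-mean-squared intensity error."""
    a, b = _check_pair(g_e, g_r)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def mae(g_e, g_r, as_printed: bool = False) -> float:
    """Mean absolute error (default) or the nested-radical variant."""
    a, b = _check_pair(g_e, g_r)
    if as_printed:
        return float(np.sqrt(np.sum(np.abs(a - b))) / a.size)
    return float(np.mean(np.abs(a - b)))


def psnr(g_e, g_r, peak: float = INTENSITY_MAX, as_printed: bool = False) -> float:
    """Peak signal-to-noise ratio in dB; identical inputs return the cap."""
    a, b = _check_pair(g_e, g_r)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    if as_printed:
        return float(20.0 * np.log10(peak / mse))
    return float(20.0 * np.log10(peak / np.sqrt(mse)))


def ssim(g_e, g_r, params: SSIMParams | None = None) -> float:
    """Mean structural similarity over valid Gaussian windows.

    Per window: (2 mu_e mu_r + c1)(2 cov + c2) /
    ((mu_e^2 + mu_r^2 + c1)(var_e + var_r + c2)), with Gaussian-weighted
    moments; windows are fully inside the image (valid mode).
    """
    a, b = _check_pair(g_e, g_r)
    p = params or SSIMParams()
    win = p.gaussian_window()
    k = p.window
    if a.shape[0] < k or a.shape[1] < k:
        raise ValueError(f"image smaller than the {k}x{k} SSIM window")
    wa = np.lib.stride_tricks.sliding_window_view(a, (k, k))
    wb = np.lib.stride_tricks.sliding_window_view(b, (k, k))
    mu_a = np.einsum("ijkl,kl->ij", wa, win)
    mu_b = np.einsum("ijkl,kl->ij", wb, win)
    m_aa = np.einsum("ijkl,kl->ij", wa * wa, win)
    m_bb = np.einsum("ijkl,kl->ij", wb * wb, win)
    m_ab = np.einsum("ijkl,kl->ij", wa * wb, win)
    var_a = m_aa - mu_a ** 2
    var_b = m_bb - mu_b ** 2
    cov = m_ab - mu_a * mu_b
    num = (2 * mu_a * mu_b + p.c1) * (2 * cov + p.c2)
    den = (mu_a ** 2 + mu_b ** 2 + p.c1) * (var_a + var_b + p.c2)
    return float(np.mean(num / den))


@dataclass
class MetricsReport:
    """Per-image metric rows plus mean/std aggregates."""

    per_image: pd.DataFrame
    aggregate: dict = field(default_factory=dict)

    COLUMNS = ("id", "e_rmse", "e_mae", "e_psnr", "e_ssim")

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "MetricsReport":
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        agg = {}
        for col in cls.COLUMNS[1:]:
            agg[f"{col}_mean"] = float(df[col].mean())
            agg[f"{col}_std"] = float(df[col].std(ddof=0))
        return cls(df, agg)

    def to_csv(self, path):
        self.per_image.to_csv(path, index=False)


def evaluate_dataset(model, samples: SampleSet,
                     ssim_params: SSIMParams | None = None) -> MetricsReport:
    """All four metrics per image, on the 12-bit scale, plus aggregates.

    ``model`` maps an Image2D to an Image2D (e.g. a generator wrapper or the
    lookup-table oracle). Requires paired samples; for an unpaired set,
    recover the hidden pairing first (``samples.true_pairs()`` exists for
    evaluation) and rebuild a paired SampleSet.
    """
    if not samples.paired:
        raise ValueError("evaluate_dataset needs paired samples (references)")
    rows = []
    for i, (src, ref) in enumerate(zip(samples.sources, samples.targets)):
        est = model(src)
        est_pix = _pix(est)
        ref_pix = _pix(ref)
        # guard: metrics must see de-normalised intensities, not [-1, 1]
        if ref.intensity_max > 255 and ref_pix.max() <= 2.0 and est_pix.max() <= 2.0:
            raise ValueError(
                "images look network-scaled (max <= 2); de-normalise before "
                "computing metrics"
            )
        rows.append({
            "id": i,
            "e_rmse": rmse(est_pix, ref_pix),
            "e_mae": mae(est_pix, ref_pix),
            "e_psnr": psnr(est_pix, ref_pix, peak=ref.intensity_max),
            "e_ssim": ssim(est_pix, ref_pix, ssim_params),
        })
    return MetricsReport.from_rows(rows)


def profile_1d(img, row: int) -> np.ndarray:
    """Intensity sequence along one row, for profile/difference comparisons."""
    arr = _pix(img)
    if not 0 <= row < arr.shape[0]:
        raise IndexError(f"row {row} outside [0, {arr.shape[0]})")
    return arr[row].copy()
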