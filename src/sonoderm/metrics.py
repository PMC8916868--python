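"""Image-quality metrics (MSE, PSNR, SSIM) and the noise-sweep harness.

Conventions: MSE uses the 1/(m*n) population normalization; SSIM is by
default computed from whole-image statistics with the population (1/N)
variance/covariance convention, matching the MSE normalization, with a
windowed mean-SSIM offered as an option. PSNR of identical images is
reported as the +infinity sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import Image2D
from .nlm import ADMMConfig, NLMConfig, denoise_nlm, denoise_nlm_improved, mu_for_sigma
from .phantom import NoiseSpec, add_noise

__all__ = ["SSIMConfig", "mse", "psnr", "ssim", "sweep_noise_levels"]


@dataclass(frozen=True)
class SSIMConfig:
    """SSIM stabilizing constants and mode.

    c1/c2 default to (0.01*L)^2 and (0.03*L)^2 for dynamic range L.
    ``global`` mode uses whole-image statistics; ``windowed`` averages
    local SSIM over square windows of radius ``window_radius``.
    """

    L: float = 255.0
    c1: float | None = None
    c2: float | None = None
    mode: str = "global"
    window_radius: int = 3

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"dynamic range L must be positive, got {self.L}")
        if self.mode not in ("global", "windowed"):
            raise ValueError(f"unknown SSIM mode {self.mode!r}")
        if self.window_radius < 1:
            raise ValueError(f"window_radius must be >= 1, got {self.window_radius}")
        for name in ("c1", "c2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def c1_value(self) -> float:
        return (0.01 * self.L) ** 2 if self.c1 is None else self.c1

    @property
    def c2_value(self) -> float:
        return (0.03 * self.L) ** 2 if self.c2 is None else self.c2


def _pair(i: Image2D, k: Image2D) -> tuple[np.ndarray, np.ndarray]:
    if i.shape != k.shape:
        raise ValueError(f"shape mismatch: {i.shape} vs {k.shape}")
    return i.pixels, k.pixels


def mse(i: Image2D, k: Image2D) -> float:
    """Mean squared error (1/(m*n)) * sum (I - K)^2."""
    a, b = _pair(i, k)
    d = a - b
    return float(np.mean(d * d))


def psnr(i: Image2D, k: Image2D, L: float = 255.0) -> float:
    """Peak signal-to-noise ratio 10*log10(L^2 / MSE), in dB; +inf if MSE = 0."""
    if L <= 0:
        raise ValueError(f"L must be positive, got {L}")
    e = mse(i, k)
    if e == 0.0:
        return float("inf")
    return float(10.0 * np.log10(L * L / e))


def _ssim_terms(a, b, c1, c2):
    # population statistics (1/N), matching the MSE normalization
    mi, mj = a.mean(), b.mean()
    vi = np.mean(a * a) - mi * mi
    vj = np.mean(b * b) - mj * mj
    cov = np.mean(a * b) - mi * mj
    return ((2 * mi * mj + c1) * (2 * cov + c2)) / (
        (mi * mi + mj * mj + c1) * (vi + vj + c2)
    )


def ssim(i: Image2D, k: Image2D, cfg: SSIMConfig | None = None) -> float:
    """Structural similarity index; 1 iff identical (for c1, c2 > 0)."""
    if cfg is None:
        cfg = SSIMConfig()
    a, b = _pair(i, k)
    c1, c2 = cfg.c1_value, cfg.c2_value
    if cfg.mode == "global":
        return float(_ssim_terms(a, b, c1, c2))
    size = 2 * cfg.window_radius + 1

    def box(x):
        return ndimage.uniform_filter(x, size=size, mode="reflect")

    mi, mj = box(a), box(b)
    vi = box(a * a) - mi * mi
    vj = box(b * b) - mj * mj
    cov = box(a * b) - mi * mj
    local = ((2 * mi * mj + c1) * (2 * cov + c2)) / (
        (mi * mi + mj * mj + c1) * (vi + vj + c2)
    )
    return float(local.mean())


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def sweep_noise_levels(
    clean: Image2D,
    sigmas,
    n_seeds: int = 10,
    seed: int = 0,
    nlm_cfg: NLMConfig | None = None,
    admm_cfg: ADMMConfig | None = None,
    ssim_cfg: SSIMConfig | None = None,
    mu_per_sigma: bool = True,
) -> pd.DataFrame:
    """Benchmark classic vs regularized NLM over additive-noise levels.

    For every sigma and each method in {noisy, nlm, nlm_improved} the
    metrics are averaged over ``n_seeds`` noise realizations. The classic
    method runs with gamma = 0 (plain NLM weights); the improved method
    uses the configured cosine exponent plus the ADMM regularization.
    With ``mu_per_sigma`` the filter parameter is matched to each noise
    level as mu_for_sigma(sigma). Deterministic given ``seed``.
    """
    sigmas = list(sigmas)
    if not sigmas:
        raise ValueError("sigmas must be non-empty")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    base = nlm_cfg if nlm_cfg is not None else NLMConfig()
    admm = admm_cfg if admm_cfg is not None else ADMMConfig()
    seeds = _child_seeds(seed, len(sigmas) * n_seeds)
    rows = []
    idx = 0
    for sigma in sigmas:
        cfg = replace(base, mu=mu_for_sigma(sigma)) if mu_per_sigma else base
        cfg_classic = replace(cfg, gamma=0.0)
        acc = {m: np.zeros(3) for m in ("noisy", "nlm", "nlm_improved")}
        for _ in range(n_seeds):
            noisy = add_noise(clean, NoiseSpec(sigma=float(sigma)), seeds[idx])
            idx += 1
            outputs = {
                "noisy": noisy,
                "nlm": denoise_nlm(noisy, cfg_classic),
                "nlm_improved": denoise_nlm_improved(noisy, cfg, admm),
            }
            for method, img in outputs.items():
                acc[method] += np.array(
                    [mse(img, clean), psnr(img, clean), ssim(img, clean, ssim_cfg)]
                )
        for method in ("noisy", "nlm", "nlm_improved"):
            e, p, s = acc[method] / n_seeds
            rows.append(
                {"sigma": float(sigma), "method": method, "mse": e, "psnr": p, "ssim": s}
            )
    return pd.DataFrame(rows, columns=["sigma", "method", "mse", "psnr", "ssim"])
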