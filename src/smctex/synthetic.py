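"""Synthetic multiband canopy imagery with depth-resolved soil moisture.

Emulates a jointing-stage wheat trial: ``n_plots`` plots, each observed as a
six-band reflectance grid, with volumetric soil moisture content (SMC)
sampled in three depth layers (0–20, 20–40, 40–60 cm).

The canopy is a Gaussian random field synthesised spectrally (FFT of white
noise shaped by a power-law spectrum k^(−β/2)).  Shallow-layer SMC modulates
the spectral slope β and the field amplitude: wetter plots carry denser,
smoother canopies, hence lower windowed texture contrast.  Red-edge and NIR
bands respond most strongly (``band_gains``).  Depth layers follow an AR(1)
structure with coefficient ρ, so deeper layers correlate with — but are not
identical to — the shallow layer; the imagery depends only on shallow SMC,
so the texture–moisture correlation decays with depth exactly as the
inter-layer SMC correlation does.

Vegetation gaps are Bernoulli soil patches dilated with a 3×3 element and
filled with a soil spectrum (low NDVI), so the downstream masking stage has
real work to do.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import ReflectancePlot

__all__ = [
    "DEPTH_LAYERS",
    "SyntheticConfig",
    "generate_smc",
    "generate_plot_image",
    "generate_dataset",
    "config_from_manifest",
]

DEPTH_LAYERS = ("0-20", "20-40", "40-60")

# mean reflectance of closed wheat canopy / bare soil per band
_VEG_BASE = np.array([0.04, 0.08, 0.05, 0.25, 0.32, 0.42])
_SOIL_BASE = np.array([0.10, 0.14, 0.18, 0.22, 0.24, 0.26])


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic trial.

    ``depth_coupling`` κ_d is the nominal texture–moisture coupling per
    layer; κ_shallow scales how strongly shallow SMC shapes the canopy
    field, and deeper layers couple indirectly through ``depth_autocorr`` ρ
    (effective coupling ≈ κ_shallow·ρ^(d−1)).  κ must not increase with
    depth.
    """

    n_plots: int = 96
    plot_px: int = 64
    n_bands: int = 6
    depth_layers: tuple[str, ...] = DEPTH_LAYERS
    smc_range: tuple[float, float] = (0.08, 0.30)  # volumetric fraction
    depth_coupling: tuple[float, float, float] = (0.9, 0.68, 0.51)
    depth_autocorr: float = 0.75
    noise_sd: float = 0.01
    seed: int = 0
    band_gains: tuple[float, ...] = (0.2, 0.3, 0.25, 0.7, 0.85, 1.0)
    soil_gap_prob: float = 0.015
    # GRF shaping: spectral slope beta_lo..beta_lo+beta_span*kappa1 and
    # amplitude decay over the SMC range
    beta_lo: float = 1.2
    beta_span: float = 2.6
    amp_base: float = 0.04
    amp_decay: float = 0.6

    def __post_init__(self) -> None:
        if self.n_plots < 10:
            raise ValueError("n_plots must be >= 10")
        if self.plot_px < 16:
            raise ValueError("plot_px must be >= 16 (windowed textures need interior)")
        if self.n_bands != 6:
            raise ValueError("n_bands is fixed at 6")
        if len(self.band_gains) != 6:
            raise ValueError("band_gains must have 6 entries")
        lo, hi = self.smc_range
        if not 0 < lo < hi:
            raise ValueError("smc_range must satisfy 0 < lo < hi")
        k = self.depth_coupling
        if len(k) != len(self.depth_layers):
            raise ValueError("depth_coupling must give one kappa per layer")
        if any(not 0 <= x <= 1 for x in k):
            raise ValueError("depth_coupling entries must lie in [0, 1]")
        if any(k[i] < k[i + 1] for i in range(len(k) - 1)):
            raise ValueError("depth_coupling must not increase with depth")
        if not 0 <= self.depth_autocorr < 1:
            raise ValueError("depth_autocorr must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _plot_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def generate_smc(config: SyntheticConfig) -> pd.DataFrame:
    """Per-plot, per-layer volumetric SMC with AR(1) depth structure.

    Layer 1 is standard normal in a latent scale; each deeper layer is
    ρ·previous + sqrt(1−ρ²)·innovation, then mapped linearly into
    ``smc_range`` (mid ± 3 latent sd spans the range) and clipped to the
    range bounds exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_plots
    rho = config.depth_autocorr
    nd = len(config.depth_layers)
    z = np.empty((n, nd))
    z[:, 0] = rng.standard_normal(n)
    for d in range(1, nd):
        z[:, d] = rho * z[:, d - 1] + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
    lo, hi = config.smc_range
    mid, half = (lo + hi) / 2, (hi - lo) / 2
    smc = np.clip(mid + z * (half / 3.0), lo, hi)
    ids = _plot_ids(n)
    rows = [
        {"plot_id": ids[i], "depth_layer": config.depth_layers[d],
         "smc": smc[i, d]}
        for i in range(n) for d in range(nd)
    ]
    return pd.DataFrame(rows)


def _gaussian_random_field(px: int, beta: float, white: np.ndarray) -> np.ndarray:
    """Shape pre-drawn white noise with a k^(−β/2) power-law spectrum."""
    kx = np.fft.fftfreq(px)
    k = np.sqrt(kx[:, None] ** 2 + kx[None, :] ** 2)
    amp = np.zeros_like(k)
    nz = k > 0
    amp[nz] = k[nz] ** (-beta / 2.0)
    F = np.fft.fft2(white) * amp
    f = np.real(np.fft.ifft2(F))
    sd = f.std()
    if sd > 0:
        f = (f - f.mean()) / sd
    return f


def generate_plot_image(smc_shallow: float, config: SyntheticConfig,
                        plot_seed) -> ReflectancePlot:
    """One plot's six-band reflectance grid driven by shallow-layer SMC.

    Deterministic given ``(smc_shallow, config, plot_seed)``.  Wetter plots
    get a steeper spectral slope (smoother field) and a smaller amplitude,
    hence lower local texture contrast in every band.
    """
    lo, hi = config.smc_range
    if not lo <= smc_shallow <= hi:
        raise ValueError(
            f"smc_shallow={smc_shallow} outside smc_range {config.smc_range}")
    rng = np.random.default_rng(plot_seed)
    px = config.plot_px
    white = rng.standard_normal((px, px))
    soil_u = rng.random((px, px))
    noise = rng.standard_normal((px, px, 6))

    kappa1 = config.depth_coupling[0]
    s = (smc_shallow - lo) / (hi - lo)
    beta = config.beta_lo + config.beta_span * kappa1 * s
    amp = config.amp_base * (1.0 - config.amp_decay * kappa1 * s)
    f = _gaussian_random_field(px, beta, white)

    gains = np.asarray(config.band_gains, dtype=float)
    pixels = (_VEG_BASE[None, None, :]
              + amp * gains[None, None, :] * f[:, :, None])

    soil = ndimage.binary_dilation(soil_u < config.soil_gap_prob,
                                   np.ones((3, 3), bool))
    pixels = np.where(soil[:, :, None], _SOIL_BASE[None, None, :], pixels)
    if config.noise_sd > 0:
        pixels = pixels + config.noise_sd * noise
    pixels = np.clip(pixels, 0.0, 1.0).astype(np.float32)
    return ReflectancePlot("plot", pixels, mask=~soil)


def generate_dataset(config: SyntheticConfig, out_dir=None):
    """The full synthetic trial: ``n_plots`` images plus the SMC table.

    Returns ``(plots, smc_table)``.  When ``out_dir`` is given, writes one
    multiband float32 TIFF per plot (band order blue/green/red/RE720/RE750/
    NIR, band-first), ``smc.csv`` and a YAML ``manifest.yaml`` echoing the
    configuration, so the dataset can be regenerated exactly.
    """
    smc = generate_smc(config)
    shallow = smc[smc.depth_layer == config.depth_layers[0]].set_index("plot_id")["smc"]
    ids = _plot_ids(config.n_plots)
    plots = []
    for i, pid in enumerate(ids):
        plot = generate_plot_image(float(shallow[pid]), config,
                                   plot_seed=(config.seed, i))
        plot.plot_id = pid
        plots.append(plot)

    if out_dir is not None:
        import tifffile
        import yaml

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            files = []
            for plot in plots:
                fn = out / f"{plot.plot_id}.tif"
                tifffile.imwrite(str(fn), np.moveaxis(plot.pixels, -1, 0))
                files.append(fn.name)
            smc.to_csv(out / "smc.csv", index=False)
            manifest = {"config": _config_dict(config), "files": files}
            (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
        except OSError as exc:
            raise OSError(f"failed writing dataset under {out}: {exc}") from exc
    return plots, smc


def _config_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    return d


def config_from_manifest(path) -> SyntheticConfig:
    """Rebuild the generating configuration from a dataset manifest."""
    import yaml

    manifest = yaml.safe_load(Path(path).read_text())
    cfg = manifest["config"]
    for key, val in cfg.items():
        if isinstance(val, list):
            cfg[key] = tuple(val)
    return SyntheticConfig(**cfg)
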