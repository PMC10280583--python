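"""Synthetic NIR-like spectra with known composition.

The generator follows the Beer-Lambert picture that underlies linear
calibration: a mixture's absorbance is the concentration-weighted sum of
pure-component absorbance curves, wrapped in the artifacts scatter
correction exists to remove:

    x_i(lam) = m_i * ( sum_k c_ik/100 * s_k(lam) + a_i + b_i * lam~ ) + eps_i

with ``m_i`` a multiplicative scatter factor (log-normal), ``a_i + b_i*lam~``
an additive linear baseline on the normalized wavelength axis, and
``eps_i`` i.i.d. Gaussian channel noise. Default artifact levels emulate a
well-controlled benchtop instrument measuring similar samples (sub-percent
replicate scatter); stronger scatter for preprocessing studies is a knob
(``scatter_sigma=0.05`` makes scatter the dominant nuisance). Scatter must
stay well below the starch signal-to-total-absorbance ratio (~0.013) for
the compositions to remain linearly identifiable, since the scatter
direction nearly coincides with the dominant starch contribution. Pure-component curves ``s_k`` are
sums of Gaussian bands (one broad background band plus several narrow
ones), so they are smooth, strictly positive, and mutually distinguishable.

Compositions ``c_ik`` (stored in the targets table, in percent) are drawn
per target from truncated normals whose means and standard deviations
default to the corn-benchmark summary statistics (moisture 10.23 +- 0.38,
oil 3.50 +- 0.18, protein 8.67 +- 0.50, starch 64.70 +- 0.82 percent).

An optional ``quadratic`` coefficient adds a mild Beer-Lambert deviation
(x + q * x^2 on the mixture term) to give nonlinear feature extractors
something linear models cannot capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SpectraSet

COMPONENTS = ("moisture", "oil", "protein", "starch")

#: composition mean/std defaults (percent), corn-benchmark totals
DEFAULT_COMPOSITION = {
    "moisture": (10.23, 0.38),
    "oil": (3.50, 0.18),
    "protein": (8.67, 0.50),
    "starch": (64.70, 0.82),
}

#: default composition correlations (COMPONENTS order). Constituent
#: percentages respect approximate mass closure (they sum toward a stable
#: dry-matter total), which forces the dominant constituent (starch) to
#: anticorrelate with the others; with the default marginals this brings
#: the std of the summed percentages down to ~0.37 from ~1.05 under
#: independence. Without closure, total absorbance is itself a starch
#: proxy, which misrepresents real constituent data and makes scatter
#: artifacts and scatter correction statistically indistinguishable in
#: their effect on calibration. Pass ``composition_corr=None`` (or an
#: identity matrix) for independent draws.
DEFAULT_COMPOSITION_CORR = (
    (1.00, 0.00, 0.00, -0.55),
    (0.00, 1.00, 0.00, -0.30),
    (0.00, 0.00, 1.00, -0.65),
    (-0.55, -0.30, -0.65, 1.00),
)


def default_wavelengths(n_channels: int = 700) -> np.ndarray:
    """The 1100-2498 nm grid (2 nm spacing at the default 700 channels)."""
    return np.linspace(1100.0, 2498.0, n_channels)


@dataclass
class ComponentLibrary:
    """Pure-component absorbance curves on a common wavelength grid."""

    wavelengths: np.ndarray
    curves: dict[str, np.ndarray]
    seed: int

    def matrix(self) -> np.ndarray:
        """(n_components, n_channels) array in COMPONENTS order."""
        return np.stack([self.curves[k] for k in COMPONENTS])


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_samples: int = 80
    n_channels: int = 700
    composition: dict = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION))
    scatter_sigma: float = 0.002      # sd of log multiplicative factor
    baseline_intercept_sigma: float = 0.002  # AU
    baseline_slope_sigma: float = 0.001      # AU over the full axis
    noise_std: float = 1e-4           # AU per channel
    quadratic: float = 0.0            # Beer-Lambert deviation coefficient
    composition_corr: tuple | None = DEFAULT_COMPOSITION_CORR
    seed: int = 0

    def validate(self) -> None:
        for name, sigma in (
            ("scatter_sigma", self.scatter_sigma),
            ("baseline_intercept_sigma", self.baseline_intercept_sigma),
            ("baseline_slope_sigma", self.baseline_slope_sigma),
            ("noise_std", self.noise_std),
        ):
            if sigma < 0:
                raise ValueError(f"{name} must be >= 0")
        for k, (mu, sd) in self.composition.items():
            if mu <= 0 or sd < 0:
                raise ValueError(f"composition for {k!r} must be positive")
        if self.composition_corr is not None:
            R = np.asarray(self.composition_corr, dtype=float)
            k = len(self.composition)
            if R.shape != (k, k):
                raise ValueError(
                    f"composition_corr must be {k}x{k}, got {R.shape}")
            if not np.allclose(R, R.T) or np.linalg.eigvalsh(R).min() <= 0:
                raise ValueError(
                    "composition_corr must be symmetric positive definite")


def make_library(seed: int, wavelengths: np.ndarray | None = None
                 ) -> ComponentLibrary:
    """Seeded pure-component curves: 3-6 Gaussian bands each.

    Each curve carries one broad band (width 600-1000 nm) setting the
    absorbance floor plus 2-5 narrow bands (width 30-120 nm) giving it a
    distinct fingerprint; all amplitudes are positive so curves are
    non-negative everywhere. Libraries whose curves correlate above 0.999
    are redrawn (components must stay distinguishable).
    """
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths)
    rng = np.random.default_rng(seed)
    lo, hi = wl[0], wl[-1]
    for _attempt in range(20):
        curves = {}
        for name in COMPONENTS:
            centers = [rng.uniform(lo + 0.3 * (hi - lo), hi - 0.3 * (hi - lo))]
            widths = [rng.uniform(600.0, 1000.0)]
            amps = [rng.uniform(0.5, 1.0)]
            for _ in range(int(rng.integers(2, 6))):
                centers.append(rng.uniform(lo + 50, hi - 50))
                widths.append(rng.uniform(30.0, 120.0))
                amps.append(rng.uniform(0.2, 1.0))
            curve = np.zeros_like(wl)
            for c, w, a in zip(centers, widths, amps):
                curve += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
            curves[name] = curve
        corr = np.corrcoef(np.stack(list(curves.values())))
        off = corr[~np.eye(len(COMPONENTS), dtype=bool)]
        if np.all(off < 0.999):
            return ComponentLibrary(wavelengths=wl, curves=curves, seed=seed)
    raise RuntimeError("could not draw a distinguishable component library")


def _truncated_normal(rng, mean, std, size, max_retries=1000):
    """Positive-truncated normal draws by rejection."""
    out = rng.normal(mean, std, size=size)
    for _ in range(max_retries):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, std, size=int(bad.sum()))
    raise RuntimeError(
        f"could not draw positive compositions (mean={mean}, std={std})"
    )


def _truncated_mvn(rng, means, stds, corr, n, max_retries=1000):
    """Correlated composition draws; rows with any non-positive entry are
    redrawn (rejection)."""
    L = np.linalg.cholesky(corr)
    draw = lambda size: means + (rng.standard_normal((size, means.size))
                                 @ L.T) * stds
    out = draw(n)
    for _ in range(max_retries):
        bad = (out <= 0).any(axis=1)
        if not bad.any():
            return out
        out[bad] = draw(int(bad.sum()))
    raise RuntimeError("could not draw positive correlated compositions")


def generate_dataset(library: ComponentLibrary,
                     config: SyntheticConfig) -> SpectraSet:
    """Draw a seeded synthetic SpectraSet with a targets table in percent."""
    config.validate()
    wl = library.wavelengths
    if wl.size != config.n_channels:
        raise ValueError(
            f"library grid has {wl.size} channels, config wants "
            f"{config.n_channels}"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    names = list(config.composition)
    mus = np.array([config.composition[k][0] for k in names])
    sds = np.array([config.composition[k][1] for k in names])
    if config.composition_corr is None:
        conc = np.column_stack([
            _truncated_normal(rng, mu, sd, n) for mu, sd in zip(mus, sds)
        ])
    else:
        conc = _truncated_mvn(
            rng, mus, sds, np.asarray(config.composition_corr, float), n)
    S = np.stack([library.curves[k] for k in names])  # (K, L)
    mix = (conc / 100.0) @ S
    if config.quadratic:
        mix = mix + config.quadratic * mix ** 2
    lam = (wl - wl[0]) / (wl[-1] - wl[0])
    a = rng.normal(0.0, config.baseline_intercept_sigma, size=n)
    b = rng.normal(0.0, config.baseline_slope_sigma, size=n)
    m = np.exp(rng.normal(0.0, config.scatter_sigma, size=n))
    noise = rng.normal(0.0, config.noise_std, size=(n, wl.size))
    absorbance = m[:, None] * (mix + a[:, None] + b[:, None] * lam) + noise
    ids = [f"S{i:03d}" for i in range(n)]
    targets = pd.DataFrame(conc, columns=names, index=ids)
    return SpectraSet(wavelengths=wl, absorbance=absorbance,
                      sample_ids=ids, targets=targets)


def default_dataset(seed: int = 0, **overrides) -> SpectraSet:
    """Library + dataset at the default study conditions in one call."""
    config = SyntheticConfig(seed=seed, **overrides)
    wl = default_wavelengths(config.n_channels)
    library = make_library(seed, wl)
    return generate_dataset(library, config)


def golden_fixture() -> SpectraSet:
    """Tiny checked-in 8-sample x 32-channel dataset for unit tests.

    Stored as bit-stable CSV text inside the package so preprocessing
    outputs can be verified against hand-computed values on every platform.
    """
    from importlib.resources import files

    from .dataset import read_spectra

    path = files("nircae").joinpath("data/golden.csv")
    with path.open("rb") as fh:
        return read_spectra(fh)
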