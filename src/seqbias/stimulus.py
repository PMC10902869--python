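"""Grating-in-noise stimulus rendering and orientation-energy decomposition.

The stimulus is a sinusoidal grating at +/-45 deg of vertical, 1 cycle/deg,
random phase, embedded in smoothed white noise inside a circular aperture of
~5 deg radius on a mean-gray background.  Orientation content of a rendered
image is quantified with a quadrature Gabor filter bank covering
orientations -89..90 deg in 1-deg steps and spatial frequencies 0.6-1.4
cycles/deg in 0.1 c/deg steps (the target frequency +/- 0.4 c/deg): the
energy in cell (theta, f) is the quadrature magnitude
``sqrt(c^2 + s^2)`` of the mean-subtracted image projected onto the even and
odd filters of that cell.

All filters share the stimulus aperture as their envelope, are zero-mean and
unit-norm, which makes energies comparable across cells.  Because every
filter is an aperture-windowed sinusoid, the two projections per cell equal
the real and imaginary parts of a single complex exponential inner product;
:meth:`FilterBank.energies` exploits this to evaluate the whole bank without
materialising 1620 filter pairs, and is verified against explicitly
constructed filters in the test suite.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

BACKGROUND: float = 0.5


@dataclasses.dataclass(frozen=True)
class StimulusParams:
    """Physical and raster parameters of the stimulus.

    ``noise_contrast`` is applied as the standard deviation of the smoothed
    noise luminance relative to the mean-gray background (luminance SD =
    ``0.5 * noise_contrast``), then the composite is clipped to [0, 1].
    """

    grating_sf: float = 1.0  # cycles/deg
    noise_contrast: float = 0.3
    noise_smooth_sd: float = 0.08  # deg
    aperture_radius: float = 5.0  # deg
    aperture_edge: float = 0.5  # deg, raised-cosine ramp width
    size_deg: float = 10.0
    pixels_per_degree: float = 24.0

    def __post_init__(self) -> None:
        if self.aperture_radius <= 0:
            raise ValueError("aperture_radius must be positive")
        if self.pixels_per_degree < 4 * self.grating_sf:
            raise ValueError(
                "pixels_per_degree below Nyquist margin (need >= 4 x grating_sf)"
            )

    @property
    def n_pixels(self) -> int:
        return int(round(self.size_deg * self.pixels_per_degree))


#: Desk-scale raster (64 x 64 over 10 deg) used for batch pipelines.
REDUCED_RASTER = StimulusParams(pixels_per_degree=6.4)


def _axes(params: StimulusParams) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates in degrees; x rightward, y upward.

    ``x`` indexes columns, ``y`` indexes rows (top row = largest y).
    """
    n = params.n_pixels
    half = (n - 1) / 2.0
    x = (np.arange(n) - half) / params.pixels_per_degree
    y = (half - np.arange(n)) / params.pixels_per_degree
    return x, y


def aperture(params: StimulusParams) -> np.ndarray:
    """Raised-cosine circular aperture envelope in [0, 1]."""
    x, y = _axes(params)
    r = np.hypot(x[None, :], y[:, None])
    inner = params.aperture_radius - params.aperture_edge
    env = 0.5 * (1 + np.cos(np.pi * (r - inner) / params.aperture_edge))
    env[r <= inner] = 1.0
    env[r >= params.aperture_radius] = 0.0
    return env


def _carrier_phase(angle_deg: float, sf: float, params: StimulusParams) -> np.ndarray:
    """Spatial phase (radians) of a sinusoid oriented ``angle_deg`` clockwise
    of vertical at spatial frequency ``sf`` (cycles/deg)."""
    x, y = _axes(params)
    th = np.deg2rad(angle_deg)
    fx = sf * np.cos(th)
    fy = -sf * np.sin(th)
    return 2 * np.pi * (fx * x[None, :] + fy * y[:, None])


def grating_raster(
    angle_deg: float,
    contrast: float,
    params: StimulusParams,
    phase: float = 0.0,
) -> np.ndarray:
    """Noiseless aperture grating; ``phase`` in cycles (0..1)."""
    carrier = np.cos(_carrier_phase(angle_deg, params.grating_sf, params) + 2 * np.pi * phase)
    return BACKGROUND + aperture(params) * (0.5 * contrast * carrier)


@dataclasses.dataclass
class StimulusImage:
    """A rendered luminance raster in [0, 1] plus its generating condition."""

    raster: np.ndarray
    orientation: int | None
    contrast: float
    params: StimulusParams


def render_stimulus(
    orientation: int | None,
    contrast: float,
    params: StimulusParams | None = None,
    seed: int = 0,
) -> StimulusImage:
    """Render one grating-in-noise stimulus.

    ``orientation`` is +1 (clockwise, +45 deg) or -1 (counterclockwise,
    -45 deg); it may be ``None`` only for 0%-contrast (noise-only) trials.
    The random phase and the noise field are drawn from ``seed``.
    """
    params = params or StimulusParams()
    if not 0.0 <= contrast <= 1.0:
        raise ValueError(f"contrast must lie in [0, 1], got {contrast}")
    if contrast > 0 and orientation not in (1, -1):
        raise ValueError("orientation must be +1 or -1 when contrast > 0")
    rng = np.random.default_rng(seed)
    phase = rng.random()
    noise = rng.standard_normal((params.n_pixels, params.n_pixels))
    noise = gaussian_filter(noise, sigma=params.noise_smooth_sd * params.pixels_per_degree)
    noise = (noise - noise.mean()) / noise.std()

    signal = np.zeros_like(noise)
    if contrast > 0:
        carrier = np.cos(
            _carrier_phase(45.0 * orientation, params.grating_sf, params)
            + 2 * np.pi * phase
        )
        signal = 0.5 * contrast * carrier
    raster = BACKGROUND + aperture(params) * (
        signal + 0.5 * params.noise_contrast * noise
    )
    np.clip(raster, 0.0, 1.0, out=raster)
    return StimulusImage(raster=raster, orientation=orientation, contrast=contrast, params=params)


# ---------------------------------------------------------------------------
# filter bank and energy profiles
# ---------------------------------------------------------------------------

DEFAULT_ORIENTATIONS_DEG = np.arange(-89, 91)  # 180 values, 1-deg steps
DEFAULT_SFS_CPD = np.linspace(0.6, 1.4, 9)  # target frequency 1 +/- 0.4 c/deg


class FilterBank:
    """Quadrature Gabor bank over an (orientation, spatial frequency) grid.

    Each cell holds an even (cosine-phase) and an odd (sine-phase) filter
    with the stimulus aperture as a shared envelope; filters are zero-mean
    and normalised to unit L2 norm.
    """

    def __init__(
        self,
        params: StimulusParams | None = None,
        orientations_deg: np.ndarray | None = None,
        sfs_cpd: np.ndarray | None = None,
    ) -> None:
        self.params = params or StimulusParams()
        self.orientations_deg = (
            DEFAULT_ORIENTATIONS_DEG.copy()
            if orientations_deg is None
            else np.asarray(orientations_deg)
        )
        self.sfs_cpd = (
            DEFAULT_SFS_CPD.copy() if sfs_cpd is None else np.asarray(sfs_cpd, float)
        )
        th = np.deg2rad(self.orientations_deg.astype(float))
        # cell order: orientation-major, i.e. cell c = oi * n_sf + fi
        fx = (np.cos(th)[:, None] * self.sfs_cpd[None, :]).ravel()
        fy = (-np.sin(th)[:, None] * self.sfs_cpd[None, :]).ravel()
        x, y = _axes(self.params)
        self._x, self._y = x, y
        self._fx, self._fy = fx, fy
        self._aperture = aperture(self.params)
        self._ex = np.exp(2j * np.pi * fx[:, None] * x[None, :])  # (C, N)
        self._ey = np.exp(2j * np.pi * fy[:, None] * y[None, :])  # (C, N)
        self._compute_filter_norms()

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.orientations_deg), len(self.sfs_cpd)

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]

    def _compute_filter_norms(self, chunk: int = 64) -> None:
        n = self.params.n_pixels
        a = self._aperture
        n_even = np.empty(self.n_cells)
        n_odd = np.empty(self.n_cells)
        for lo in range(0, self.n_cells, chunk):
            hi = min(lo + chunk, self.n_cells)
            phi = 2 * np.pi * (
                self._fx[lo:hi, None, None] * self._x[None, None, :]
                + self._fy[lo:hi, None, None] * self._y[None, :, None]
            )
            even = a[None] * np.cos(phi)
            odd = a[None] * np.sin(phi)
            for arr, out in ((even, n_even), (odd, n_odd)):
                s = arr.sum(axis=(1, 2))
                ss = (arr**2).sum(axis=(1, 2))
                out[lo:hi] = np.sqrt(np.maximum(ss - s**2 / (n * n), 1e-300))
        self._norm_even = n_even
        self._norm_odd = n_odd

    def filter_pair(self, oi: int, fi: int) -> tuple[np.ndarray, np.ndarray]:
        """Explicit zero-mean, unit-norm (even, odd) filters of one cell."""
        c = oi * len(self.sfs_cpd) + fi
        phi = 2 * np.pi * (
            self._fx[c] * self._x[None, :] + self._fy[c] * self._y[:, None]
        )
        out = []
        for f in (np.cos(phi), np.sin(phi)):
            g = self._aperture * f
            g = g - g.mean()
            out.append(g / np.linalg.norm(g))
        return out[0], out[1]

    def energies(
        self,
        rasters: np.ndarray,
        dtype: type = np.complex128,
        block_cells: int = 512,
    ) -> np.ndarray:
        """Energy profiles for a batch of rasters.

        Parameters
        ----------
        rasters : array, shape (N, N) or (B, N, N)
        dtype : complex dtype of the internal projection (complex64 halves
            the runtime at ~1e-6 relative accuracy).

        Returns
        -------
        array, shape (B, n_orientations, n_sfs) — nonnegative energies.
        """
        single = rasters.ndim == 2
        r = rasters[None] if single else rasters
        n = self.params.n_pixels
        if r.shape[-2:] != (n, n):
            raise ValueError(
                f"raster resolution {r.shape[-2:]} does not match filter bank ({n}, {n})"
            )
        w = (r - r.mean(axis=(1, 2), keepdims=True)) * self._aperture
        w = w.astype(np.float32 if dtype == np.complex64 else np.float64, copy=False)
        b = w.shape[0]
        z = np.empty((b, self.n_cells), dtype=complex)
        ex = self._ex.astype(dtype, copy=False)
        ey = self._ey.astype(dtype, copy=False)
        flat = w.reshape(b * n, n)
        for lo in range(0, self.n_cells, block_cells):
            hi = min(lo + block_cells, self.n_cells)
            t = (flat @ ex[lo:hi].T).reshape(b, n, hi - lo)
            z[:, lo:hi] = np.einsum("bnc,cn->bc", t, ey[lo:hi])
        energy = np.hypot(z.real / self._norm_even, z.imag / self._norm_odd)
        energy = energy.reshape(b, *self.shape)
        return energy[0] if single else energy

    def cw_mask(self) -> np.ndarray:
        """Orientations counted as clockwise evidence (1..89 deg)."""
        o = self.orientations_deg
        return (o >= 1) & (o <= 89)

    def ccw_mask(self) -> np.ndarray:
        """Orientations counted as counterclockwise evidence (-89..-1 deg)."""
        o = self.orientations_deg
        return (o <= -1) & (o >= -89)


@dataclasses.dataclass
class EnergyProfile:
    """Orientation x spatial-frequency energy of one stimulus image."""

    energy: np.ndarray  # (n_orientations, n_sfs), nonnegative
    orientations_deg: np.ndarray
    sfs_cpd: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    def argmax_cell(self) -> tuple[float, float]:
        oi, fi = np.unravel_index(np.argmax(self.energy), self.energy.shape)
        return float(self.orientations_deg[oi]), float(self.sfs_cpd[fi])

    def to_frame(self) -> pd.DataFrame:
        o, f = np.meshgrid(self.orientations_deg, self.sfs_cpd, indexing="ij")
        df = pd.DataFrame(
            {
                "orientation_deg": o.ravel(),
                "sf_cpd": np.round(f.ravel(), 6),
                "energy": self.energy.ravel(),
            }
        )
        for k, v in self.meta.items():
            df[k] = v
        return df


def compute_energy_profile(img: StimulusImage, bank: FilterBank) -> EnergyProfile:
    """Project one image onto the quadrature bank.

    Raises ``ValueError`` when the image raster and the bank were built at
    different resolutions.
    """
    energy = bank.energies(img.raster)
    return EnergyProfile(
        energy=energy,
        orientations_deg=bank.orientations_deg.copy(),
        sfs_cpd=bank.sfs_cpd.copy(),
        meta={"orientation": img.orientation, "contrast": img.contrast},
    )


def class_mean_energies(energy: np.ndarray, bank: FilterBank) -> tuple[float, float]:
    """Mean energy in the clockwise (1..89 deg) and counterclockwise
    (-89..-1 deg) orientation classes, pooled over all spatial frequencies.

    Accepts a single (O, S) profile or a batch (..., O, S); returns arrays of
    matching leading shape (scalars for a single profile).
    """
    cw = energy[..., bank.cw_mask(), :].mean(axis=(-2, -1))
    ccw = energy[..., bank.ccw_mask(), :].mean(axis=(-2, -1))
    return cw, ccw
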