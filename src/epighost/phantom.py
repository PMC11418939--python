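"""Synthetic 2-D head-like scenes: complex image, coil maps, B0, T2*.

The object is an ellipse composite with a few high-contrast internal edges so
that both low-spatial-frequency ghosts (fuzzy clouds) and high-frequency edge
ghosts are visible against it.  The head ellipse covers roughly 37 % of the
FOV, leaving a usable ghost region.  All randomness (ellipse jitter, phase and
field coefficients, coil geometry) flows from a single integer seed, so scenes
are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["PhantomScene", "make_phantom", "make_timeseries_b0"]

# (value, a, b, x0, y0, angle_deg) in unit coordinates (FOV spans [-1, 1])
_BASE_ELLIPSES = (
    (0.80, 0.62, 0.76, 0.00, 0.00, 0.0),
    (-0.25, 0.26, 0.36, -0.14, 0.06, 15.0),
    (-0.25, 0.22, 0.30, 0.16, 0.05, -15.0),
    (0.35, 0.10, 0.15, 0.00, -0.38, 0.0),
    (0.30, 0.09, 0.11, 0.24, 0.30, 0.0),
    (-0.20, 0.08, 0.12, -0.18, 0.34, 0.0),
    (0.40, 0.07, 0.07, 0.07, -0.10, 0.0),
)


@dataclass(frozen=True)
class PhantomScene:
    """Ground-truth scene on an N x N grid over a square FOV."""

    image: np.ndarray  # complex (N, N), indexed [y, x]
    coil_maps: np.ndarray  # complex (n_coils, N, N)
    b0_map_hz: np.ndarray  # (N, N)
    t2star_map_s: np.ndarray  # (N, N), > 0 (may be inf)
    pixel_size_m: float
    seed: int

    @property
    def matrix(self) -> int:
        return self.image.shape[0]

    @property
    def fov_m(self) -> float:
        return self.matrix * self.pixel_size_m

    def support_mask(self) -> np.ndarray:
        """Object support (boolean)."""
        return np.abs(self.image) > 0.01 * np.abs(self.image).max()

    def ideal_variant(self) -> "PhantomScene":
        """Same object and coils with zero off-resonance and no decay; the
        reference scene for artifact-free encoding."""
        return replace(
            self,
            b0_map_hz=np.zeros_like(self.b0_map_hz),
            t2star_map_s=np.full_like(self.t2star_map_s, np.inf),
        )


def _unit_grid(matrix: int) -> tuple[np.ndarray, np.ndarray]:
    c = (np.arange(matrix) - matrix // 2) * (2.0 / matrix)
    return np.meshgrid(c, c, indexing="xy")  # x varies along axis 1


def _render_ellipses(matrix: int, ellipses, rng: np.random.Generator) -> np.ndarray:
    x, y = _unit_grid(matrix)
    img = np.zeros((matrix, matrix))
    for i, (val, a, b, x0, y0, ang) in enumerate(ellipses):
        if i > 0:  # jitter internal structure only; the head outline is fixed
            x0 = x0 + rng.uniform(-0.02, 0.02)
            y0 = y0 + rng.uniform(-0.02, 0.02)
            val = val * (1 + rng.uniform(-0.05, 0.05))
        th = np.deg2rad(ang)
        xr = (x - x0) * np.cos(th) + (y - y0) * np.sin(th)
        yr = -(x - x0) * np.sin(th) + (y - y0) * np.cos(th)
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += val
    return np.clip(img, 0.0, None)


def _smooth_poly(x, y, rng, scale):
    c = rng.normal(0, 1, size=6)
    f = c[0] + c[1] * x + c[2] * y + c[3] * x * y + c[4] * x**2 + c[5] * y**2
    return scale * f / max(np.abs(f).max(), 1e-12)


def make_phantom(
    matrix: int,
    n_coils: int = 8,
    shim_quality: str = "good",
    seed: int = 0,
    fov_m: float = 0.1,
) -> PhantomScene:
    """Generate a deterministic head-like scene.

    ``shim_quality='good'`` gives a smooth low-order B0 field of a few Hz
    (a well-shimmed head at the simulated echo-train length); ``'poor'`` adds
    a strong off-resonance rim just inside the upper object boundary,
    emulating a deliberately degraded shim at an air-tissue interface.  The
    maximum poor-shim field exceeds the good-shim field at least five-fold.
    Coil maps
    are Gaussian lobes placed around the object with smooth, distinct complex
    phase; a single coil degenerates to a uniform map.
    """
    if matrix < 32:
        raise ValueError("matrix must be >= 32")
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if shim_quality not in ("good", "poor"):
        raise ValueError("shim_quality must be 'good' or 'poor'")
    rng = np.random.default_rng(seed)
    x, y = _unit_grid(matrix)

    mag = _render_ellipses(matrix, _BASE_ELLIPSES, rng)
    phase = _smooth_poly(x, y, rng, scale=0.8)
    image = mag * np.exp(1j * phase)

    if n_coils == 1:
        coil_maps = np.ones((1, matrix, matrix), dtype=complex)
    else:
        coil_maps = np.empty((n_coils, matrix, matrix), dtype=complex)
        angles = 2 * np.pi * np.arange(n_coils) / n_coils + rng.uniform(
            -0.1, 0.1, n_coils
        )
        for c in range(n_coils):
            cx, cy = 1.15 * np.cos(angles[c]), 1.15 * np.sin(angles[c])
            amp = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * 0.95**2))
            ph = (
                2 * np.pi * c / n_coils
                + 0.25 * rng.normal() * (x * np.cos(angles[c]) + y * np.sin(angles[c]))
                + 0.08 * rng.normal() * x * y
            )
            coil_maps[c] = amp * np.exp(1j * ph)

    b0 = _smooth_poly(x, y, rng, scale=5.0)
    if shim_quality == "poor":
        # rim of strong off-resonance just inside the upper object boundary
        # (air-tissue interface analogue); the field displaces the rim signal
        # into the object interior, so the ghost band outside the object
        # carries the resulting thin, high-spatial-frequency edge ghosts
        rho = np.sqrt((x / 0.62) ** 2 + (y / 0.76) ** 2)
        theta = np.arctan2(y, x)
        focus = (
            45.0
            * np.exp(-((rho - 0.90) ** 2) / (2 * 0.03**2))
            * np.exp(-((theta + np.pi / 2) ** 2) / (2 * 0.6**2))
        )
        b0 = b0 + focus

    support = mag > 0.01 * mag.max()
    t2s = np.full((matrix, matrix), 0.02)
    t2s[support] = 0.05
    # shorter T2* in the deep structures (second base ellipse region)
    deep = _render_ellipses(matrix, _BASE_ELLIPSES[1:2], np.random.default_rng(seed))
    t2s[(deep > 0) & support] = 0.03

    return PhantomScene(
        image=image,
        coil_maps=coil_maps,
        b0_map_hz=b0,
        t2star_map_s=t2s,
        pixel_size_m=fov_m / matrix,
        seed=seed,
    )


def make_timeseries_b0(
    scene: PhantomScene,
    n_frames: int,
    resp_amp_hz: float,
    resp_period_frames: float,
) -> np.ndarray:
    """Frame-wise B0 maps with a sinusoidal respiration-like fluctuation.

    Frame ``t`` carries ``b0 + resp_amp * sin(2 pi t / period) * mode`` where
    ``mode`` is a smooth seeded spatial mode with unit maximum, strongest near
    the inferior edge of the object (as chest motion modulates the field
    gradient across the head).  Returns an (n_frames, N, N) array.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(scene.seed + 7919)
    n = scene.matrix
    x, y = _unit_grid(n)
    cx, cy = rng.uniform(-0.2, 0.2), rng.uniform(-0.6, -0.2)
    mode = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * 0.5**2)) * (
        1 + 0.3 * (y - cy)
    )
    mode = mode / np.abs(mode).max()
    t = np.arange(n_frames)
    amp = resp_amp_hz * np.sin(2 * np.pi * t / resp_period_frames)
    return scene.b0_map_hz[None] + amp[:, None, None] * mode[None]
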