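"""Scanner-style EPI reconstruction.

Pipeline: per-line least-squares regridding onto the uniform read grid
(using *nominal* coordinates by design -- the mismatch with the actual
trajectory is the ghost source), line-class two-parameter Nyquist phase
correction from a three-line navigator, GRAPPA filling of skipped ky lines,
2-D inverse FFT, and coil combination with ground-truth sensitivity maps.

k-space convention: DC at index N//2 along both axes; the centered DFT is
``fftshift(fft(ifftshift(.)))`` and images are indexed ``[y, x]`` with pixel
centers on the integer grid.

:func:`reconstruct_with_actual_trajectory` runs the identical pipeline with
the regridding fed the actual coordinates; for noiseless unaccelerated data
it removes GIRF-induced ghosts almost entirely, which pins the artifact's
cause to the trajectory mismatch rather than off-resonance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np

from .forward import KSpaceData
from .phantom import PhantomScene
from .girf import GirfModel
from .waveforms import EpiProtocol

__all__ = [
    "ConditioningError",
    "PhaseCorrParams",
    "GrappaKernel",
    "ReconImage",
    "regrid_line",
    "estimate_phase_correction",
    "grappa_calibrate",
    "grappa_apply",
    "reconstruct",
    "reconstruct_with_actual_trajectory",
    "ideal_reference",
]


class ConditioningError(RuntimeError):
    """GRAPPA calibration is rank-deficient (e.g. too few distinct coils)."""


@dataclass(frozen=True)
class PhaseCorrParams:
    """Constant and linear odd/even phase offsets.

    ``phi1`` is the phase slope in rad per read-axis sample, applied
    antisymmetrically about the line center; negative-polarity lines are
    multiplied by ``exp(i (phi0 + phi1 (p - N//2)))`` in the hybrid
    (x, line) domain.
    """

    phi0: float
    phi1: float


@dataclass(frozen=True)
class GrappaKernel:
    """Calibrated GRAPPA weights mapping source neighborhoods to missing lines."""

    weights: dict  # target line offset d -> (n_features, n_coils) complex
    kernel_geometry: tuple[int, int]  # (source lines, read taps)
    regularization: float
    grappa_factor: int

    @property
    def is_identity(self) -> bool:
        return self.grappa_factor == 1


@dataclass
class ReconImage:
    """Reconstructed 2-D image plus the options that produced it."""

    image: np.ndarray  # (matrix_phase, matrix_read); complex unless SoS
    provenance: dict

    @property
    def is_magnitude_only(self) -> bool:
        return not np.iscomplexobj(self.image)


def _centered_ifft(s: np.ndarray, axes) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(s, axes=axes), axes=axes), axes=axes
    )


def _to_hybrid(s: np.ndarray) -> np.ndarray:
    """k -> x along the read (last) axis."""
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(s, axes=-1), axis=-1), axes=-1
    )


def _from_hybrid(p: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft(np.fft.ifftshift(p, axes=-1), axis=-1), axes=-1)


def _gridding_matrix(
    kx: np.ndarray, fov_m: float, n_grid: int, lam: float
) -> np.ndarray:
    """W such that ``uniform = W @ samples``.

    Solves the Tikhonov-stabilized least-squares mapping from nonuniform
    samples to the FOV-limited image profile and re-evaluates it on the
    uniform grid (sinc interpolation in k).  ``fov_m`` is the FOV spanned by
    the ``n_grid`` output grid (the oversampled read FOV when the readout is
    oversampled).
    """
    x = (np.arange(n_grid) - n_grid // 2) * (fov_m / n_grid)
    e = np.exp(-2j * np.pi * kx[:, None] * x[None, :])  # (M, N)
    k_u = (np.arange(n_grid) - n_grid // 2) / fov_m
    f = np.exp(-2j * np.pi * k_u[:, None] * x[None, :])  # (N, N)
    gram = e.conj().T @ e
    reg = lam * np.trace(gram).real / n_grid
    rho_op = np.linalg.solve(gram + reg * np.eye(n_grid), e.conj().T)
    return f @ rho_op


def regrid_line(
    samples: np.ndarray,
    nominal_kx: np.ndarray,
    fov_m: float,
    n_grid: int | None = None,
    lam: float = 1e-5,
) -> np.ndarray:
    """Regrid one readout line's samples onto the uniform k grid.

    ``samples`` may have leading batch axes (e.g. coils); the last axis must
    match ``nominal_kx``.  Coordinates must be strictly monotone (either
    direction).  Large ``lam`` shrinks the output toward zero.
    """
    kx = np.asarray(nominal_kx, dtype=float)
    d = np.diff(kx)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("nominal_kx must be strictly monotone along the line")
    n = n_grid if n_grid is not None else len(kx)
    w = _gridding_matrix(kx, fov_m, n, lam)
    return np.asarray(samples) @ w.T


def estimate_phase_correction(
    nav_samples: np.ndarray,
    nav_kx: np.ndarray,
    nav_polarity: Sequence[int],
    fov_m: float,
    lam: float = 1e-5,
) -> PhaseCorrParams:
    """Estimate (phi0, phi1) from a three-line ky=0 navigator.

    The navigator lines alternate polarity; each is regridded with its own
    nominal coordinates and projected to x.  The magnitude-weighted linear
    fit to the unwrapped phase of the cross-correlation between the mean
    positive-polarity and mean negative-polarity projections gives the
    constant and linear phase offsets.
    """
    nav_samples = np.asarray(nav_samples)
    if nav_samples.ndim == 2:
        nav_samples = nav_samples[None]
    pol = np.asarray(nav_polarity)
    n_lines = nav_samples.shape[1]
    if n_lines != len(pol) or n_lines < 2:
        raise ValueError("navigator needs >= 2 polarity-labelled lines")
    grid = np.stack(
        [
            regrid_line(nav_samples[:, l, :], nav_kx[l], fov_m, lam=lam)
            for l in range(n_lines)
        ],
        axis=1,
    )  # (coils, lines, N)
    proj = _to_hybrid(grid)
    p_plus = proj[:, pol > 0, :].mean(axis=1)
    p_minus = proj[:, pol < 0, :].mean(axis=1)
    q = np.sum(p_plus * np.conj(p_minus), axis=0)
    amax = np.abs(q).max()
    if amax == 0:
        raise ValueError("zero-signal navigator: cannot estimate phase correction")
    dphi = np.unwrap(np.angle(q))
    wgt = np.abs(q)
    mask = wgt > 0.05 * amax
    n = len(q)
    xi = np.arange(n) - n // 2
    coef = np.polynomial.polynomial.polyfit(
        xi[mask], dphi[mask], deg=1, w=np.sqrt(wgt[mask])
    )
    return PhaseCorrParams(phi0=float(coef[0]), phi1=float(coef[1]))


def apply_phase_correction(
    kgrid: np.ndarray, line_polarity: np.ndarray, params: PhaseCorrParams
) -> np.ndarray:
    """Apply the two-parameter correction to negative-polarity lines.

    ``kgrid`` is (..., n_lines, N) on the uniform read grid.
    """
    n = kgrid.shape[-1]
    xi = np.arange(n) - n // 2
    ramp = np.exp(1j * (params.phi0 + params.phi1 * xi))
    proj = _to_hybrid(kgrid)
    neg = np.asarray(line_polarity) < 0
    proj[..., neg, :] *= ramp
    return _from_hybrid(proj)


def grappa_calibrate(
    acs_grid: np.ndarray,
    grappa_factor: int,
    kernel_lines: int = 2,
    kernel_taps: int = 5,
    lam: float = 1e-4,
) -> GrappaKernel:
    """Calibrate GRAPPA weights from regridded ACS lines.

    ``acs_grid`` is (n_coils, n_acs, N).  Default geometry: 2 source lines
    (the acquired lines bracketing the gap) x 5 read taps, Tikhonov weight
    ``lam`` relative to the Gram trace.  R=1 returns an identity pass-through.
    """
    r = grappa_factor
    if r == 1:
        return GrappaKernel({}, (kernel_lines, kernel_taps), lam, 1)
    n_coils, n_acs, n_read = acs_grid.shape
    if n_coils < r:
        raise ConditioningError(
            f"GRAPPA R={r} with {n_coils} coil(s): aliasing is unresolvable"
        )
    if n_acs < r + 1:
        raise ValueError("too few ACS lines for the kernel geometry")
    half = kernel_taps // 2
    t_pos = np.arange(half, n_read - half)
    n_feat = n_coils * kernel_lines * kernel_taps

    def features(lines: np.ndarray, centers: np.ndarray) -> np.ndarray:
        # lines: (n_coils, kernel_lines, N); returns (len(centers), n_feat)
        cols = []
        for dl in range(kernel_lines):
            for dt in range(-half, half + 1):
                cols.append(lines[:, dl, centers + dt].T)  # (n_cent, n_coils)
        return np.concatenate(cols, axis=1)

    weights = {}
    for d in range(1, r):
        rows_a, rows_b = [], []
        for y in range(0, n_acs - r):
            src = acs_grid[:, [y, y + r], :]
            rows_a.append(features(src, t_pos))
            rows_b.append(acs_grid[:, y + d, t_pos].T)
        a = np.concatenate(rows_a, axis=0)
        b = np.concatenate(rows_b, axis=0)
        gram = a.conj().T @ a
        reg = lam * np.trace(gram).real / n_feat
        w = np.linalg.solve(gram + reg * np.eye(n_feat), a.conj().T @ b)
        # a geometry that cannot explain its own calibration data (duplicated
        # or uninformative coils) is unusable, regardless of conditioning
        resid = np.linalg.norm(a @ w - b) / max(np.linalg.norm(b), 1e-300)
        if resid > 0.5:
            raise ConditioningError(
                "rank-deficient GRAPPA calibration: coil geometry cannot "
                f"resolve the aliasing (training residual {resid:.2f})"
            )
        weights[d] = w
    return GrappaKernel(weights, (kernel_lines, kernel_taps), lam, r)


def grappa_apply(
    full_grid: np.ndarray, acquired_mask: np.ndarray, kernel: GrappaKernel
) -> np.ndarray:
    """Fill missing ky lines in place-copy using a calibrated kernel.

    ``full_grid`` is (n_coils, n_phase, N) with acquired rows populated.
    ky is treated as circular at the edges; read-tap overhang is zero-padded.
    """
    if kernel.is_identity:
        return full_grid
    r = kernel.grappa_factor
    n_coils, n_phase, n_read = full_grid.shape
    half = kernel.kernel_geometry[1] // 2
    out = full_grid.copy()
    padded = np.pad(full_grid, ((0, 0), (0, 0), (half, half)))
    centers = np.arange(n_read) + half
    for idx in np.where(~acquired_mask)[0]:
        y_lo = (idx // r) * r
        d = idx - y_lo
        y_hi = (y_lo + r) % n_phase
        if not (acquired_mask[y_lo] and acquired_mask[y_hi]):
            raise ValueError("sampling pattern inconsistent with GRAPPA factor")
        src = padded[:, [y_lo, y_hi], :]
        cols = []
        for dl in range(2):
            for dt in range(-half, half + 1):
                cols.append(src[:, dl, centers + dt].T)
        feats = np.concatenate(cols, axis=1)  # (n_read, n_feat)
        out[:, idx, :] = (feats @ kernel.weights[d]).T
    return out


def _combine(
    coil_imgs: np.ndarray, coil_maps: np.ndarray, mode: str
) -> np.ndarray:
    ssq = np.sum(np.abs(coil_maps) ** 2, axis=0)
    floor = 1e-12 * max(ssq.max(), 1e-300)
    denom = np.where(ssq > floor, ssq, np.inf)
    if mode == "phase_preserving":
        return np.sum(np.conj(coil_maps) * coil_imgs, axis=0) / denom
    if mode == "sos":
        # root-sum-of-squares normalized by the map magnitude; discards phase
        return np.sqrt(np.sum(np.abs(coil_imgs) ** 2, axis=0) / denom)
    raise ValueError("coil_combine must be 'sos' or 'phase_preserving'")


def _regrid_frame(
    samples: np.ndarray,
    kx_lines: np.ndarray,
    fov_m: float,
    n_grid: int,
    lam: float,
    cache: dict,
) -> np.ndarray:
    out = np.empty(samples.shape[:-1] + (n_grid,), dtype=complex)
    for l in range(kx_lines.shape[0]):
        key = kx_lines[l].tobytes()
        w = cache.get(key)
        if w is None:
            d = np.diff(kx_lines[l])
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("non-monotone read trajectory in line %d" % l)
            w = _gridding_matrix(kx_lines[l], fov_m, n_grid, lam)
            cache[key] = w
        out[..., l, :] = samples[..., l, :] @ w.T
    return out


def reconstruct(
    data: KSpaceData,
    scene: PhantomScene,
    *,
    frame: int | None = None,
    phase_correction: bool = True,
    grappa: bool | None = None,
    coil_combine: str = "phase_preserving",
    use_actual_trajectory: bool = False,
    lam_grid: float = 1e-5,
    grappa_lam: float = 1e-4,
    phase_corr_params: PhaseCorrParams | None = None,
    grappa_kernel: GrappaKernel | None = None,
) -> "ReconImage | list[ReconImage]":
    """Reconstruct one frame (or all frames) of an acquisition.

    ``grappa=None`` enables GRAPPA automatically when the protocol is
    accelerated.  ``phase_corr_params`` / ``grappa_kernel`` may be supplied to
    freeze the (data-dependent) calibration steps, which makes the remaining
    pipeline exactly linear in the k-space samples.
    """
    if frame is None and data.n_frames > 1:
        return [
            reconstruct(
                data,
                scene,
                frame=f,
                phase_correction=phase_correction,
                grappa=grappa,
                coil_combine=coil_combine,
                use_actual_trajectory=use_actual_trajectory,
                lam_grid=lam_grid,
                grappa_lam=grappa_lam,
                phase_corr_params=phase_corr_params,
                grappa_kernel=grappa_kernel,
            )
            for f in range(data.n_frames)
        ]
    f = frame if frame is not None else 0
    protocol = data.protocol
    r = protocol.grappa_factor
    do_grappa = (r > 1) if grappa is None else grappa
    if do_grappa and r > 1 and data.acs is None and grappa_kernel is None:
        raise ValueError("GRAPPA requested but no ACS data present")

    pol = int(data.frame_polarity[f])
    traj = data.trajectories[pol]
    kx = traj.actual_kx if use_actual_trajectory else traj.nominal_kx
    os_f = protocol.readout_oversampling
    n_grid = os_f * protocol.matrix_read
    fov = os_f * scene.fov_m  # oversampled read FOV; margin cropped after FFT
    cache: dict = {}
    grid = _regrid_frame(data.samples[f], kx, fov, n_grid, lam_grid, cache)
    line_pol = data.line_polarity * pol

    params = phase_corr_params
    if phase_correction:
        if params is None:
            nav_pol = pol * np.array(_NAV_PATTERN_ARR)
            params = estimate_phase_correction(
                data.navigator[f], kx[:3], nav_pol, fov, lam=lam_grid
            )
        grid = apply_phase_correction(grid, line_pol, params)

    n_phase = protocol.matrix_phase
    full = np.zeros((data.n_coils, n_phase, n_grid), dtype=complex)
    full[:, data.line_indices, :] = grid

    if do_grappa and r > 1:
        kernel = grappa_kernel
        if kernel is None:
            acs = data.acs
            acs_pol = int(acs.frame_polarity[0])
            acs_traj = acs.trajectories[acs_pol]
            acs_kx = (
                acs_traj.actual_kx if use_actual_trajectory else acs_traj.nominal_kx
            )
            acs_grid = _regrid_frame(
                acs.samples[0], acs_kx, fov, n_grid, lam_grid, cache
            )
            if phase_correction and params is not None:
                acs_grid = apply_phase_correction(
                    acs_grid, acs.line_polarity * acs_pol, params
                )
            kernel = grappa_calibrate(acs_grid, r, lam=grappa_lam)
        full = grappa_apply(full, data.acquired_line_mask, kernel)

    coil_imgs = _centered_ifft(full, axes=(-2, -1))
    if os_f > 1:  # crop the oversampled read margin
        n = protocol.matrix_read
        lo = n_grid // 2 - n // 2
        coil_imgs = coil_imgs[..., lo : lo + n]
    img = _combine(coil_imgs, scene.coil_maps, coil_combine)
    return ReconImage(
        image=img,
        provenance={
            "frame": f,
            "frame_polarity": pol,
            "phase_correction": phase_correction,
            "grappa": bool(do_grappa and r > 1),
            "grappa_factor": r,
            "coil_combine": coil_combine,
            "use_actual_trajectory": use_actual_trajectory,
            "girf": data.girf,
            "protocol": protocol,
        },
    )


_NAV_PATTERN_ARR = (1, -1, 1)


def reconstruct_with_actual_trajectory(
    data: KSpaceData, scene: PhantomScene, **options
) -> "ReconImage | list[ReconImage]":
    """The identical pipeline with regridding fed the actual trajectory.

    The simulator always knows the true coordinates, so this serves as the
    in-repo oracle: if ghosts vanish here, their cause was the trajectory
    mismatch, not off-resonance.
    """
    options.pop("use_actual_trajectory", None)
    return reconstruct(data, scene, use_actual_trajectory=True, **options)


def ideal_reference(
    scene: PhantomScene,
    protocol: EpiProtocol,
    *,
    phase_correction: bool = True,
    coil_combine: str = "phase_preserving",
    keep_b0: bool = False,
) -> ReconImage:
    """Pipeline-matched artifact-free reference reconstruction.

    Identity GIRF and no noise; by default the off-resonance map is zeroed as
    well, so both trajectory- and off-resonance-induced deviations of a test
    reconstruction count as artifact.  With ``keep_b0=True`` the scene's own
    field map is retained -- the reference then represents the scene as seen
    by ideal gradient hardware, and only hardware-corruption effects count.
    """
    from .forward import acquire

    scene0 = (
        scene
        if keep_b0
        else dc_replace(scene, b0_map_hz=np.zeros_like(scene.b0_map_hz))
    )
    data = acquire(scene0, protocol, GirfModel(), 0.0, seed=0)
    out = reconstruct(
        data,
        scene0,
        phase_correction=phase_correction,
        coil_combine=coil_combine,
    )
    return out if isinstance(out, ReconImage) else out[0]
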