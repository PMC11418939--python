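"""Forward EPI acquisition: brute-force DFT encoding along actual trajectories.

Each k-space sample is the direct sum over scene pixels

    s(c, line, i) = sum_r C_c(r) m(r) exp(-t_i/T2*(r)) exp(-2 pi i dB0(r) t_i)
                    * exp(-2 pi i (kx_i x + ky y))  + noise

evaluated at the *actual* (GIRF-perturbed) read coordinates and true ADC
sample times, with t = 0 at excitation and the k-space-center line crossing at
TE.  The model is deliberately a slow, exact DFT so it remains an oracle
independent of the reconstruction's gridding approximations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .girf import GirfModel, KTrajectory, integrate_trajectory, reverse_waveform
from .phantom import PhantomScene
from .waveforms import EpiProtocol, design_epi_readout

__all__ = ["KSpaceData", "acquire", "acquire_dual_polarity"]

_NAV_PATTERN = (1, -1, 1)  # navigator line polarities for a forward frame


@dataclass
class KSpaceData:
    """Acquired multi-frame, multi-coil EPI k-space with trajectory metadata.

    ``samples`` is (n_frames, n_coils, n_lines, n_read).  ``trajectories``
    maps frame polarity (+1/-1) to the :class:`~epighost.girf.KTrajectory`
    used for frames of that polarity; ``line_polarity`` refers to a +1 frame
    and is negated for reversed frames.  ``navigator`` holds three ky=0 lines
    per frame with line polarities ``frame_polarity * (1, -1, 1)``.
    """

    samples: np.ndarray
    trajectories: dict[int, KTrajectory]
    ky_per_line: np.ndarray
    line_indices: np.ndarray
    acquired_line_mask: np.ndarray
    line_polarity: np.ndarray
    frame_polarity: np.ndarray
    echo_spacing_s: float
    te_s: float
    protocol: EpiProtocol
    girf: GirfModel
    navigator: np.ndarray
    acs: "KSpaceData | None" = None
    noise_sd: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def n_coils(self) -> int:
        return self.samples.shape[1]

    @property
    def nominal_kx(self) -> np.ndarray:
        return self.trajectories[1].nominal_kx

    @property
    def actual_kx(self) -> np.ndarray:
        return self.trajectories[1].actual_kx

    def frame(self, f: int) -> "KSpaceData":
        """A view-like single-frame copy (shares trajectory metadata)."""
        return KSpaceData(
            samples=self.samples[f : f + 1],
            trajectories=self.trajectories,
            ky_per_line=self.ky_per_line,
            line_indices=self.line_indices,
            acquired_line_mask=self.acquired_line_mask,
            line_polarity=self.line_polarity,
            frame_polarity=self.frame_polarity[f : f + 1],
            echo_spacing_s=self.echo_spacing_s,
            te_s=self.te_s,
            protocol=self.protocol,
            girf=self.girf,
            navigator=self.navigator[f : f + 1],
            acs=self.acs,
            noise_sd=self.noise_sd,
        )


def _encode_lines(
    scene: PhantomScene,
    kx_lines: np.ndarray,
    ky_vals: np.ndarray,
    times: np.ndarray,
    b0_map: np.ndarray,
) -> np.ndarray:
    """Direct DFT of the scene at given per-line coordinates and times.

    Returns (n_coils, n_lines, n_read).
    """
    n = scene.matrix
    coords = (np.arange(n) - n // 2) * scene.pixel_size_m
    xg, yg = np.meshgrid(coords, coords, indexing="xy")
    xf, yf = xg.ravel(), yg.ravel()
    with np.errstate(divide="ignore"):
        rate = np.where(
            np.isfinite(scene.t2star_map_s), 1.0 / scene.t2star_map_s, 0.0
        )
    rf = (rate + 2j * np.pi * b0_map).ravel()
    m = (scene.coil_maps * scene.image[None]).reshape(scene.coil_maps.shape[0], -1)

    n_lines, n_read = kx_lines.shape
    out = np.empty((m.shape[0], n_lines, n_read), dtype=complex)
    for l in range(n_lines):
        ex = np.exp(
            -2j * np.pi * (kx_lines[l][:, None] * xf[None, :] + ky_vals[l] * yf[None, :])
            - times[l][:, None] * rf[None, :]
        )
        out[:, l, :] = (ex @ m.T).T
    return out


def _effective_te(protocol: EpiProtocol, waveform, center_line: int) -> float:
    a, b = waveform.adc_time_windows[center_line]
    t_center = (a + b) / 2.0 - waveform.t_excitation_s
    te = protocol.te_s if protocol.te_s is not None else 0.0
    return max(te, t_center)


def acquire(
    scene: PhantomScene,
    protocol: EpiProtocol,
    girf: GirfModel | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    polarity: int = 1,
    acs_ideal: bool = True,
    b0_map: np.ndarray | None = None,
    _with_acs: bool = True,
) -> KSpaceData:
    """Simulate one EPI frame (plus navigator, plus ACS when accelerated).

    GRAPPA sampling acquires every ``grappa_factor``-th ky line with the lobe
    train running at the protocol echo spacing; the ACS block is a separate,
    noiseless pass over the central ``acs_lines`` lines with a nominal
    trajectory by default, emulating the clean segmented/FLASH reference
    scans vendors use (``acs_ideal=False`` instead gives the ACS the same
    trajectory corruption as the imaging train).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if polarity not in (1, -1):
        raise ValueError("polarity must be +1 or -1")
    girf = girf if girf is not None else GirfModel()
    b0 = b0_map if b0_map is not None else scene.b0_map_hz
    if protocol.matrix_read != scene.matrix or protocol.matrix_phase != scene.matrix:
        raise ValueError("protocol matrix must match the scene matrix")

    n_phase = protocol.matrix_phase
    r = protocol.grappa_factor
    line_idx = np.arange(0, n_phase, r)
    n_lines = len(line_idx)
    wf, _ = design_epi_readout(protocol, n_lines)
    traj_p = integrate_trajectory(wf, protocol, girf)
    traj_m = integrate_trajectory(reverse_waveform(wf), protocol, girf)
    traj = traj_p if polarity == 1 else traj_m

    ky = (line_idx - n_phase // 2) / scene.fov_m
    j_center = int(np.argmin(np.abs(line_idx - n_phase // 2)))
    te_eff = _effective_te(protocol, wf, j_center)
    a, bb = wf.adc_time_windows[j_center]
    t_offset = te_eff - ((a + bb) / 2.0 - wf.t_excitation_s)
    times = traj.sample_times_s + t_offset

    samples = _encode_lines(scene, traj.actual_kx, ky, times, b0)[None]

    # navigator: first three lobes of the same train, ky = 0
    nav = _encode_lines(
        scene, traj.actual_kx[:3], np.zeros(3), times[:3], b0
    )[None]

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if noise_sd > 0:
        samples = samples + noise_sd * (
            rng.standard_normal(samples.shape) + 1j * rng.standard_normal(samples.shape)
        )
        nav = nav + noise_sd * (
            rng.standard_normal(nav.shape) + 1j * rng.standard_normal(nav.shape)
        )

    mask = np.zeros(n_phase, dtype=bool)
    mask[line_idx] = True

    acs_data = None
    if r > 1 and _with_acs:
        acs_idx = np.arange(
            n_phase // 2 - protocol.acs_lines // 2,
            n_phase // 2 - protocol.acs_lines // 2 + protocol.acs_lines,
        )
        wf_acs, _ = design_epi_readout(protocol, len(acs_idx))
        g_acs = None if acs_ideal else girf
        traj_acs_p = integrate_trajectory(wf_acs, protocol, g_acs)
        traj_acs = traj_acs_p if polarity == 1 else integrate_trajectory(
            reverse_waveform(wf_acs), protocol, g_acs
        )
        ky_acs = (acs_idx - n_phase // 2) / scene.fov_m
        jc = int(np.argmin(np.abs(acs_idx - n_phase // 2)))
        te_acs = _effective_te(protocol, wf_acs, jc)
        aa, ab = wf_acs.adc_time_windows[jc]
        t_acs = traj_acs.sample_times_s + (
            te_acs - ((aa + ab) / 2.0 - wf_acs.t_excitation_s)
        )
        acs_samples = _encode_lines(scene, traj_acs.actual_kx, ky_acs, t_acs, b0)[None]
        acs_mask = np.zeros(n_phase, dtype=bool)
        acs_mask[acs_idx] = True
        acs_data = KSpaceData(
            samples=acs_samples,
            trajectories={
                1: traj_acs_p,
                -1: integrate_trajectory(reverse_waveform(wf_acs), protocol, g_acs),
            },
            ky_per_line=ky_acs,
            line_indices=acs_idx,
            acquired_line_mask=acs_mask,
            line_polarity=traj_acs_p.line_polarity,
            frame_polarity=np.array([polarity]),
            echo_spacing_s=float(protocol.echo_spacing_s or 0.0),
            te_s=te_acs,
            protocol=protocol,
            girf=girf,
            navigator=np.zeros((1, samples.shape[1], 0, 0), dtype=complex),
        )

    return KSpaceData(
        samples=samples,
        trajectories={1: traj_p, -1: traj_m},
        ky_per_line=ky,
        line_indices=line_idx,
        acquired_line_mask=mask,
        line_polarity=traj_p.line_polarity,
        frame_polarity=np.array([polarity]),
        echo_spacing_s=float(protocol.echo_spacing_s or 0.0),
        te_s=te_eff,
        protocol=protocol,
        girf=girf,
        navigator=nav,
        acs=acs_data,
        noise_sd=noise_sd,
    )


def acquire_dual_polarity(
    scene: PhantomScene,
    protocol: EpiProtocol,
    girf: GirfModel | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_frames: int = 2,
    b0_series: np.ndarray | None = None,
    acs_ideal: bool = True,
) -> KSpaceData:
    """Simulate an alternating-polarity frame series.

    Odd-numbered frames (0-based even index) use the forward readout train,
    the others the negated train, both through the same GIRF.  Per-frame B0
    maps may be supplied (e.g. from
    :func:`~epighost.phantom.make_timeseries_b0`); per-frame noise streams are
    spawned deterministically from ``seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if b0_series is not None and len(b0_series) != n_frames:
        raise ValueError("b0_series must have one map per frame")
    frame_seeds = np.random.SeedSequence(seed).generate_state(n_frames) % (2**31)
    frames = []
    for f in range(n_frames):
        pol = 1 if f % 2 == 0 else -1
        b0 = b0_series[f] if b0_series is not None else None
        frames.append(
            acquire(
                scene,
                protocol,
                girf,
                noise_sd,
                seed=int(frame_seeds[f]),
                polarity=pol,
                acs_ideal=acs_ideal,
                b0_map=b0,
                _with_acs=(f == 0),
            )
        )
    first = frames[0]
    return KSpaceData(
        samples=np.concatenate([fr.samples for fr in frames], axis=0),
        trajectories=first.trajectories,
        ky_per_line=first.ky_per_line,
        line_indices=first.line_indices,
        acquired_line_mask=first.acquired_line_mask,
        line_polarity=first.line_polarity,
        frame_polarity=np.array([1 if f % 2 == 0 else -1 for f in range(n_frames)]),
        echo_spacing_s=first.echo_spacing_s,
        te_s=first.te_s,
        protocol=protocol,
        girf=first.girf,
        navigator=np.concatenate([fr.navigator for fr in frames], axis=0),
        acs=first.acs,
        noise_sd=noise_sd,
    )
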