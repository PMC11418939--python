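"""Parametric gradient impulse response and k-space trajectory integration.

The hardware response to a commanded gradient is modeled in the time domain as

    h(t) = delta(t - delay)
           - sum_i a_i * (1/tau_i) * exp(-t/tau_i) * u(t)
           - sum_j A_j * w_j * exp(-zeta_j w_j t) * sin(w_j sqrt(1-zeta_j^2) t) * u(t)

i.e. a pure delay, multi-exponential eddy-current decay, and damped sinusoid
resonance terms, with every decaying term paired with a compensating delta
so the discrete DC gain is exactly one (hardware reproduces steady
gradients; only switching transients are corrupted).  The resonance terms emulate the inductive coupling between
the gradient coil and a high-order shim circuit, which amplifies trajectory
errors whenever the readout train has spectral energy near the resonance
frequency; setting ``third_order_shim_connected=False`` removes them, the
simulator analogue of physically unplugging the shim.

Everything here is linear in the commanded waveform, which is the property
dual-polarity averaging relies on: negating the readout train exactly negates
the k-space deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .waveforms import GAMMA_CYC, EpiProtocol, GradientWaveform, _cumint, _eval_cumint

__all__ = [
    "GirfModel",
    "KTrajectory",
    "apply_girf",
    "integrate_trajectory",
    "reverse_waveform",
    "girf_preset",
    "GIRF_PRESETS",
]


@dataclass(frozen=True)
class GirfModel:
    """Delay + eddy decays + resonances; the identity model has no terms."""

    delay_s: float = 0.0
    eddy_terms: tuple[tuple[float, float], ...] = ()  # (amplitude, tau_s)
    resonance_terms: tuple[tuple[float, float, float], ...] = ()  # (amp, freq_hz, zeta)
    third_order_shim_connected: bool = True

    def __post_init__(self) -> None:
        for a, tau in self.eddy_terms:
            if tau <= 0:
                raise ValueError("eddy time constants must be positive")
            if abs(a) >= 1:
                raise ValueError("eddy amplitudes must satisfy |a| < 1")
        for a, f, zeta in self.resonance_terms:
            if f <= 0:
                raise ValueError("resonance frequencies must be positive")
            if not (0 < zeta <= 1):
                raise ValueError("resonance damping must lie in (0, 1]")
            if abs(a) >= 1:
                raise ValueError("resonance amplitudes must satisfy |a| < 1")

    @property
    def active_resonance_terms(self) -> tuple[tuple[float, float, float], ...]:
        return self.resonance_terms if self.third_order_shim_connected else ()

    @property
    def is_identity(self) -> bool:
        return (
            self.delay_s == 0
            and not self.eddy_terms
            and not self.active_resonance_terms
        )

    def scaled(self, factor: float) -> "GirfModel":
        """Scale every imperfection amplitude (delay, eddy, resonance) by
        ``factor``; used for perturbation-order experiments."""
        return replace(
            self,
            delay_s=self.delay_s * factor,
            eddy_terms=tuple((a * factor, tau) for a, tau in self.eddy_terms),
            resonance_terms=tuple(
                (a * factor, f, z) for a, f, z in self.resonance_terms
            ),
        )


# Presets are simulator parameter sets, not measurements: 'shim_coupled' adds
# one resonance near the 1100 Hz mechanical/coupling band on top of a small
# delay and eddy decay; 'shim_disconnected' is the same model with the
# resonance circuit open.
GIRF_PRESETS: dict[str, GirfModel] = {
    "identity": GirfModel(),
    "delay_only": GirfModel(delay_s=2e-6),
    "shim_coupled": GirfModel(
        delay_s=2e-6,
        eddy_terms=((0.02, 250e-6),),
        resonance_terms=((0.008, 1100.0, 0.05),),
        third_order_shim_connected=True,
    ),
    "shim_disconnected": GirfModel(
        delay_s=2e-6,
        eddy_terms=((0.02, 250e-6),),
        resonance_terms=((0.008, 1100.0, 0.05),),
        third_order_shim_connected=False,
    ),
}


def girf_preset(name: str) -> GirfModel:
    try:
        return GIRF_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown GIRF preset {name!r}; available: {sorted(GIRF_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class KTrajectory:
    """Per-line nominal and actual read-direction k-space coordinates.

    Arrays are (n_lines, n_samples).  Coordinates are re-zeroed per line so
    the nominal trajectory spans ``[-N/(2 fov), +N/(2 fov))``; the actual
    trajectory keeps the same per-line reference so that constant per-line
    offsets (e.g. from a pure delay) survive as deviations.
    ``sample_times_s`` are measured from the start of the readout train.
    """

    nominal_kx: np.ndarray
    actual_kx: np.ndarray
    line_polarity: np.ndarray
    sample_times_s: np.ndarray

    @property
    def n_lines(self) -> int:
        return self.nominal_kx.shape[0]

    @property
    def delta_kx(self) -> np.ndarray:
        return self.actual_kx - self.nominal_kx


def _girf_kernel(girf: GirfModel, raster: float, n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Discretized kernel: (delay taps, continuous-part taps).

    The delta is realised as a two-tap linear-interpolation shift (exact for
    delays that are whole raster steps); the continuous part is sampled on the
    raster and integrated by the trapezoid rule (half weight at t=0).
    """
    delay = girf.delay_s
    n_shift = int(np.floor(delay / raster))
    frac = delay / raster - n_shift
    delta_taps = np.zeros(n_shift + 2)
    delta_taps[n_shift] = 1.0 - frac
    delta_taps[n_shift + 1] = frac

    taus = [tau for _, tau in girf.eddy_terms]
    zw = [z * 2 * np.pi * f for _, f, z in girf.active_resonance_terms]
    if not taus and not zw:
        return delta_taps, np.zeros(0)
    t_decay = max([8 * tau for tau in taus] + [10.0 / v for v in zw if v > 0])
    n_ker = min(n_max, max(2, int(np.ceil(t_decay / raster)) + 1))
    t = np.arange(n_ker) * raster
    c = np.zeros(n_ker)
    for a, tau in girf.eddy_terms:
        c -= a / tau * np.exp(-t / tau)
    for a, f, zeta in girf.active_resonance_terms:
        w = 2 * np.pi * f
        wd = w * np.sqrt(1 - zeta**2)
        c -= a * w * np.exp(-zeta * w * t) * np.sin(wd * t)
    taps = c * raster
    taps[0] *= 0.5  # trapezoid rule at the kernel origin
    # pair every decaying term with a compensating delta so the discrete DC
    # gain is exactly one: steady gradients are reproduced exactly (hardware
    # calibrates the static response) and the residual error is the switching
    # transient localized at the trapezoid corners
    delta_taps[0] -= taps.sum()
    return delta_taps, taps


def apply_girf(waveform: GradientWaveform, girf: GirfModel) -> GradientWaveform:
    """Convolve a waveform with the impulse response; identity model is exact
    pass-through.  Zero-padded (causal) edge handling."""
    if girf.is_identity:
        return waveform
    g = waveform.samples_mTm
    n = len(g)
    delta_taps, cont_taps = _girf_kernel(girf, waveform.raster_s, n)
    out = np.convolve(g, delta_taps)[:n]
    if len(cont_taps):
        out = out + np.convolve(g, cont_taps)[:n]
    return replace(waveform, samples_mTm=out)


def reverse_waveform(waveform: GradientWaveform) -> GradientWaveform:
    """The reversed-polarity readout train (every lobe sign negated)."""
    return waveform.negated()


def integrate_trajectory(
    waveform: GradientWaveform,
    protocol: EpiProtocol,
    girf: GirfModel | None = None,
) -> KTrajectory:
    """Integrate nominal and GIRF-perturbed waveforms to per-line k_x.

    k_x(t) = gamma * integral of G from the train start, evaluated exactly for
    the piecewise-linear raster waveform at the (off-raster) ADC sample times,
    then referenced per line to the nominal window-center value so each
    nominal line spans [-N/(2 fov), +N/(2 fov)).
    """
    raster = waveform.raster_s
    g_nom = waveform.samples_mTm
    actual_wf = apply_girf(waveform, girf) if girf is not None else waveform
    g_act = actual_wf.samples_mTm

    cum_nom = _cumint(g_nom, raster)
    cum_act = _cumint(g_act, raster)

    # k accrues only after excitation: deviation accumulated during the
    # lead-in lobes does not phase the magnetization, so both integrals are
    # referenced to the excitation instant
    t_exc = np.array([waveform.t_excitation_s])
    k_nom_exc = _eval_cumint(cum_nom, g_nom, raster, t_exc)[0]
    k_act_exc = _eval_cumint(cum_act, g_act, raster, t_exc)[0]

    n_lines = waveform.n_lines
    n_s = waveform.n_samples_per_line
    nominal = np.empty((n_lines, n_s))
    actual = np.empty((n_lines, n_s))
    times = np.empty((n_lines, n_s))
    for l in range(n_lines):
        t = waveform.adc_sample_times(l)
        a, b = waveform.adc_time_windows[l]
        t_center = np.array([(a + b) / 2.0])
        ref = _eval_cumint(cum_nom, g_nom, raster, t_center)[0] - k_nom_exc
        k_n = _eval_cumint(cum_nom, g_nom, raster, t) - k_nom_exc
        k_a = _eval_cumint(cum_act, g_act, raster, t) - k_act_exc
        nominal[l] = (k_n - ref) * GAMMA_CYC
        actual[l] = (k_a - ref) * GAMMA_CYC
        times[l] = t - waveform.t_excitation_s
    return KTrajectory(
        nominal_kx=nominal,
        actual_kx=actual,
        line_polarity=waveform.line_polarity.copy(),
        sample_times_s=times,
    )
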