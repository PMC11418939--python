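"""Trapezoidal EPI readout gradient trains and their spectral content.

The readout train is a sequence of alternating-sign trapezoidal lobes, one per
echo spacing.  Each lobe carries one ADC window whose gradient first moment
encodes exactly ``matrix_read / fov_m`` cycles/m.  With ramp sampling enabled
the ADC window may extend onto the trapezoid slopes (excluding a small
low-velocity margin near the corners); otherwise it is confined to the flat
top.  All corner times are multiples of the gradient raster, so the raster
samples describe the continuous piecewise-linear waveform exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: gyromagnetic ratio of 1H in Hz/T
GAMMA_HZ_PER_T = 42.576e6
#: cycles/m accrued per (mT/m x second) of gradient area
GAMMA_CYC = GAMMA_HZ_PER_T * 1e-3

#: fraction of the flat-top amplitude below which ADC samples are not placed
#: (avoids near-zero k-space velocity at the trapezoid corners)
ADC_AMPLITUDE_MARGIN = 0.1


class InfeasibleTimingError(ValueError):
    """Requested echo spacing / resolution cannot be met within gmax and slew."""


@dataclass(frozen=True)
class EpiProtocol:
    """Acquisition prescription for a 2-D single-shot EPI readout.

    Exactly one of ``echo_spacing_s`` and ``bandwidth_per_pixel_hz`` must be
    given; the other is derived by :func:`design_epi_readout` (bandwidth per
    pixel is the reciprocal of the ADC window duration).
    """

    fov_m: float = 0.1
    matrix_read: int = 96
    matrix_phase: int = 96
    echo_spacing_s: float | None = 1.0e-3
    bandwidth_per_pixel_hz: float | None = None
    gmax_mTm: float = 80.0
    slew_Tms: float = 200.0
    raster_s: float = 10e-6
    ramp_sampling: bool = True
    grappa_factor: int = 1
    acs_lines: int = 24
    polarity_scheme: str = "single"
    te_s: float | None = None
    readout_oversampling: int = 2
    leadin_lobes: int = 16

    def __post_init__(self) -> None:
        if self.readout_oversampling < 1:
            raise ValueError("readout_oversampling must be >= 1")
        if self.leadin_lobes < 0 or self.leadin_lobes % 2:
            raise ValueError("leadin_lobes must be a non-negative even count")
        if self.fov_m <= 0:
            raise ValueError("fov_m must be positive")
        if self.matrix_read < 8:
            raise ValueError("matrix_read must be at least 8")
        if self.grappa_factor < 1:
            raise ValueError("grappa_factor must be >= 1")
        if (self.echo_spacing_s is None) == (self.bandwidth_per_pixel_hz is None):
            raise ValueError(
                "exactly one of echo_spacing_s and bandwidth_per_pixel_hz "
                "must be specified"
            )
        if self.echo_spacing_s is not None and self.echo_spacing_s <= 0:
            raise ValueError("echo_spacing_s must be positive")
        if self.bandwidth_per_pixel_hz is not None and self.bandwidth_per_pixel_hz <= 0:
            raise ValueError("bandwidth_per_pixel_hz must be positive")
        if self.gmax_mTm <= 0 or self.slew_Tms <= 0:
            raise ValueError("gmax and slew must be positive")
        if self.grappa_factor > 1 and self.acs_lines < 2 * self.grappa_factor:
            raise ValueError("acs_lines must be >= 2*grappa_factor when accelerated")
        if self.polarity_scheme not in ("single", "alternating_tr"):
            raise ValueError("polarity_scheme must be 'single' or 'alternating_tr'")

    @property
    def k_extent_cyc_per_m(self) -> float:
        """Full read-direction k-space extent, ``matrix_read / fov_m``."""
        return self.matrix_read / self.fov_m

    @property
    def n_acquired_lines(self) -> int:
        return -(-self.matrix_phase // self.grappa_factor)

    def with_echo_spacing(self, echo_spacing_s: float) -> "EpiProtocol":
        return replace(
            self, echo_spacing_s=echo_spacing_s, bandwidth_per_pixel_hz=None
        )


@dataclass(frozen=True)
class RampReport:
    """Ramp-sampling summary of a designed readout train."""

    ramp_fraction: float
    dwell_s: float
    flat_top_s: float
    ramp_s: float
    amplitude_mTm: float
    adc_duration_s: float

    @property
    def bandwidth_per_pixel_hz(self) -> float:
        return 1.0 / self.adc_duration_s


@dataclass(frozen=True)
class GradientWaveform:
    """A raster-sampled readout gradient train with ADC windows.

    ``samples_mTm`` are the values of the continuous piecewise-linear waveform
    at raster points; all trapezoid corners coincide with raster points, so
    linear interpolation of the samples reproduces the waveform exactly.
    ``adc_time_windows`` hold the exact (continuous-time) ADC window per line;
    ``adc_windows`` are the covering raster index ranges required by the HDF5
    container.
    """

    samples_mTm: np.ndarray
    raster_s: float
    line_boundaries: tuple[tuple[int, int], ...]
    adc_windows: tuple[tuple[int, int], ...]
    flat_top_ranges: tuple[tuple[int, int], ...]
    adc_time_windows: tuple[tuple[float, float], ...]
    dwell_s: float
    n_samples_per_line: int
    line_polarity: np.ndarray = field(repr=False)
    #: time of excitation within the waveform; the gradient train runs
    #: steady-state lead-in lobes (no ADC) before this point so that the
    #: hardware response has settled when the first line is acquired
    t_excitation_s: float = 0.0

    @property
    def n_lines(self) -> int:
        return len(self.line_boundaries)

    @property
    def duration_s(self) -> float:
        return (len(self.samples_mTm) - 1) * self.raster_s

    def adc_sample_times(self, line: int) -> np.ndarray:
        """ADC sample times (s, from waveform start) for one readout line."""
        t0, _ = self.adc_time_windows[line]
        return t0 + self.dwell_s * np.arange(self.n_samples_per_line)

    def negated(self) -> "GradientWaveform":
        return replace(
            self,
            samples_mTm=-self.samples_mTm,
            line_polarity=-self.line_polarity,
        )


def _round_raster(t: float, raster: float) -> int:
    return int(round(t / raster))


def design_epi_readout(
    protocol: EpiProtocol, n_lines: int | None = None
) -> tuple[GradientWaveform, RampReport]:
    """Design a trapezoidal EPI readout train for a protocol.

    The lobe duration equals the echo spacing.  The ramp time is the smallest
    raster multiple for which the ADC area requirement can be met within the
    slew and amplitude limits; the flat top fills the remainder of the lobe
    and the amplitude is then solved exactly so that the gradient first moment
    over the (symmetric, centered) ADC window equals ``matrix_read / fov_m``
    cycles/m.  Minimising the amplitude maximises the ADC duration, i.e. the
    design acquires at the lowest bandwidth the timing permits -- the reason
    ramp sampling is used on real systems.

    Returns the waveform and a :class:`RampReport`.  Raises
    :class:`InfeasibleTimingError` naming the limiting constraint when the
    echo spacing is too short for the required k-space area.
    """
    raster = protocol.raster_s
    area_req = protocol.k_extent_cyc_per_m / GAMMA_CYC  # (mT/m) * s

    if protocol.echo_spacing_s is not None:
        esp = protocol.echo_spacing_s
    else:
        # bandwidth fixes the ADC duration; the shortest feasible lobe wraps
        # minimal ramps around it
        t_adc = 1.0 / protocol.bandwidth_per_pixel_hz
        esp = _shortest_lobe_for_adc(protocol, t_adc, area_req)

    n_lobe = _round_raster(esp, raster)
    if n_lobe < 4:
        raise InfeasibleTimingError("echo spacing shorter than four raster steps")
    esp_q = n_lobe * raster
    if abs(esp_q - esp) > raster:
        raise InfeasibleTimingError("echo spacing not representable on the raster")

    slew_mTm_per_s = protocol.slew_Tms * 1e3  # mT/m per s
    margin = ADC_AMPLITUDE_MARGIN
    # usable ramp fraction of a full ramp's area when ADC avoids |G| < margin*G
    ramp_usable = (1.0 - margin**2) if protocol.ramp_sampling else 0.0

    best = None
    gmax_ok = False
    for n_ramp in range(1, n_lobe // 2 + 1):
        t_r = n_ramp * raster
        t_f = esp_q - 2 * t_r
        denom = t_f + ramp_usable * t_r
        if denom <= 0:
            continue
        g = area_req / denom
        if g > protocol.gmax_mTm:
            continue
        gmax_ok = True
        if g > slew_mTm_per_s * t_r * (1 + 1e-12):
            continue
        best = (t_r, t_f, g)
        break
    if best is None:
        if gmax_ok:
            raise InfeasibleTimingError(
                "slew rate limit: ramps cannot reach the required amplitude "
                "within the echo spacing"
            )
        raise InfeasibleTimingError(
            "gmax limit: echo spacing too short for the required k-space "
            "area at the maximum gradient amplitude"
        )
    t_r, t_f, g = best

    # exact symmetric ADC window [t_c - w, t_c + w] with area area_req
    flat_area = g * t_f
    if area_req <= flat_area * (1 + 1e-12):
        w = area_req / (2.0 * g)
        w = min(w, t_f / 2.0)
        delta = 0.0
    else:
        slope = g / t_r
        b = (area_req - flat_area) / 2.0  # area needed on each ramp
        disc = g * g - 2.0 * slope * b
        if disc < 0:
            raise InfeasibleTimingError("ADC window exceeds the lobe area")
        delta = (g - np.sqrt(disc)) / slope
        max_delta = (1.0 - margin) * t_r
        if delta > max_delta * (1 + 1e-9):
            raise InfeasibleTimingError(
                "ADC window would extend into the low-amplitude corner margin"
            )
        delta = min(delta, max_delta)
        w = t_f / 2.0 + delta
    t_adc = 2.0 * w

    n_train = n_lines if n_lines is not None else protocol.n_acquired_lines
    if n_train < 1:
        raise ValueError("n_lines must be >= 1")
    n_lead = protocol.leadin_lobes

    # assemble the raster train: lobe l spans [l*esp, (l+1)*esp], sign (-1)^l;
    # the first n_lead lobes are steady-state lead-in without ADC and the
    # excitation sits at their end
    n_total = n_lobe * (n_lead + n_train) + 1
    samples = np.zeros(n_total)
    tt = np.arange(n_lobe + 1) * raster
    lobe = np.where(
        tt < t_r,
        tt / t_r * g,
        np.where(tt <= t_r + t_f, g, np.clip((esp_q - tt) / t_r, 0.0, 1.0) * g),
    )
    for l in range(n_lead + n_train):
        i0 = l * n_lobe
        sign = 1.0 if l % 2 == 0 else -1.0
        samples[i0 : i0 + n_lobe + 1] = sign * lobe
    line_boundaries = []
    adc_windows = []
    flat_ranges = []
    adc_time_windows = []
    for l in range(n_lead, n_lead + n_train):
        i0 = l * n_lobe
        line_boundaries.append((i0, i0 + n_lobe))
        flat_ranges.append((i0 + _round_raster(t_r, raster), i0 + _round_raster(t_r + t_f, raster)))
        t_c = l * esp_q + esp_q / 2.0
        a, b_t = t_c - w, t_c + w
        adc_time_windows.append((a, b_t))
        adc_windows.append((int(np.floor(a / raster)), int(np.ceil(b_t / raster))))

    n_read_samples = protocol.readout_oversampling * protocol.matrix_read
    dwell = t_adc / n_read_samples
    wf = GradientWaveform(
        samples_mTm=samples,
        raster_s=raster,
        line_boundaries=tuple(line_boundaries),
        adc_windows=tuple(adc_windows),
        flat_top_ranges=tuple(flat_ranges),
        adc_time_windows=tuple(adc_time_windows),
        dwell_s=dwell,
        n_samples_per_line=n_read_samples,
        line_polarity=np.array(
            [1 if (n_lead + l) % 2 == 0 else -1 for l in range(n_train)]
        ),
        t_excitation_s=n_lead * esp_q,
    )
    ramp_time_in_adc = 2.0 * delta
    report = RampReport(
        ramp_fraction=ramp_time_in_adc / t_adc,
        dwell_s=dwell,
        flat_top_s=t_f,
        ramp_s=t_r,
        amplitude_mTm=g,
        adc_duration_s=t_adc,
    )
    return wf, report


def _shortest_lobe_for_adc(
    protocol: EpiProtocol, t_adc: float, area_req: float
) -> float:
    """Shortest echo spacing accommodating an ADC window of given duration."""
    raster = protocol.raster_s
    slew = protocol.slew_Tms * 1e3
    margin = ADC_AMPLITUDE_MARGIN
    ramp_usable = (1.0 - margin**2) if protocol.ramp_sampling else 0.0
    # search increasing lobe lengths until a feasible design exists whose ADC
    # duration is at least t_adc (the final design then trims w to area_req)
    n_adc = max(4, _round_raster(t_adc, raster))
    for n_lobe in range(n_adc, 100 * n_adc):
        esp = n_lobe * raster
        for n_ramp in range(1, n_lobe // 2 + 1):
            t_r = n_ramp * raster
            t_f = esp - 2 * t_r
            denom = t_f + ramp_usable * t_r
            if denom <= 0:
                continue
            g = area_req / denom
            if g > protocol.gmax_mTm or g > slew * t_r:
                continue
            # achieved ADC duration for this geometry
            if area_req <= g * t_f:
                dur = area_req / g
            else:
                slope = g / t_r
                b = (area_req - g * t_f) / 2.0
                disc = g * g - 2.0 * slope * b
                if disc < 0:
                    continue
                delta = (g - np.sqrt(disc)) / slope
                if delta > (1.0 - margin) * t_r * (1 + 1e-9):
                    continue
                dur = t_f + 2.0 * delta
            if dur >= t_adc * (1 - 1e-9):
                return esp
            break  # larger ramps only shorten the ADC window
    raise InfeasibleTimingError("no lobe length accommodates the requested bandwidth")


def lobe_shape(report: RampReport, echo_spacing_s: float, t: np.ndarray) -> np.ndarray:
    """Evaluate one (positive) trapezoid lobe at times ``t`` in [0, esp]."""
    g, t_r, t_f = report.amplitude_mTm, report.ramp_s, report.flat_top_s
    return np.where(
        t < t_r,
        t / t_r * g,
        np.where(t <= t_r + t_f, g, np.clip((echo_spacing_s - t) / t_r, 0, 1) * g),
    )


def adc_window_area(waveform: GradientWaveform, line: int) -> float:
    """Gradient first moment (cycles/m) over one line's ADC window.

    Exact integral of the piecewise-linear raster waveform between the
    continuous-time ADC window edges.
    """
    a, b = waveform.adc_time_windows[line]
    k = _cumint(waveform.samples_mTm, waveform.raster_s)
    va = _eval_cumint(k, waveform.samples_mTm, waveform.raster_s, np.array([a]))[0]
    vb = _eval_cumint(k, waveform.samples_mTm, waveform.raster_s, np.array([b]))[0]
    return float(abs(vb - va) * GAMMA_CYC)


def _cumint(samples: np.ndarray, raster: float) -> np.ndarray:
    """Cumulative trapezoid integral of the raster samples (exact for the
    piecewise-linear waveform)."""
    out = np.empty(len(samples))
    out[0] = 0.0
    np.cumsum((samples[1:] + samples[:-1]) * (raster / 2.0), out=out[1:])
    return out


def _eval_cumint(
    cum: np.ndarray, samples: np.ndarray, raster: float, t: np.ndarray
) -> np.ndarray:
    """Evaluate the running integral at arbitrary times (piecewise quadratic)."""
    idx = np.clip((t / raster).astype(int), 0, len(samples) - 2)
    frac = t - idx * raster
    g0 = samples[idx]
    slope = (samples[idx + 1] - samples[idx]) / raster
    return cum[idx] + g0 * frac + 0.5 * slope * frac * frac


def epi_waveform_harmonics(echo_spacing_s: float, n_max: int = 5) -> np.ndarray:
    """Harmonic frequencies (Hz) of the periodic EPI readout train.

    One full waveform period is a positive plus a negative lobe, i.e.
    ``2 * echo_spacing``, so harmonic ``n`` sits at ``n / (2 * esp)``.  Note
    that a symmetric alternating train is half-wave antisymmetric and carries
    energy only at the odd harmonics.
    """
    if echo_spacing_s <= 0:
        raise ValueError("echo spacing must be positive")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    n = np.arange(1, n_max + 1)
    return n / (2.0 * echo_spacing_s)


def resonance_overlap(
    harmonics_hz: Sequence[float], band_center_hz: float, band_halfwidth_hz: float
) -> np.ndarray:
    """Flag which harmonics fall inside a mechanical-resonance band."""
    if band_halfwidth_hz < 0:
        raise ValueError("band halfwidth must be non-negative")
    h = np.asarray(harmonics_hz, dtype=float)
    return np.abs(h - band_center_hz) <= band_halfwidth_hz
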