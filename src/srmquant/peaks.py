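"""Chromatographic peak detection, integration, S/N and interference QC.

The processing rules mirror manual SRM review practice on a triple
quadrupole: the heavy internal standard fixes the expected retention time;
light peaks must co-elute with the heavy standard and reproduce its
relative transition-intensity signature; quantifiable signals need
S/N >= 10, with noise taken as the highest background intensity within
+/-15 s of the apex but outside the integrated peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

SNR_CAP = 1e6  # reported S/N when no background is observable

#: reason codes for missing L/H values
NO_PEAK = "no_peak"
LOW_SNR = "low_snr"
RT_MISMATCH = "rt_mismatch"
INTERFERED = "interfered"


@dataclass(frozen=True)
class Trace:
    """One transition's extracted ion chromatogram in one sample."""

    sample_id: str
    transition_key: tuple[str, str, int]  # (peptide, fragment, fragment charge)
    label: str  # 'light' | 'heavy'
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if t.size < 2:
            raise ValueError("a trace needs at least 2 points")
        if t.size != y.size:
            raise ValueError("times and intensities differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("intensities must be non-negative")
        if self.label not in ("light", "heavy"):
            raise ValueError(f"label must be 'light' or 'heavy', got {self.label!r}")

    @property
    def irregular_sampling(self) -> bool:
        """True when the max/min sampling interval ratio is >= 2."""
        d = np.diff(self.times)
        return bool(d.max() / d.min() >= 2)


@dataclass(frozen=True)
class ChromatogramSet:
    """All traces (light + heavy, three transitions) of one peptide in one
    sample. ``quantifier`` names the fragment used for quantitation."""

    sample_id: str
    peptide: str
    traces: tuple[Trace, ...]
    quantifier: str  # fragment name, e.g. 'y7'

    def get(self, fragment: str, label: str) -> Trace | None:
        for tr in self.traces:
            if tr.transition_key[1] == fragment and tr.label == label:
                return tr
        return None

    @property
    def fragments(self) -> list[str]:
        seen: list[str] = []
        for tr in self.traces:
            if tr.transition_key[1] not in seen:
                seen.append(tr.transition_key[1])
        return seen


@dataclass(frozen=True)
class PeakResult:
    apex_time: float
    apex_intensity: float
    left: float
    right: float
    area: float = 0.0
    noise_level: float = float("nan")
    snr: float = float("nan")
    found: bool = True


@dataclass(frozen=True)
class GroupQC:
    """QC verdict for one peptide in one sample."""

    rt_match: bool
    expected_ratios: tuple[float, ...]
    observed_ratios: tuple[float, ...]
    interference_flags: tuple[bool, ...]
    detectable: bool
    reason: str | None = None  # set when not detectable


@dataclass(frozen=True)
class QuantResult:
    sample_id: str
    peptide: str
    qc: GroupQC
    light_area: float
    heavy_area: float
    lh_ratio: float | None  # None when not detectable
    quantifier_snr: float


def detect_peak(
    trace: Trace,
    expected_rt: float,
    search_half_window: float = 15.0,
    boundary_fraction: float = 0.05,
    boundary_cap: float = 30.0,
    rise_fraction: float = 0.2,
) -> PeakResult:
    """Locate the peak nearest ``expected_rt``.

    The apex is the maximum intensity inside ``expected_rt +/-
    search_half_window`` (nearest-to-expectation on ties). Boundaries walk
    outward to the first point below ``boundary_fraction * apex``, or to a
    valley where the signal turns back up by more than ``rise_fraction *
    apex`` (a neighboring peak; small noise-driven rises do not split the
    peak), capped at ``boundary_cap`` seconds from the apex. ``found`` is
    False when no positive signal exists in the window.
    """
    t, y = trace.times, trace.intensities
    if not (t[0] <= expected_rt <= t[-1]):
        raise ValueError(
            f"expected RT {expected_rt} outside trace range [{t[0]}, {t[-1]}]"
        )
    in_win = np.flatnonzero(np.abs(t - expected_rt) <= search_half_window)
    if in_win.size == 0:
        raise ValueError("search window contains no trace points")
    y_win = y[in_win]
    apex_val = y_win.max()
    if apex_val <= 0:
        return PeakResult(expected_rt, 0.0, expected_rt, expected_rt, found=False)
    # ties broken toward the expected RT
    tie_idx = in_win[y_win == apex_val]
    apex_i = int(tie_idx[np.argmin(np.abs(t[tie_idx] - expected_rt))])
    apex_t = float(t[apex_i])

    floor = boundary_fraction * apex_val
    rise = rise_fraction * apex_val
    left_i = apex_i
    low = y[apex_i]
    while left_i > 0:
        nxt = left_i - 1
        if apex_t - t[nxt] > boundary_cap:
            break
        if y[nxt] <= floor or y[nxt] - low > rise:  # floor, or a real valley
            break
        low = min(low, y[nxt])
        left_i = nxt
    right_i = apex_i
    low = y[apex_i]
    while right_i < t.size - 1:
        nxt = right_i + 1
        if t[nxt] - apex_t > boundary_cap:
            break
        if y[nxt] <= floor or y[nxt] - low > rise:
            break
        low = min(low, y[nxt])
        right_i = nxt
    # include the crossing point itself so the baseline anchors below the floor
    if left_i > 0 and y[left_i] > floor:
        left_i -= 1
    if right_i < t.size - 1 and y[right_i] > floor:
        right_i += 1
    return PeakResult(apex_t, float(apex_val), float(t[left_i]), float(t[right_i]))


def integrate_area(trace: Trace, peak: PeakResult) -> float:
    """Baseline-subtracted trapezoidal area between the peak boundaries.

    The baseline is the straight line through the boundary intensities;
    the result is floored at zero.
    """
    if not peak.found:
        raise ValueError("cannot integrate a peak that was not found")
    t, y = trace.times, trace.intensities
    if peak.left < t[0] or peak.right > t[-1]:
        raise ValueError("peak boundaries outside trace")
    sel = (t >= peak.left) & (t <= peak.right)
    ts, ys = t[sel], y[sel]
    if ts.size < 2:
        return 0.0
    baseline = np.interp(ts, [ts[0], ts[-1]], [ys[0], ys[-1]])
    return max(float(np.trapezoid(ys - baseline, ts)), 0.0)


def signal_to_noise(
    trace: Trace, peak: PeakResult, noise_half_window: float = 15.0
) -> tuple[float, float]:
    """(S/N, noise level) with noise = the highest intensity within
    ``noise_half_window`` seconds of the apex but outside the peak
    boundaries. With no background points or zero background the S/N is
    capped at ``SNR_CAP``."""
    if not peak.found:
        raise ValueError("cannot compute S/N for a peak that was not found")
    t, y = trace.times, trace.intensities
    near = np.abs(t - peak.apex_time) <= noise_half_window
    outside = (t < peak.left) | (t > peak.right)
    bg = y[near & outside]
    if bg.size == 0 or bg.max() <= 0:
        return SNR_CAP, 0.0
    noise = float(bg.max())
    return min(peak.apex_intensity / noise, SNR_CAP), noise


class MissingHeavyStandardError(ValueError):
    """A heavy internal-standard trace or peak is absent — the assay's
    reference signature cannot be established."""


def expected_transition_ratios(heavy_areas: dict[str, float]) -> dict[str, float]:
    """Normalize heavy-standard peak areas to a unit-sum signature."""
    total = sum(heavy_areas.values())
    if total <= 0:
        raise MissingHeavyStandardError("heavy standard areas sum to zero")
    return {k: v / total for k, v in heavy_areas.items()}


def flag_interference(
    observed: dict[str, float],
    expected: dict[str, float],
    threshold: float = 0.2,
) -> dict[str, bool]:
    """Flag transitions whose observed share deviates from the heavy-
    standard signature by more than ``threshold`` relative, i.e.
    |obs_i - exp_i| / exp_i > threshold."""
    flags: dict[str, bool] = {}
    for k, exp in expected.items():
        if exp == 0:
            raise ValueError(f"expected ratio for {k} is zero")
        flags[k] = abs(observed[k] - exp) / exp > threshold
    return flags


def ratio_dot_product(observed: dict[str, float], expected: dict[str, float]) -> float:
    """Normalized dot product of the two signatures (secondary diagnostic;
    1.0 = identical shape)."""
    keys = sorted(expected)
    o = np.array([observed[k] for k in keys])
    e = np.array([expected[k] for k in keys])
    denom = np.linalg.norm(o) * np.linalg.norm(e)
    return float(o @ e / denom) if denom > 0 else float("nan")


def quantify_group(
    cs: ChromatogramSet,
    snr_min: float = 10.0,
    interference_threshold: float = 0.2,
    rt_tolerance: float = 6.0,
    search_half_window: float = 15.0,
    boundary_fraction: float = 0.05,
) -> QuantResult:
    """Full light/heavy quantification of one peptide in one sample.

    Heavy peaks (detected around the intensity-weighted heavy apex) fix
    the expected RT and the transition-ratio signature; light peaks are
    then detected in that window. Detectability requires RT agreement
    within ``rt_tolerance``, quantifier S/N >= ``snr_min`` and an
    uninterfered quantifier. L/H is the light/heavy quantifier area ratio;
    when not detectable it is None and ``qc.reason`` carries a code.
    """
    fragments = cs.fragments
    heavy_peaks: dict[str, PeakResult] = {}
    heavy_areas: dict[str, float] = {}
    for frag in fragments:
        tr = cs.get(frag, "heavy")
        if tr is None:
            raise MissingHeavyStandardError(
                f"{cs.peptide}: no heavy trace for transition {frag}"
            )
        guess = float(tr.times[np.argmax(tr.intensities)])
        pk = detect_peak(tr, guess, search_half_window, boundary_fraction)
        if not pk.found:
            raise MissingHeavyStandardError(
                f"{cs.peptide}: heavy standard peak not found for {frag}"
            )
        heavy_peaks[frag] = pk
        heavy_areas[frag] = integrate_area(tr, pk)

    expected = expected_transition_ratios(heavy_areas)
    quant_frag = cs.quantifier
    heavy_apex = heavy_peaks[quant_frag].apex_time

    light_areas: dict[str, float] = {}
    light_peaks: dict[str, PeakResult] = {}
    for frag in fragments:
        tr = cs.get(frag, "light")
        if tr is None:
            light_areas[frag] = 0.0
            continue
        pk = detect_peak(tr, heavy_apex, search_half_window, boundary_fraction)
        light_peaks[frag] = pk
        light_areas[frag] = integrate_area(tr, pk) if pk.found else 0.0

    total_light = sum(light_areas.values())
    if quant_frag not in light_peaks or not light_peaks[quant_frag].found or total_light <= 0:
        qc = GroupQC(False, _vec(expected, fragments), (0.0,) * len(fragments),
                     (False,) * len(fragments), False, NO_PEAK)
        return QuantResult(cs.sample_id, cs.peptide, qc, 0.0,
                           heavy_areas[quant_frag], None, 0.0)

    observed = {k: v / total_light for k, v in light_areas.items()}
    flags = flag_interference(observed, expected, interference_threshold)

    lp = light_peaks[quant_frag]
    snr, _noise = signal_to_noise(cs.get(quant_frag, "light"), lp)
    rt_ok = abs(lp.apex_time - heavy_apex) <= rt_tolerance

    reason = None
    if not rt_ok:
        reason = RT_MISMATCH
    elif snr < snr_min:
        reason = LOW_SNR
    elif flags[quant_frag]:
        reason = INTERFERED
    detectable = reason is None

    qc = GroupQC(
        rt_match=rt_ok,
        expected_ratios=_vec(expected, fragments),
        observed_ratios=_vec(observed, fragments),
        interference_flags=tuple(flags[f] for f in fragments),
        detectable=detectable,
        reason=reason,
    )
    lh = light_areas[quant_frag] / heavy_areas[quant_frag] if detectable else None
    return QuantResult(
        cs.sample_id, cs.peptide, qc,
        light_areas[quant_frag], heavy_areas[quant_frag], lh, snr,
    )


def _vec(d: dict[str, float], order: list[str]) -> tuple[float, ...]:
    return tuple(d[k] for k in order)
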