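"""Synthetic SRM data with known ground truth.

Two generators cover the pipeline's inputs end to end:

* :func:`simulate_chromatogram_set` builds one peptide's light and heavy
  extracted ion chromatograms — Gaussian co-eluting peaks sharing a fixed
  transition-intensity signature, additive detector noise, optional
  intensity spikes and an optional co-eluting contaminant on one light
  transition.
* :func:`simulate_cohort` builds a samples x peptides L/H matrix with a
  clinical manifest — log-normal abundances with per-marker group effect
  sizes, controlled within-protein peptide correlation, a per-sample
  prostatic-secretion factor shared by all prostate-derived markers and
  PSA, and a post-op group whose PSA is a small fraction of pre-op levels
  (the prostate having been removed).

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import PSA_PEPTIDE
from .peaks import ChromatogramSet, Trace
from .quantify import SampleRecord


# ------------------------------------------------------------ chromatograms

@dataclass(frozen=True)
class Interference:
    """A co-eluting contaminant in one light transition channel."""

    transition_index: int       # 0, 1 or 2
    relative_height: float      # fraction of that transition's light apex
    rt_offset: float = 0.0      # contaminant apex relative to the peptide's


@dataclass(frozen=True)
class ChromSimConfig:
    """Conditions for one simulated chromatogram set.

    Defaults emulate a spiked urine digest run: a 10-fmol/uL heavy
    standard giving an apex of ~1e4 counts, 3-second peak width, 0.5 s
    dwell-cycle sampling, and a transition signature of roughly 5:3:2.
    """

    true_lh: float = 1.0
    transition_ratio_signature: tuple[float, float, float] = (0.5, 0.3, 0.2)
    apex_rt: float = 60.0
    peak_sigma: float = 3.0
    sampling_interval: float = 0.5
    time_start: float = 0.0
    time_end: float = 120.0
    heavy_apex_total: float = 10_000.0  # summed apex height over transitions
    noise_sd: float = 5.0
    relative_noise: float = 0.0  # extra per-trace noise SD as fraction of that trace's apex
    spike_probability: float = 0.0
    spike_height: float = 0.0
    interference: Interference | None = None
    light_rt_shift: float = 0.0         # mis-elution of the endogenous peptide
    peptide: str = "AVIDDAFAR"
    fragments: tuple[str, str, str] = ("y7", "y6", "y5")
    seed: int = 0

    def __post_init__(self) -> None:
        sig = self.transition_ratio_signature
        if abs(sum(sig) - 1.0) > 1e-9 or any(s <= 0 for s in sig):
            raise ValueError("transition signature must be positive and sum to 1")
        for name in ("peak_sigma", "sampling_interval", "heavy_apex_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.true_lh < 0 or self.noise_sd < 0 or self.relative_noise < 0:
            raise ValueError("true_lh and noise levels must be >= 0")


@dataclass(frozen=True)
class ChromTruth:
    true_lh: float
    apex_rt: float
    signature: tuple[float, float, float]
    interfered_fragment: str | None


def _gaussian(t: np.ndarray, apex: float, mu: float, sigma: float) -> np.ndarray:
    return apex * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def simulate_chromatogram_set(
    cfg: ChromSimConfig, sample_id: str = "SIM-01C"
) -> tuple[ChromatogramSet, ChromTruth]:
    """Generate light + heavy traces for one peptide under ``cfg``.

    Heavy peaks carry the signature ratios at ``heavy_apex_total`` summed
    apex height; light peaks are the same shape scaled by ``true_lh``
    (optionally RT-shifted); Gaussian noise (truncated at zero) and
    optional spikes are added per point; an optional contaminant Gaussian
    is injected into one light channel.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.time_start, cfg.time_end + 1e-9, cfg.sampling_interval)
    traces = []
    interfered = None
    for i, frag in enumerate(cfg.fragments):
        heavy_apex = cfg.heavy_apex_total * cfg.transition_ratio_signature[i]
        y_heavy = _gaussian(t, heavy_apex, cfg.apex_rt, cfg.peak_sigma)
        y_light = _gaussian(
            t, heavy_apex * cfg.true_lh,
            cfg.apex_rt + cfg.light_rt_shift, cfg.peak_sigma,
        )
        if cfg.interference is not None and cfg.interference.transition_index == i:
            contaminant_apex = heavy_apex * cfg.true_lh * cfg.interference.relative_height
            y_light = y_light + _gaussian(
                t, contaminant_apex,
                cfg.apex_rt + cfg.interference.rt_offset, cfg.peak_sigma,
            )
            interfered = frag
        for label, y in (("heavy", y_heavy), ("light", y_light)):
            sd = cfg.noise_sd + cfg.relative_noise * (y.max() if y.max() > 0 else 0.0)
            noisy = y + rng.normal(0.0, sd, t.size) if sd > 0 else y.copy()
            if cfg.spike_probability > 0:
                spikes = rng.random(t.size) < cfg.spike_probability
                noisy = noisy + spikes * cfg.spike_height
            traces.append(
                Trace(sample_id, (cfg.peptide, frag, 1), label,
                      t.copy(), np.clip(noisy, 0.0, None))
            )
    cs = ChromatogramSet(sample_id, cfg.peptide, tuple(traces), cfg.fragments[0])
    truth = ChromTruth(cfg.true_lh, cfg.apex_rt,
                       cfg.transition_ratio_signature, interfered)
    return cs, truth


# ------------------------------------------------------------------ cohorts

@dataclass(frozen=True)
class MarkerSimSpec:
    """One surrogate peptide's generating parameters (natural-log scale)."""

    protein: str
    effect_d: float = 0.0        # cancer-vs-non-cancer shift in within-group SDs
    prostate_derived: bool = True
    significance_fold: float = 1.0  # extra fold-change in significant cancers
    base_log_mean: float = 0.0


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort generating conditions.

    Defaults mirror the pilot study design: 14 pre-op cancer, 6 non-cancer
    and 7 post-op urine samples; within the cancer group, 6 low-volume/
    low-grade and 5 clinically significant tumors (the rest unannotated);
    post-op PSA at 1% of pre-op levels. ``rho_within_protein`` sets the
    target log-scale correlation between surrogate peptides of the same
    protein; ``secretion_sd`` is the SD of a per-sample log factor shared
    by every prostate-derived marker and PSA (prostatic output varies
    between donors, confounding raw concentrations).
    """

    markers: dict[str, MarkerSimSpec] = field(default_factory=dict)
    n_cancer: int = 14
    n_noncancer: int = 6
    n_postop: int = 7
    n_low_grade: int = 6
    n_significant: int = 5
    rho_within_protein: float = 0.8
    within_sd: float = 1.0       # log-scale within-group SD of each peptide
    secretion_sd: float = 0.0
    psa_log_mean: float = 3.0    # exp(3) ~ 20 L/H units for pre-op PSA
    psa_log_sd: float = 1.0
    postop_psa_fraction: float = 0.01
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cancer, self.n_noncancer, self.n_postop) < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_low_grade + self.n_significant > self.n_cancer:
            raise ValueError("stratum sizes exceed the cancer group")
        if not 0 <= self.rho_within_protein < 1:
            raise ValueError("rho_within_protein must be in [0, 1)")
        if not 0 < self.postop_psa_fraction <= 1:
            raise ValueError("postop_psa_fraction must be in (0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def default_marker_specs(effect_d: float = 1.0) -> dict[str, MarkerSimSpec]:
    """A compact marker set echoing the published panel's structure:
    two proteins carried by multiple surrogate peptides (for concordance)
    plus two single-peptide markers, all with the same effect size."""
    return {
        "AVIDDAFAR": MarkerSimSpec("MMP9", effect_d, significance_fold=12.0),
        "FQTFEGDLK": MarkerSimSpec("MMP9", effect_d, significance_fold=12.0),
        "LGLGADVAQVTGALR": MarkerSimSpec("MMP9", effect_d, significance_fold=12.0),
        "VLYLSAFTSK": MarkerSimSpec("CD90", effect_d),
        "HVLFGTVGVPEHTYR": MarkerSimSpec("CD90", effect_d),
        "SDLVNEEATGQFR": MarkerSimSpec("CEAM5", effect_d),
        "LPQTLSR": MarkerSimSpec("AGR2", effect_d),
    }


def simulate_cohort(
    cfg: CohortSimConfig,
) -> tuple[pd.DataFrame, list[SampleRecord], dict]:
    """Generate (marker matrix, manifest, truth) for one cohort.

    The log-scale model per sample s and peptide j of protein P is

        log v_sj = base_j + d_j * sd_w * [s cancer] + log(fold_j) * [s significant]
                   + f_s * [j prostate-derived] + sd_w * (sqrt(rho) * z_sP
                   + sqrt(1-rho) * e_sj)

    with f_s ~ N(0, secretion_sd^2) the shared prostatic-secretion factor
    and z, e standard normals. PSA follows the same secretion factor with
    no group effect, times ``postop_psa_fraction`` in post-op samples.
    """
    markers = cfg.markers or default_marker_specs()
    rng = np.random.default_rng(cfg.seed)

    sample_ids, groups = [], []
    for i in range(cfg.n_cancer):
        sample_ids.append(f"P{i + 1:03d}C")
        groups.append("cancer")
    for i in range(cfg.n_noncancer):
        sample_ids.append(f"P{i + 1:03d}N")
        groups.append("non-cancer")
    for i in range(cfg.n_postop):
        sample_ids.append(f"POST{i + 1:03d}")
        groups.append("post-op")
    n = len(sample_ids)

    # cancer-group strata: first n_low_grade low-grade, next n_significant
    # significant, remainder unannotated
    manifest: list[SampleRecord] = []
    n_assigned = 0
    for sid, grp in zip(sample_ids, groups):
        gleason = volume = None
        if grp == "cancer":
            if n_assigned < cfg.n_low_grade:
                gleason, volume = 6, 0.3
            elif n_assigned < cfg.n_low_grade + cfg.n_significant:
                gleason, volume = 8, 1.8
            n_assigned += 1
        manifest.append(
            SampleRecord(
                sid, grp,
                total_protein_ug=float(rng.uniform(200, 300)),
                gleason=gleason, tumor_volume_cc=volume,
                serum_psa=float(rng.lognormal(1.5, 0.5)) if grp != "post-op" else None,
            )
        )

    is_cancer = np.array([g == "cancer" for g in groups])
    is_postop = np.array([g == "post-op" for g in groups])
    is_significant = np.array([r.significance == "significant" for r in manifest])

    secretion = rng.normal(0.0, cfg.secretion_sd, n) if cfg.secretion_sd > 0 else np.zeros(n)
    proteins = sorted({m.protein for m in markers.values()})
    z_protein = {p: rng.standard_normal(n) for p in proteins}

    rho, sd_w = cfg.rho_within_protein, cfg.within_sd
    data: dict[str, np.ndarray] = {}
    for pep, spec in markers.items():
        eps = rng.standard_normal(n)
        logv = (
            spec.base_log_mean
            + spec.effect_d * sd_w * is_cancer
            + np.log(spec.significance_fold) * is_significant
            + (secretion if spec.prostate_derived else 0.0)
            + sd_w * (np.sqrt(rho) * z_protein[spec.protein]
                      + np.sqrt(1.0 - rho) * eps)
        )
        data[pep] = np.exp(logv)

    log_psa = cfg.psa_log_mean + cfg.psa_log_sd * rng.standard_normal(n) + secretion
    log_psa = log_psa + np.log(cfg.postop_psa_fraction) * is_postop
    data[PSA_PEPTIDE] = np.exp(log_psa)

    matrix = pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"))
    if cfg.missing_rate > 0:
        marker_cols = [c for c in matrix.columns if c != PSA_PEPTIDE]
        mask = rng.random((n, len(marker_cols))) < cfg.missing_rate
        matrix[marker_cols] = matrix[marker_cols].mask(mask)

    truth = {
        "markers": markers,
        "secretion_factor": pd.Series(secretion, index=matrix.index),
        "config": cfg,
    }
    return matrix, manifest, truth
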