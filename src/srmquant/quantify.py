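"""Concentration conversion and PSA-referenced normalization.

With heavy standards spiked at a known concentration into a digest of
known total-protein concentration, the L/H peak-area ratio converts
directly to analyte amount per mass of total urinary protein:

    fmol / ug total protein = L/H x spike (fmol/uL) / digest (ug/uL)

reported per 100 ug, and in ng/100 ug when the protein molecular weight
is supplied. Normalizing every marker's L/H by the urinary PSA peptide's
L/H references each sample to its prostate-specific secretion level and
cancels per-sample multiplicative effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import PSA_PEPTIDE

#: default spiking conditions: 10 fmol/uL heavy standards in 0.5 ug/uL digest
DEFAULT_SPIKE_FMOL_PER_UL = 10.0
DEFAULT_DIGEST_UG_PER_UL = 0.5

GROUPS = ("cancer", "non-cancer", "post-op")


@dataclass(frozen=True)
class SampleRecord:
    """Clinical annotations for one urine sample."""

    sample_id: str
    group: str  # cancer | non-cancer | post-op
    total_protein_ug: float | None = None
    gleason: int | None = None
    tumor_volume_cc: float | None = None
    serum_psa: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def significance(self) -> str:
        """'low_grade' for Gleason <= 6 and tumor volume <= 0.5 cc,
        'significant' otherwise; 'n.a.' when either field is missing."""
        if self.gleason is None or self.tumor_volume_cc is None:
            return "n.a."
        if self.gleason <= 6 and self.tumor_volume_cc <= 0.5:
            return "low_grade"
        return "significant"

    @classmethod
    def from_suffix(cls, sample_id: str, **kwargs) -> "SampleRecord":
        """Infer the group from the sample-code suffix convention:
        trailing N = non-cancer, trailing C = cancer (pre-op)."""
        if sample_id.endswith("N"):
            group = "non-cancer"
        elif sample_id.endswith("C"):
            group = "cancer"
        else:
            raise ValueError(
                f"cannot infer group from sample id {sample_id!r}; "
                "expected an N or C suffix"
            )
        return cls(sample_id, group, **kwargs)


def lh_to_amount(
    lh: float,
    spike_conc: float = DEFAULT_SPIKE_FMOL_PER_UL,
    digest_conc: float = DEFAULT_DIGEST_UG_PER_UL,
    protein_mw: float | None = None,
    purity: float = 1.0,
) -> float:
    """Convert an L/H ratio to fmol per 100 ug total urinary protein
    (or ng/100 ug when ``protein_mw`` in Da is given).

    ``purity`` multiplies the effective heavy-standard concentration
    (1.0 for pure standards; crude standards would use their assayed
    purity).
    """
    if lh < 0:
        raise ValueError("L/H ratio must be >= 0")
    if spike_conc <= 0 or digest_conc <= 0 or purity <= 0:
        raise ValueError("spike, digest concentration and purity must be > 0")
    fmol_per_100ug = lh * (spike_conc * purity) / digest_conc * 100.0
    if protein_mw is None:
        return fmol_per_100ug
    if protein_mw <= 0:
        raise ValueError("protein molecular weight must be > 0")
    return fmol_per_100ug * protein_mw * 1e-6  # fmol * g/mol * 1e-6 = ng


def amount_to_lh(
    amount_fmol_per_100ug: float,
    spike_conc: float = DEFAULT_SPIKE_FMOL_PER_UL,
    digest_conc: float = DEFAULT_DIGEST_UG_PER_UL,
) -> float:
    """Inverse of :func:`lh_to_amount` (fmol scale)."""
    return amount_fmol_per_100ug / 100.0 * digest_conc / spike_conc


def normalize_to_psa(
    matrix: pd.DataFrame, psa_peptide: str = PSA_PEPTIDE
) -> tuple[pd.DataFrame, pd.Series]:
    """Divide every marker L/H by the sample's PSA-peptide L/H.

    Rows where the PSA value is missing or non-positive are excluded;
    the returned Series maps each excluded sample id to the reason.
    Missing marker cells stay missing; the PSA column maps to 1.
    """
    if psa_peptide not in matrix.columns:
        raise KeyError(f"PSA column {psa_peptide!r} not in matrix")
    psa = matrix[psa_peptide]
    dropped: dict[str, str] = {}
    keep = []
    for sid, val in psa.items():
        if pd.isna(val):
            dropped[sid] = "PSA value missing"
        elif val <= 0:
            dropped[sid] = "PSA value non-positive"
        else:
            keep.append(sid)
    sub = matrix.loc[keep]
    normalized = sub.div(sub[psa_peptide], axis=0)
    return normalized, pd.Series(dropped, dtype=object, name="excluded_reason")


def psa_origin_summary(
    pre_op: "np.ndarray | list[float]", post_op: "np.ndarray | list[float]"
) -> dict[str, float]:
    """Compare urinary PSA amounts before and after radical prostatectomy.

    Returns group means and medians, the mean-based percentage
    100*mean(post)/mean(pre) (with its nearest-integer headline), and the
    median-based percentage. A post-op level near 1% of pre-op indicates
    the urinary PSA signal is essentially all of prostatic origin.
    """
    pre = np.asarray(pre_op, dtype=float)
    post = np.asarray(post_op, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("both groups must be non-empty")
    mean_pct = 100.0 * post.mean() / pre.mean()
    return {
        "pre_mean": float(pre.mean()),
        "pre_median": float(np.median(pre)),
        "post_mean": float(post.mean()),
        "post_median": float(np.median(post)),
        "percent_mean": float(mean_pct),
        "percent_mean_headline": float(round(mean_pct)),
        "percent_median": float(100.0 * np.median(post) / np.median(pre)),
    }
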