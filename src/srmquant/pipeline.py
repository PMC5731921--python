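"""End-to-end orchestration: chromatograms -> L/H matrix -> marker report.

``run_quant`` applies the chromatogram QC/quantification rules per peptide
per sample and writes the marker matrix; ``run_report`` produces the
performance tables (raw and PSA-normalized P/AUC/cutoff per peptide),
within-protein concordance, the logistic panel search and the risk
stratification. Both are deterministic given their inputs and seed, and
every run writes a provenance block (config echo, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    quantifier_map,
    read_assay_csv,
    read_chromatogram_csv,
    read_manifest_csv,
    results_to_matrix,
    write_matrix_csv,
)
from .panel import PSA_PEPTIDE, PROTEIN_OF
from .peaks import quantify_group
from .quantify import SampleRecord, normalize_to_psa
from .stats import (
    bh_adjust,
    concordance,
    optimal_cutoff,
    rank_test,
    roc,
    search_panels,
    stratify,
)


@dataclass
class RunConfig:
    """Thresholds and paths for a pipeline run. The QC thresholds default
    to the assay's operating rules: quantifiability at S/N >= 10,
    interference at 20% relative signature deviation, co-elution within
    6 s, peak boundaries at 5% of apex."""

    assay_path: str | None = None
    chromatogram_path: str | None = None
    manifest_path: str | None = None
    output_dir: str = "srmquant_out"
    snr_min: float = 10.0
    interference_threshold: float = 0.2
    rt_tolerance: float = 6.0
    boundary_fraction: float = 0.05
    psa_peptide: str = PSA_PEPTIDE
    panel_max_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_min <= 0 or self.interference_threshold <= 0:
            raise ValueError("snr_min and interference_threshold must be > 0")
        if self.rt_tolerance <= 0 or not 0 < self.boundary_fraction < 1:
            raise ValueError("rt_tolerance > 0 and boundary_fraction in (0,1) required")

    def provenance(self) -> dict:
        cfg = asdict(self)
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return {"config": cfg, "config_hash": digest,
                "seed": self.seed, "srmquant_version": __version__}


def _write_provenance(cfg: RunConfig, outdir: Path, stage: str) -> None:
    with open(outdir / f"provenance_{stage}.yaml", "w") as fh:
        yaml.safe_dump(cfg.provenance(), fh, sort_keys=True)


def run_quant(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify every (sample, peptide) chromatogram set.

    Returns (L/H matrix, QC report) and writes marker_matrix.csv (with a
    missing-reason sidecar) and qc_report.csv to the output directory.
    """
    if cfg.assay_path is None or cfg.chromatogram_path is None:
        raise ValueError("run_quant needs assay_path and chromatogram_path")
    assays = read_assay_csv(cfg.assay_path)
    sets = read_chromatogram_csv(cfg.chromatogram_path, quantifier_map(assays))
    results = [
        quantify_group(
            cs,
            snr_min=cfg.snr_min,
            interference_threshold=cfg.interference_threshold,
            rt_tolerance=cfg.rt_tolerance,
            boundary_fraction=cfg.boundary_fraction,
        )
        for cs in sets
    ]
    matrix, reasons = results_to_matrix(results)
    qc = pd.DataFrame([{
        "sample_id": r.sample_id,
        "peptide": r.peptide,
        "detectable": r.qc.detectable,
        "reason": r.qc.reason,
        "rt_match": r.qc.rt_match,
        "quantifier_snr": r.quantifier_snr,
        "light_area": r.light_area,
        "heavy_area": r.heavy_area,
        "lh_ratio": r.lh_ratio,
        "expected_ratios": "|".join(f"{v:.4f}" for v in r.qc.expected_ratios),
        "observed_ratios": "|".join(f"{v:.4f}" for v in r.qc.observed_ratios),
        "interference_flags": "|".join(str(f) for f in r.qc.interference_flags),
    } for r in results])

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_csv(matrix, outdir / "marker_matrix.csv", reasons)
    qc.to_csv(outdir / "qc_report.csv", index=False)
    _write_provenance(cfg, outdir, "quant")
    return matrix, qc


def marker_performance(
    matrix: pd.DataFrame,
    labels: pd.Series,
    psa_peptide: str | None = PSA_PEPTIDE,
) -> pd.DataFrame:
    """Per-peptide two-group test and ROC, raw and PSA-normalized.

    ``labels``: 1 = cancer, 0 = non-cancer, indexed by sample. Columns
    mirror the usual marker-performance table: raw P and AUC, normalized
    P/AUC with the Youden-cutoff sensitivity and specificity, plus a
    supplementary Benjamini-Hochberg column on the normalized P.
    """
    peptides = [c for c in matrix.columns if c != psa_peptide]
    norm = None
    if psa_peptide is not None and psa_peptide in matrix.columns:
        norm, _ = normalize_to_psa(matrix, psa_peptide)

    rows = []
    for pep in peptides:
        row: dict = {"peptide": pep}
        for tag, mat in (("raw", matrix), ("norm", norm)):
            if mat is None:
                continue
            vals = mat[pep]
            common = vals.index.intersection(labels.index)
            v, y = vals.loc[common], labels.loc[common]
            ok = v.notna()
            v, y = v[ok], y[ok].astype(int)
            if y.nunique() < 2:
                continue
            _, p = rank_test(v[y == 1], v[y == 0])
            curve = roc(v.to_numpy(), y.to_numpy())
            row[f"p_{tag}"] = p
            row[f"auc_{tag}"] = curve.auc
            row[f"auc_{tag}_ci_low"] = curve.ci_low
            row[f"auc_{tag}_ci_high"] = curve.ci_high
            if tag == "norm":
                cut = optimal_cutoff(curve)
                row["cutoff"] = cut.cutoff
                row["sensitivity"] = cut.sensitivity
                row["specificity"] = cut.specificity
        rows.append(row)
    out = pd.DataFrame(rows).set_index("peptide")
    if "p_norm" in out.columns:
        out["p_norm_bh"] = bh_adjust(out["p_norm"])
    return out


def run_report(
    cfg: RunConfig,
    matrix: pd.DataFrame | None = None,
    manifest: list[SampleRecord] | None = None,
    protein_map: dict[str, str] | None = None,
) -> dict:
    """Produce the full marker report directory.

    Inputs may be passed directly or read from the configured paths.
    Writes performance.csv, concordance.csv, panel_search.csv,
    stratification.csv (or a placeholder when clinical annotations are
    absent) and a provenance block. Returns the tables in a dict.
    """
    from .io import read_matrix_csv  # local import to avoid cycle noise

    if matrix is None:
        if cfg.output_dir and (Path(cfg.output_dir) / "marker_matrix.csv").exists():
            matrix = read_matrix_csv(Path(cfg.output_dir) / "marker_matrix.csv")
        else:
            raise ValueError("run_report needs a marker matrix")
    if manifest is None:
        if cfg.manifest_path is None:
            raise ValueError("run_report needs a manifest")
        manifest = read_manifest_csv(cfg.manifest_path)
    protein_map = protein_map if protein_map is not None else PROTEIN_OF

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    by_id = {r.sample_id: r for r in manifest}
    shared = [s for s in matrix.index if s in by_id]
    matrix = matrix.loc[shared]
    groups = pd.Series({s: by_id[s].group for s in shared})
    labels = groups.map({"cancer": 1, "non-cancer": 0}).dropna()
    pre_matrix = matrix.loc[labels.index]

    psa = cfg.psa_peptide if cfg.psa_peptide in matrix.columns else None
    perf = marker_performance(pre_matrix, labels, psa)
    perf.to_csv(outdir / "performance.csv")

    conc_reports = concordance(pre_matrix.drop(columns=[psa], errors="ignore"),
                               protein_map)
    conc = pd.DataFrame([{
        "protein": rep.protein, "peptide_a": pr.peptide_a, "peptide_b": pr.peptide_b,
        "r_squared": pr.r_squared, "n_used": pr.n_used,
        "discordant_candidate": pr.discordant_candidate, "skip_reason": pr.skip_reason,
    } for rep in conc_reports for pr in rep.pairs])
    conc.to_csv(outdir / "concordance.csv", index=False)

    panel_df = pd.DataFrame()
    if psa is not None:
        norm, _ = normalize_to_psa(pre_matrix, psa)
        members = [c for c in norm.columns if c != psa]
        fits = search_panels(norm[members], labels.loc[norm.index],
                             max_size=cfg.panel_max_size)
        panel_df = pd.DataFrame([{
            "members": "+".join(m.members), "size": len(m.members),
            "auc": m.auc, "p_value": m.p_value, "n_used": m.n_used,
        } for m in fits])
        panel_df.to_csv(outdir / "panel_search.csv", index=False)

    strat_df = pd.DataFrame()
    cancer_ids = [s for s in shared if by_id[s].group == "cancer"]
    sig = pd.Series({s: by_id[s].significance for s in cancer_ids})
    if {"low_grade", "significant"} <= set(sig.unique()):
        strat_source = matrix if psa is None else normalize_to_psa(matrix, psa)[0]
        strat_ids = [s for s in cancer_ids if s in strat_source.index]
        strat_df = stratify(strat_source.loc[strat_ids], sig.loc[strat_ids])
        strat_df.to_csv(outdir / "stratification.csv")
    else:
        (outdir / "stratification.csv").write_text(
            "peptide,U,p_value,n_low_grade,n_significant\n"
            "# n.a. - manifest lacks Gleason/tumor-volume annotations\n"
        )

    _write_provenance(cfg, outdir, "report")
    return {"performance": perf, "concordance": conc,
            "panel_search": panel_df, "stratification": strat_df}
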