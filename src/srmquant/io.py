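"""CSV readers and writers for the pipeline's external formats.

Formats (all plain CSV, pandas-backed):

* assay table — one row per transition: protein, accession, peptide,
  fixed_mods, precursor_charge, fragment, fragment_charge, q1_light,
  q3_light, q1_heavy, q3_heavy, is_quantifier;
* chromatogram export (long) — sample_id, peptide, fragment,
  fragment_charge, label, time_sec, intensity;
* sample manifest — sample_id, group, total_protein_ug, gleason,
  tumor_volume_cc, serum_psa;
* marker matrix (wide, samples x peptides) with a sidecar
  missing-reason CSV.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .assay import FragmentIon, TransitionAssay
from .masses import DEFAULT_FIXED_MODS, PeptideSpec
from .peaks import ChromatogramSet, QuantResult, Trace
from .quantify import SampleRecord

_FRAG_RE = re.compile(r"^([by])(\d+)$")


class InputFormatError(ValueError):
    """A CSV input failed validation; the message carries row context."""


def _parse_fragment(name: str, charge: int) -> FragmentIon:
    m = _FRAG_RE.match(name)
    if not m:
        raise InputFormatError(f"bad fragment name {name!r} (expected e.g. 'y7')")
    return FragmentIon(m.group(1), int(m.group(2)), charge)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into {header: sequence} for the uniqueness
    screen."""
    from pyteomics import fasta

    try:
        with open(path) as fh:
            records = {header: seq for header, seq in fasta.read(fh)}
    except OSError as exc:
        raise InputFormatError(f"cannot read FASTA {path}: {exc}") from exc
    if not records:
        raise InputFormatError(f"{path}: no FASTA records found")
    return records


# -------------------------------------------------------------- assay table

def write_assay_csv(rows: list[TransitionAssay], path: str | Path) -> None:
    recs = []
    for r in rows:
        mods = ";".join(f"{res}+{shift}" for res, shift in sorted(r.peptide.fixed_mods))
        recs.append({
            "protein": r.peptide.protein_name,
            "accession": r.peptide.accession,
            "peptide": r.peptide.sequence,
            "fixed_mods": mods,
            "precursor_charge": r.precursor_charge,
            "fragment": f"{r.fragment.series}{r.fragment.index}",
            "fragment_charge": r.fragment.charge,
            "q1_light": round(r.q1_light, 4),
            "q3_light": round(r.q3_light, 4),
            "q1_heavy": round(r.q1_heavy, 4),
            "q3_heavy": round(r.q3_heavy, 4),
            "is_quantifier": r.is_quantifier,
        })
    pd.DataFrame(recs).to_csv(path, index=False)


def read_assay_csv(path: str | Path) -> list[TransitionAssay]:
    df = pd.read_csv(path)
    required = {"protein", "peptide", "precursor_charge", "fragment",
                "fragment_charge", "q1_light", "q3_light", "q1_heavy",
                "q3_heavy", "is_quantifier"}
    missing = required - set(df.columns)
    if missing:
        raise InputFormatError(f"assay CSV missing columns: {sorted(missing)}")
    rows = []
    for i, rec in df.iterrows():
        mods = set(DEFAULT_FIXED_MODS)
        if "fixed_mods" in df.columns and isinstance(rec["fixed_mods"], str) and rec["fixed_mods"]:
            mods = set()
            for part in rec["fixed_mods"].split(";"):
                res, shift = part.split("+")
                mods.add((res, float(shift)))
        try:
            p = PeptideSpec(
                rec["peptide"], frozenset(mods),
                protein_name=str(rec["protein"]),
                accession=str(rec.get("accession", "")),
            )
            frag = _parse_fragment(rec["fragment"], int(rec["fragment_charge"]))
            rows.append(TransitionAssay(
                p, int(rec["precursor_charge"]), frag,
                float(rec["q1_light"]), float(rec["q3_light"]),
                float(rec["q1_heavy"]), float(rec["q3_heavy"]),
                bool(rec["is_quantifier"]),
            ))
        except (ValueError, KeyError) as exc:
            raise InputFormatError(f"assay CSV row {i}: {exc}") from exc
    return rows


def quantifier_map(rows: list[TransitionAssay]) -> dict[str, str]:
    """peptide sequence -> quantifier fragment name, validated unique."""
    out: dict[str, str] = {}
    for r in rows:
        if r.is_quantifier:
            pep = r.peptide.sequence
            frag = f"{r.fragment.series}{r.fragment.index}"
            if pep in out and out[pep] != frag:
                raise InputFormatError(f"{pep}: more than one quantifier transition")
            out[pep] = frag
    return out


# ------------------------------------------------------------ chromatograms

def write_chromatogram_csv(sets: list[ChromatogramSet], path: str | Path) -> None:
    frames = []
    for cs in sets:
        for tr in cs.traces:
            frames.append(pd.DataFrame({
                "sample_id": tr.sample_id,
                "peptide": tr.transition_key[0],
                "fragment": tr.transition_key[1],
                "fragment_charge": tr.transition_key[2],
                "label": tr.label,
                "time_sec": tr.times,
                "intensity": tr.intensities,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_chromatogram_csv(
    path: str | Path, quantifiers: dict[str, str]
) -> list[ChromatogramSet]:
    """Parse a long-format chromatogram export into per-(sample, peptide)
    trace sets. Validates strictly increasing time within each trace.
    ``quantifiers`` maps peptide to its quantifier fragment name."""
    df = pd.read_csv(path)
    if df.empty:
        raise InputFormatError(f"{path}: chromatogram file is empty")
    required = {"sample_id", "peptide", "fragment", "fragment_charge",
                "label", "time_sec", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise InputFormatError(f"chromatogram CSV missing columns: {sorted(missing)}")
    sets = []
    for (sid, pep), grp in df.groupby(["sample_id", "peptide"], sort=True):
        traces = []
        for (frag, fz, label), tgrp in grp.groupby(
            ["fragment", "fragment_charge", "label"], sort=True
        ):
            tgrp = tgrp.sort_values("time_sec")
            try:
                traces.append(Trace(
                    str(sid), (str(pep), str(frag), int(fz)), str(label),
                    tgrp["time_sec"].to_numpy(float),
                    tgrp["intensity"].to_numpy(float),
                ))
            except ValueError as exc:
                raise InputFormatError(
                    f"trace (sample={sid}, peptide={pep}, fragment={frag}, "
                    f"label={label}): {exc}"
                ) from exc
        if pep not in quantifiers:
            raise InputFormatError(f"no quantifier defined for peptide {pep}")
        sets.append(ChromatogramSet(str(sid), str(pep), tuple(traces),
                                    quantifiers[str(pep)]))
    return sets


# ----------------------------------------------------------------- manifest

def write_manifest_csv(records: list[SampleRecord], path: str | Path) -> None:
    pd.DataFrame([{
        "sample_id": r.sample_id,
        "group": r.group,
        "total_protein_ug": r.total_protein_ug,
        "gleason": r.gleason,
        "tumor_volume_cc": r.tumor_volume_cc,
        "serum_psa": r.serum_psa,
    } for r in records]).to_csv(path, index=False)


def read_manifest_csv(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise InputFormatError("manifest CSV needs sample_id and group columns")

    def _opt(rec, col, cast):
        if col not in df.columns or pd.isna(rec[col]):
            return None
        return cast(rec[col])

    out = []
    for i, rec in df.iterrows():
        try:
            out.append(SampleRecord(
                str(rec["sample_id"]), str(rec["group"]),
                total_protein_ug=_opt(rec, "total_protein_ug", float),
                gleason=_opt(rec, "gleason", int),
                tumor_volume_cc=_opt(rec, "tumor_volume_cc", float),
                serum_psa=_opt(rec, "serum_psa", float),
            ))
        except ValueError as exc:
            raise InputFormatError(f"manifest row {i}: {exc}") from exc
    return out


# ------------------------------------------------------------ marker matrix

def results_to_matrix(
    results: list[QuantResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot quantification results to a samples x peptides L/H matrix
    plus a same-shaped missing-reason table (NaN cells carry a code)."""
    vals, reasons = {}, {}
    for r in results:
        vals[(r.sample_id, r.peptide)] = r.lh_ratio
        reasons[(r.sample_id, r.peptide)] = r.qc.reason
    sids = sorted({s for s, _ in vals})
    peps = sorted({p for _, p in vals})
    matrix = pd.DataFrame(
        [[vals.get((s, p), np.nan) for p in peps] for s in sids],
        index=pd.Index(sids, name="sample_id"), columns=peps, dtype=float,
    )
    reason_df = pd.DataFrame(
        [[reasons.get((s, p)) for p in peps] for s in sids],
        index=matrix.index, columns=peps,
    )
    return matrix, reason_df


def write_matrix_csv(
    matrix: pd.DataFrame, path: str | Path,
    reasons: pd.DataFrame | None = None,
) -> None:
    matrix.to_csv(path)
    if reasons is not None:
        sidecar = Path(path).with_name(Path(path).stem + "_reasons.csv")
        reasons.to_csv(sidecar)


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")
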