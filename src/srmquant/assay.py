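"""Transition assay construction, fragment annotation and peptide screening.

An SRM assay monitors, for each surrogate peptide, a precursor m/z (Q1) and
three fragment m/z values (Q3); one transition is designated the quantifier.
Printed transition lists usually omit fragment identities and precursor
charge, so this module also reverse-annotates them: ``match_precursor_charge``
finds the charge state whose computed Q1 matches a printed value, and
``annotate_q3`` assigns a printed Q3 to the nearest b/y fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .masses import PeptideSpec, fragment_mz, precursor_mz


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'b' or 'y'
    index: int
    charge: int = 1

    def __str__(self) -> str:
        sup = "" if self.charge == 1 else f"({self.charge}+)"
        return f"{self.series}{self.index}{sup}"


@dataclass(frozen=True)
class TransitionAssay:
    """One transition row: light and heavy Q1/Q3 for a chosen fragment."""

    peptide: PeptideSpec
    precursor_charge: int
    fragment: FragmentIon
    q1_light: float
    q3_light: float
    q1_heavy: float
    q3_heavy: float
    is_quantifier: bool = False

    def __post_init__(self) -> None:
        if self.q1_light <= 0 or self.q3_light <= 0:
            raise ValueError("m/z values must be positive")
        if self.fragment.index >= len(self.peptide):
            raise ValueError("fragment index must be < peptide length")


@dataclass(frozen=True)
class ScreenReport:
    """Outcome of suitability screening for one surrogate peptide."""

    peptide: PeptideSpec
    unique_in_fasta: bool | None  # None = no proteome supplied
    modification_flags: tuple[tuple[int, str], ...]
    verdict: str  # 'pass' | 'warn'


def match_precursor_charge(
    p: PeptideSpec,
    printed_q1: float,
    charges: tuple[int, ...] = (2, 3),
    tol: float = 0.05,
) -> int | None:
    """Charge state in ``charges`` whose precursor m/z is nearest the
    printed Q1, provided it falls within ``tol``; None otherwise."""
    best, best_err = None, tol
    for z in charges:
        err = abs(precursor_mz(p, z) - printed_q1)
        if err <= best_err:
            best, best_err = z, err
    return best


def annotate_q3(
    p: PeptideSpec,
    printed_q3: float,
    tol: float = 0.05,
    max_charge: int = 2,
) -> FragmentIon | None:
    """Assign a printed Q3 value to a b/y fragment of the light peptide.

    Searches both series at charges 1..max_charge and returns the nearest
    match within ``tol``, preferring y over b and lower charge on ties;
    None when nothing matches (reported, not an error).
    """
    candidates: list[tuple[float, int, int, FragmentIon]] = []
    light = p.as_light()
    for series_rank, series in ((0, "y"), (1, "b")):
        for z in range(1, max_charge + 1):
            for idx in range(1, len(p)):
                mz = fragment_mz(light, series, idx, z)
                err = abs(mz - printed_q3)
                if err <= tol:
                    candidates.append(
                        (err, series_rank, z, FragmentIon(series, idx, z))
                    )
    if not candidates:
        return None
    candidates.sort(key=lambda c: (round(c[0], 9), c[1], c[2]))
    return candidates[0][3]


def build_assay_table(
    peptides: list[tuple[PeptideSpec, int, list[FragmentIon], int]],
) -> list[TransitionAssay]:
    """Build transition rows from chosen fragments.

    Each entry is (peptide, precursor charge, three fragment ions,
    quantifier position within that list). Emits exactly three rows per
    peptide with paired light/heavy Q1 and Q3; the heavy fragment shift
    applies only to fragments containing the labeled C-terminal residue
    (all y ions; never b ions of tryptic peptides).
    """
    rows: list[TransitionAssay] = []
    for p, z, fragments, quant_idx in peptides:
        if len(fragments) != 3:
            raise ValueError(
                f"{p.sequence}: an assay carries exactly 3 transitions, "
                f"got {len(fragments)}"
            )
        if len(set(fragments)) != len(fragments):
            raise ValueError(f"{p.sequence}: duplicate fragment rows")
        if not 0 <= quant_idx < 3:
            raise ValueError(f"{p.sequence}: quantifier index out of range")
        light, heavy = p.as_light(), p.as_heavy()
        for i, frag in enumerate(fragments):
            rows.append(
                TransitionAssay(
                    peptide=light,
                    precursor_charge=z,
                    fragment=frag,
                    q1_light=precursor_mz(light, z),
                    q3_light=fragment_mz(light, frag.series, frag.index, frag.charge),
                    q1_heavy=precursor_mz(heavy, z),
                    q3_heavy=fragment_mz(heavy, frag.series, frag.index, frag.charge),
                    is_quantifier=(i == quant_idx),
                )
            )
    return rows


def _tryptic_fragments(protein_seq: str) -> list[str]:
    """Fully tryptic peptides of a protein sequence (cleave after K/R,
    not before P)."""
    peps, start = [], 0
    for i, ch in enumerate(protein_seq):
        if ch in "KR" and (i + 1 == len(protein_seq) or protein_seq[i + 1] != "P"):
            peps.append(protein_seq[start : i + 1])
            start = i + 1
    if start < len(protein_seq):
        peps.append(protein_seq[start:])
    return peps


def screen_peptide(
    p: PeptideSpec,
    proteome: dict[str, str] | None = None,
    known_mod_sites: dict[str, list[int]] | None = None,
) -> ScreenReport:
    """Screen a surrogate peptide for uniqueness and modification risk.

    Uniqueness requires the sequence to occur as a tryptic peptide of
    exactly one proteome record. Methionines are flagged for oxidation
    risk; ``known_mod_sites`` maps peptide sequence to annotated modified
    positions (0-based within the peptide), e.g. phosphosites.
    """
    flags: list[tuple[int, str]] = []
    for i, ch in enumerate(p.sequence):
        if ch == "M":
            flags.append((i, "methionine oxidation risk"))
    if known_mod_sites:
        for pos in known_mod_sites.get(p.sequence, []):
            flags.append((pos, "annotated modification site"))

    unique: bool | None = None
    if proteome is not None:
        hits = sum(
            1
            for seq in proteome.values()
            if p.sequence in _tryptic_fragments(seq)
        )
        unique = hits == 1

    verdict = "warn" if (flags or unique is False) else "pass"
    return ScreenReport(p, unique, tuple(sorted(set(flags))), verdict)
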