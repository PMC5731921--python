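"""Peptide monoisotopic masses and SRM precursor/fragment m/z arithmetic.

The mass model is the one used throughout triple-quadrupole SRM work:
monoisotopic residue masses, water added once per peptide, a proton per
charge, fixed carbamidomethylation on cysteine (iodoacetamide alkylation,
+57.02146 Da), and stable-isotope labels on the C-terminal residue of
tryptic peptides (13C/15N lysine +8.014199 Da or arginine +10.008269 Da).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyteomics import mass as _ptmass

# monoisotopic residue masses for the 20 canonical amino acids
RESIDUE_MASS: dict[str, float] = {
    aa: _ptmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

WATER = 18.010565
PROTON = 1.007276

CARBAMIDOMETHYL = 57.02146
HEAVY_K = 8.014199   # 13C6 15N2 lysine
HEAVY_R = 10.008269  # 13C6 15N4 arginine

#: default fixed modifications: carbamidomethyl on every cysteine
DEFAULT_FIXED_MODS: frozenset[tuple[str, float]] = frozenset({("C", CARBAMIDOMETHYL)})


class InvalidPeptideError(ValueError):
    """Sequence contains a non-canonical residue or violates label rules."""


@dataclass(frozen=True)
class PeptideSpec:
    """A surrogate peptide with its fixed modifications and label state.

    Parameters
    ----------
    sequence : str
        Uppercase amino-acid string over the 20 canonical residues.
    fixed_mods : frozenset of (residue, mass shift in Da)
        Applied to every occurrence of the residue. Default:
        carbamidomethyl cysteine.
    heavy_label : bool
        If True the peptide carries a 13C/15N label on its C-terminal
        residue, which must be K or R (tryptic C-terminus).
    protein_name, accession : str
        Identity of the parent protein (optional bookkeeping).
    """

    sequence: str
    fixed_mods: frozenset[tuple[str, float]] = DEFAULT_FIXED_MODS
    heavy_label: bool = False
    protein_name: str = ""
    accession: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidPeptideError("empty peptide sequence")
        for ch in self.sequence:
            if ch not in RESIDUE_MASS:
                raise InvalidPeptideError(
                    f"non-canonical residue {ch!r} in {self.sequence!r}"
                )
        if self.heavy_label and self.sequence[-1] not in ("K", "R"):
            raise InvalidPeptideError(
                "heavy label requires a C-terminal K or R, got "
                f"{self.sequence[-1]!r} in {self.sequence!r}"
            )
        if not isinstance(self.fixed_mods, frozenset):
            object.__setattr__(self, "fixed_mods", frozenset(self.fixed_mods))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def heavy_shift(self) -> float:
        """Mass shift of the isotope label (0 for light peptides)."""
        if not self.heavy_label:
            return 0.0
        return HEAVY_K if self.sequence[-1] == "K" else HEAVY_R

    def as_heavy(self) -> "PeptideSpec":
        """The same peptide with the C-terminal heavy label applied."""
        return PeptideSpec(
            self.sequence, self.fixed_mods, True, self.protein_name, self.accession
        )

    def as_light(self) -> "PeptideSpec":
        return PeptideSpec(
            self.sequence, self.fixed_mods, False, self.protein_name, self.accession
        )

    def residue_mass(self, index: int) -> float:
        """Monoisotopic mass of residue ``index`` including its fixed mods
        and, for the C-terminal residue, the heavy label."""
        ch = self.sequence[index]
        m = RESIDUE_MASS[ch]
        for res, shift in self.fixed_mods:
            if res == ch:
                m += shift
        if self.heavy_label and index == len(self.sequence) - 1:
            m += self.heavy_shift
        return m


def peptide_neutral_mass(p: PeptideSpec) -> float:
    """Monoisotopic neutral mass in Da: residues + water + mods + label."""
    return sum(p.residue_mass(i) for i in range(len(p))) + WATER


def precursor_mz(p: PeptideSpec, z: int) -> float:
    """Precursor m/z at charge ``z``: (M + z·proton) / z."""
    if z < 1:
        raise ValueError(f"precursor charge must be >= 1, got {z}")
    return (peptide_neutral_mass(p) + z * PROTON) / z


def fragment_mz(p: PeptideSpec, series: str, index: int, z: int = 1) -> float:
    """b- or y-ion m/z.

    y_n covers the n C-terminal residues plus water; b_n the n N-terminal
    residues without water. Both gain one proton per charge.
    """
    n = len(p)
    if not 1 <= index <= n - 1:
        raise ValueError(
            f"fragment index {index} out of range for length-{n} peptide"
        )
    if z < 1:
        raise ValueError(f"fragment charge must be >= 1, got {z}")
    if series == "y":
        residues = range(n - index, n)
        neutral = sum(p.residue_mass(i) for i in residues) + WATER
    elif series == "b":
        residues = range(index)
        neutral = sum(p.residue_mass(i) for i in residues)
    else:
        raise ValueError(f"ion series must be 'b' or 'y', got {series!r}")
    return (neutral + z * PROTON) / z
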