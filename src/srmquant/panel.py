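"""The published urinary prostate-cancer SRM panel.

Twenty-two surrogate peptides covering 12 candidate secreted-protein
markers, with the printed transition list (Q1 and three Q3 values, one
decimal). Fragment identities and precursor charges are not printed; they
are recovered computationally by :func:`reference_assays`.

The two PSA surrogate peptides used as the prostate-secretion reference
are IVGGWEC(cam)EK and LSEPAELTDAVK.
"""

from __future__ import annotations

from .assay import FragmentIon, TransitionAssay, annotate_q3, match_precursor_charge
from .masses import PeptideSpec, fragment_mz, precursor_mz

PSA_PEPTIDE = "IVGGWECEK"        # carbamidomethyl-C; primary normalization reference
PSA_PEPTIDE_ALT = "LSEPAELTDAVK"

#: (protein, accession, peptide sequence, printed Q1, (printed Q3 x3))
PANEL: list[tuple[str, str, str, float, tuple[float, float, float]]] = [
    ("AGR2", "O95994", "LPQTLSR", 407.7, (604.3, 476.3, 351.2)),
    ("AGR3", "Q8TD06", "LYTYEPR", 471.2, (665.3, 272.2, 277.2)),
    ("CCL3", "P10147", "QVCADPSEEWVQK", 788.4, (1188.6, 1117.5, 1002.5)),
    ("CEAM5", "P06731", "INGIPQQHTQVLFIAK", 603.0, (847.5, 761.9, 705.4)),
    ("CEAM5", "P06731", "SDLVNEEATGQFR", 733.3, (1051.5, 937.4, 679.4)),
    ("CEAM5", "P06731", "CETQNPVSAR", 581.3, (872.5, 643.4, 529.3)),
    ("CEAM6", "P40199", "EVLLLAHNLPQNR", 506.3, (741.4, 514.3, 531.8)),
    ("CEAM6", "P40199", "SDPVTLNVLYGPDGPTISPSK", 1079.1, (1055.5, 998.5, 331.2)),
    ("CRISP3", "P54108", "WANQCNYR", 556.2, (925.4, 854.4, 612.3)),
    ("CRISP3", "P54108", "YEDLYSNCK", 596.3, (899.4, 784.4, 671.3)),
    ("CXL14", "O95715", "MVIITTK", 403.2, (674.4, 575.4, 462.3)),
    ("CXL14", "O95715", "WYNAWNEK", 555.8, (761.4, 647.3, 576.3)),
    ("IL24", "Q13007", "LWEAFWAVK", 575.3, (850.4, 721.4, 650.4)),
    ("MMP9", "P14780", "AVIDDAFAR", 489.3, (807.4, 694.3, 579.4)),
    ("MMP9", "P14780", "FQTFEGDLK", 542.8, (809.4, 708.4, 561.3)),
    ("MMP9", "P14780", "LGLGADVAQVTGALR", 720.9, (914.5, 815.5, 744.4)),
    ("MMP9", "P14780", "SLGPALLLLQK", 576.9, (952.6, 727.5, 614.4)),
    ("POSTN", "Q15063", "AAAITSDILEALGR", 700.9, (1074.6, 973.5, 771.5)),
    ("SFRP4", "Q6FHJ7", "GVCISPEAIVTDLPEDVK", 971.5, (1425.7, 916.5, 587.3)),
    ("CD90", "P04216", "VLYLSAFTSK", 564.8, (916.5, 753.4, 640.3)),
    ("CD90", "P04216", "VTSLTACLVDQSLR", 521.6, (830.5, 717.4, 618.3)),
    ("CD90", "P04216", "HVLFGTVGVPEHTYR", 571.3, (958.5, 802.4, 576.3)),
]

#: protein assignment for each panel peptide (used by concordance analysis)
PROTEIN_OF: dict[str, str] = {pep: prot for prot, _, pep, _, _ in PANEL}


def panel_peptides() -> list[PeptideSpec]:
    """The panel as light :class:`PeptideSpec` objects."""
    return [
        PeptideSpec(seq, protein_name=prot, accession=acc)
        for prot, acc, seq, _, _ in PANEL
    ]


def reference_assays(tol: float = 0.05) -> list[TransitionAssay]:
    """Reconstruct the full panel transition table from the printed values.

    For each peptide the precursor charge is the one in {2, 3} whose
    computed m/z falls within ``tol`` of the printed Q1, and each printed
    Q3 is assigned to its nearest b/y fragment. The first printed
    transition is taken as the quantifier. Unassignable Q3 values are
    skipped (the assay keeps its remaining transitions), mirroring how a
    printed table with no fragment annotation must be treated.
    """
    rows: list[TransitionAssay] = []
    for prot, acc, seq, q1, q3s in PANEL:
        p = PeptideSpec(seq, protein_name=prot, accession=acc)
        z = match_precursor_charge(p, q1, tol=tol)
        if z is None:
            raise ValueError(f"{seq}: printed Q1 {q1} matches no charge in {{2,3}}")
        heavy = p.as_heavy()
        for i, q3 in enumerate(q3s):
            frag = annotate_q3(p, q3, tol=tol)
            if frag is None:
                continue
            rows.append(
                TransitionAssay(
                    peptide=p,
                    precursor_charge=z,
                    fragment=frag,
                    q1_light=precursor_mz(p, z),
                    q3_light=fragment_mz(p, frag.series, frag.index, frag.charge),
                    q1_heavy=precursor_mz(heavy, z),
                    q3_heavy=fragment_mz(heavy, frag.series, frag.index, frag.charge),
                    is_quantifier=(i == 0),
                )
            )
    return rows
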