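"""Epitope peptide sequences, single-amino-acid-polymorphism (SAP) variants,
and mass / m-over-z arithmetic.

The objects here model short synthetic epitope peptides (e.g. the C-terminal
hcTn I epitope aa184-aa198) whose residues are numbered on the full antigen
sequence, together with the point substitutions that nonsynonymous SNPs
introduce.  Residue masses come from :mod:`pyteomics.mass`; the intact
antibody is carried as a single measured mass value, never as a sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd
from pyteomics import mass as _pmass

__all__ = [
    "MassTable",
    "PeptideVariant",
    "SapEdit",
    "MASS_TABLE",
    "PROTON_MASS",
    "WATER_MASS",
    "monoisotopic_mass",
    "average_mass",
    "mz",
    "apply_sap",
    "mass_report",
    "read_peptides_csv",
    "read_peptides_fasta",
]

#: Mass of a proton (Da), used for [M + zH]z+ arithmetic.
PROTON_MASS = 1.007276

#: Monoisotopic mass of one water molecule (Da); the condensation loss per
#: peptide bond, added back once per chain.
WATER_MASS = 18.010565

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"

_SAP_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def _average_residue_masses() -> dict:
    return {
        aa: _pmass.calculate_mass(composition=_pmass.std_aa_comp[aa], average=True)
        for aa in CANONICAL
    }


@dataclass(frozen=True)
class MassTable:
    """Residue masses (Da): monoisotopic and average, plus water and proton."""

    monoisotopic: dict
    average: dict
    water: float = WATER_MASS
    proton: float = PROTON_MASS

    def __post_init__(self):
        for aa in self.monoisotopic:
            mono, avg = self.monoisotopic[aa], self.average[aa]
            if mono <= 0 or avg <= 0:
                raise ValueError(f"non-positive mass for residue {aa!r}")
            if mono >= avg:
                raise ValueError(f"monoisotopic >= average for residue {aa!r}")

    @classmethod
    def standard(cls) -> "MassTable":
        mono = {aa: _pmass.std_aa_mass[aa] for aa in CANONICAL}
        return cls(monoisotopic=mono, average=_average_residue_masses())


#: The standard residue-mass table used throughout the package.
MASS_TABLE = MassTable.standard()


@dataclass(frozen=True)
class SapEdit:
    """One amino-acid exchange, in ``X<n>Y`` notation (antigen numbering)."""

    original: str
    position: int  # residue number on the antigen sequence (1-based)
    replacement: str

    @classmethod
    def parse(cls, text: str) -> "SapEdit":
        m = _SAP_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse SAP notation {text!r} (expected e.g. 'R192Q')")
        return cls(m.group(1), int(m.group(2)), m.group(3))

    def __str__(self) -> str:
        return f"{self.original}{self.position}{self.replacement}"


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty peptide sequence")
    for i, ch in enumerate(sequence):
        if ch not in CANONICAL:
            raise ValueError(
                f"non-canonical residue {ch!r} at sequence position {i + 1}"
            )


@dataclass(frozen=True)
class PeptideVariant:
    """A peptide anchored on antigen residue numbers, with optional SAP edits.

    ``start_residue`` is the antigen residue number of the first sequence
    position (1-based, e.g. 184 for the hcTn I aa184-aa198 epitope), so the
    local index of antigen position ``n`` is ``n - start_residue``.  When the
    wild-type reference is stored, applying ``saps`` to it must reproduce
    ``sequence`` exactly.
    """

    sequence: str
    start_residue: int = 1
    saps: tuple = ()
    label: str = ""
    wildtype: str | None = None

    def __post_init__(self):
        _check_sequence(self.sequence)
        last = self.start_residue + len(self.sequence) - 1
        for sap in self.saps:
            if not (self.start_residue <= sap.position <= last):
                raise ValueError(
                    f"SAP {sap} outside residue range "
                    f"[{self.start_residue}, {last}]"
                )
        if self.wildtype is not None:
            rebuilt = list(self.wildtype)
            for sap in self.saps:
                i = sap.position - self.start_residue
                if rebuilt[i] != sap.original:
                    raise ValueError(
                        f"SAP {sap}: wild-type has {rebuilt[i]!r} at position "
                        f"{sap.position}, expected {sap.original!r}"
                    )
                rebuilt[i] = sap.replacement
            if "".join(rebuilt) != self.sequence:
                raise ValueError(
                    "stored SAP edits do not reproduce the variant sequence "
                    "from the wild-type reference"
                )

    def residue_at(self, position: int) -> str:
        i = position - self.start_residue
        if not (0 <= i < len(self.sequence)):
            raise ValueError(f"residue number {position} outside peptide")
        return self.sequence[i]


def monoisotopic_mass(peptide: "PeptideVariant | str",
                      table: MassTable = MASS_TABLE) -> float:
    """Monoisotopic mass (Da) of the neutral peptide: residue sum + water."""
    seq = peptide.sequence if isinstance(peptide, PeptideVariant) else peptide
    _check_sequence(seq)
    return sum(table.monoisotopic[aa] for aa in seq) + table.water


def average_mass(peptide: "PeptideVariant | str",
                 table: MassTable = MASS_TABLE) -> float:
    """Average (chemical) mass (Da) of the neutral peptide."""
    seq = peptide.sequence if isinstance(peptide, PeptideVariant) else peptide
    _check_sequence(seq)
    # average water: 2 H + O at average atomic weights
    water_avg = _pmass.calculate_mass(formula="H2O", average=True)
    return sum(table.average[aa] for aa in seq) + water_avg


def mz(mass_da: float, z: int, proton: float = PROTON_MASS) -> float:
    """m/z (Th) of the z-fold protonated ion ``[M + zH]z+``."""
    if z < 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return (mass_da + z * proton) / z


def apply_sap(wildtype: PeptideVariant, edits) -> PeptideVariant:
    """Apply one or more ``X<n>Y`` exchanges to a wild-type peptide.

    ``edits`` is a single notation string / :class:`SapEdit` or a sequence of
    them (applied left to right, e.g. ``["R192P", "K193E"]``).  Each edit is
    checked against the residue actually present at its position.
    """
    if isinstance(edits, (str, SapEdit)):
        edits = [edits]
    seq = list(wildtype.sequence)
    applied = list(wildtype.saps)
    for edit in edits:
        sap = SapEdit.parse(edit) if isinstance(edit, str) else edit
        i = sap.position - wildtype.start_residue
        if not (0 <= i < len(seq)):
            raise ValueError(f"SAP {sap} outside residue range of the peptide")
        if seq[i] != sap.original:
            raise ValueError(
                f"SAP {sap}: expected {sap.original!r} at position "
                f"{sap.position}, found {seq[i]!r}"
            )
        seq[i] = sap.replacement
        applied.append(sap)
    label = "+".join(str(s) for s in applied)
    return PeptideVariant(
        sequence="".join(seq),
        start_residue=wildtype.start_residue,
        saps=tuple(applied),
        label=label,
        wildtype=wildtype.wildtype or wildtype.sequence,
    )


def mass_report(peptides, charges, table: MassTable = MASS_TABLE) -> pd.DataFrame:
    """Per-peptide mass table: label, sequence, saps, mono mass, calc m/z.

    ``charges`` is one integer applied to all peptides or a list matched
    positionally.  Masses are reported to 3 dp and m/z to 2 dp.
    """
    if isinstance(charges, int):
        charges = [charges] * len(peptides)
    rows = []
    for p, z in zip(peptides, charges):
        m = monoisotopic_mass(p, table)
        rows.append({
            "label": p.label or p.sequence,
            "sequence": p.sequence,
            "saps": "+".join(str(s) for s in p.saps),
            "mono_mass": round(m, 3),
            "charge": z,
            "calc_mz": round(mz(m, z, table.proton), 2),
        })
    return pd.DataFrame(rows)


def read_peptides_csv(path) -> list:
    """Read peptides from CSV with columns label, sequence, start, saps.

    ``saps`` is a ``+``-separated list of ``X<n>Y`` notations (may be empty).
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        saps = tuple(
            SapEdit.parse(s) for s in str(row.get("saps", "")).split("+") if s
        )
        out.append(PeptideVariant(
            sequence=row["sequence"].strip(),
            start_residue=int(row.get("start", 1) or 1),
            saps=saps,
            label=str(row.get("label", "")).strip(),
        ))
    return out


def read_peptides_fasta(path) -> list:
    """Read peptides from FASTA; headers carry ``label|start=<n>``."""
    out = []
    header, chunks = None, []
    def flush():
        if header is None:
            return
        parts = header.split("|")
        label = parts[0].strip()
        start = 1
        for p in parts[1:]:
            if p.strip().startswith("start="):
                start = int(p.strip()[len("start="):])
        out.append(PeptideVariant(sequence="".join(chunks), start_residue=start,
                                  label=label))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header, chunks = line[1:], []
            else:
                chunks.append(line)
        flush()
    return out
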