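"""PDB-format structure I/O and coordinate-segment extraction.

Parsing is delegated to :mod:`gemmi`; on top of its object model this
module applies the policies the pipeline needs: model 1 only, hydrogens
ignored, one alternate location per atom (highest occupancy, ties broken
toward altloc "A" then first-seen), residues ordered by (chain, residue
number, insertion code).

A *segment* is the ordered coordinate block for a residue range under a
declared atom selection — by default N, CA, C, CB, the backbone plus the
first side-chain carbon, which pins down side-chain orientation.  Glycine
has no CB; it contributes three atoms and the exception is recorded rather
than treated as missing data.

The "complete structural information" rule: an instance is scoreable only
when every residue in its range has experimentally determined coordinates
for at least the CA atom, and preferably for all non-hydrogen backbone and
side-chain atoms.  :class:`CompletenessPolicy` encodes both sets.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import (
    EmptyStructureError,
    ExtractionError,
    PDBFormatError,
    StructureLookupError,
)

logger = logging.getLogger(__name__)

#: Default atom selection for minimotif comparison (Gly contributes 3).
DEFAULT_SELECTION = ("N", "CA", "C", "CB")

#: 3-letter -> 1-letter residue codes, with common modified residues mapped
#: to their parent amino acid (phosphotyrosine PTR -> Y, phosphoserine
#: SEP -> S, phosphothreonine TPO -> T, selenomethionine MSE -> M, ...).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified residues -> parent
    "PTR": "Y", "SEP": "S", "TPO": "T", "MSE": "M", "CSO": "C",
    "HYP": "P", "MLY": "K", "M3L": "K", "KCX": "K", "PCA": "Q",
}

ONE_TO_THREE = {v: k for k, v in list(THREE_TO_ONE.items())[:20]}


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    het: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.insertion_code)


@dataclass
class Residue:
    chain: str
    number: int
    insertion_code: str
    name: str
    atoms: dict = field(default_factory=dict)  # atom_name -> AtomRecord

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    @property
    def is_glycine(self) -> bool:
        return self.name == "GLY"


@dataclass
class StructureModel:
    """Atoms of model 1 of a structure, after altloc/hydrogen filtering."""

    structure_id: str
    atoms: list  # ordered list of AtomRecord

    def __post_init__(self):
        self._residues: dict[str, list[Residue]] = {}
        current: Residue | None = None
        for atom in self.atoms:
            if (current is None or current.chain != atom.chain
                    or current.number != atom.residue_number
                    or current.insertion_code != atom.insertion_code):
                current = Residue(atom.chain, atom.residue_number,
                                  atom.insertion_code, atom.residue_name)
                self._residues.setdefault(atom.chain, []).append(current)
            current.atoms[atom.atom_name] = atom
        for chain in self._residues:
            self._residues[chain].sort(
                key=lambda r: (r.number, r.insertion_code))

    @property
    def chains(self) -> list[str]:
        return list(self._residues)

    def residues(self, chain: str) -> list[Residue]:
        if chain not in self._residues:
            raise StructureLookupError(
                f"chain {chain!r} not in structure {self.structure_id}")
        return self._residues[chain]

    def sequence(self, chain: str) -> str:
        """One-letter sequence of a chain (modified residues mapped to
        parents, unknowns as X)."""
        return "".join(r.one_letter for r in self.residues(chain))

    def residue_range(self, chain: str, start: int, end: int) -> list[Residue]:
        """Residues with start <= number <= end, in order.  Raises if any
        number in the range is absent from the chain."""
        by_number: dict[int, list[Residue]] = {}
        for r in self.residues(chain):
            by_number.setdefault(r.number, []).append(r)
        out: list[Residue] = []
        for num in range(start, end + 1):
            if num not in by_number:
                raise StructureLookupError(
                    f"residue {num} not present in chain {chain} of "
                    f"{self.structure_id}")
            out.extend(by_number[num])
        return out


@dataclass(frozen=True)
class SegmentCoordinates:
    """Ordered coordinates for a residue range under an atom selection.

    ``exceptions`` records residue indices (0-based within the segment)
    where a declared atom was legitimately absent (glycine CB); any other
    absence is an extraction error, never a silent drop.
    """

    source: tuple  # (structure_id, chain, start, end)
    atom_selection: tuple[str, ...]
    coordinates: np.ndarray  # (n_atoms, 3) float
    residue_sequence: str
    exceptions: tuple[int, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "coordinates",
                           np.asarray(self.coordinates, dtype=float))
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n, 3) array")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)

    @property
    def n_residues(self) -> int:
        return len(self.residue_sequence)

    @property
    def gly_positions(self) -> tuple[int, ...]:
        return self.exceptions


@dataclass(frozen=True)
class CompletenessPolicy:
    """Minimal atoms required for scoreability; preferred atoms reported."""

    minimal_atoms: frozenset = frozenset({"CA"})
    preferred_atoms: frozenset = frozenset({"N", "CA", "C", "O", "CB"})

    def __post_init__(self):
        if not self.minimal_atoms <= self.preferred_atoms:
            raise ValueError("minimal_atoms must be a subset of preferred_atoms")


DEFAULT_POLICY = CompletenessPolicy()


@dataclass
class CompletenessReport:
    complete: bool
    missing_minimal: list  # (residue_key, atom_name)
    missing_preferred: list
    gly_exceptions: list  # residue_keys where CB absence was excused

    def __bool__(self) -> bool:
        return self.complete


def _prefilter_pdb_lines(text: str) -> str:
    """Drop malformed ATOM/HETATM lines (warn + log) before gemmi parses."""
    kept = []
    for lineno, line in enumerate(text.splitlines(), 1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            ok = len(line) >= 54
            if ok:
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError:
                    ok = False
            if not ok:
                warnings.warn(f"skipping malformed PDB line {lineno}: "
                              f"{line[:30]!r}...", stacklevel=3)
                logger.warning("skipped malformed PDB line %d", lineno)
                continue
        kept.append(line)
    return "\n".join(kept) + "\n"


def read_pdb(text: str, structure_id: str = "") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Model 1 only; hydrogens and waters ignored; one altloc per atom
    retained (highest occupancy; ties -> "A" or first seen).  Malformed
    fixed-width ATOM/HETATM lines are skipped with a warning.

    Raises :class:`EmptyStructureError` when no atoms survive.
    """
    st = gemmi.read_pdb_string(_prefilter_pdb_lines(text))
    if not structure_id:
        structure_id = st.name.strip() or "UNKNOWN"
    if len(st) == 0:
        raise EmptyStructureError("no ATOM/HETATM records")
    model = st[0]
    if len(st) > 1:
        logger.info("structure %s has %d models; using model 1 only",
                    structure_id, len(st))
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            if residue.name == "HOH":
                continue
            # altloc selection per atom name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            for name, variants in by_name.items():
                chosen = max(
                    variants,
                    key=lambda a: (a.occ, a.altloc == "A", -variants.index(a)),
                )
                atoms.append(AtomRecord(
                    chain=chain.name,
                    residue_number=residue.seqid.num,
                    insertion_code=(residue.seqid.icode or " ").strip(),
                    residue_name=residue.name,
                    atom_name=name,
                    position=(chosen.pos.x, chosen.pos.y, chosen.pos.z),
                    occupancy=chosen.occ,
                    altloc=chosen.altloc.replace("\x00", "").strip(),
                    het=residue.het_flag == "H",
                ))
    if not atoms:
        raise EmptyStructureError("no ATOM/HETATM records")
    atoms.sort(key=lambda a: (a.chain, a.residue_number, a.insertion_code))
    return StructureModel(structure_id=structure_id, atoms=atoms)


def check_completeness(model: StructureModel, chain: str, start: int,
                       end: int,
                       policy: CompletenessPolicy = DEFAULT_POLICY,
                       ) -> CompletenessReport:
    """Apply the complete-structural-information rule to a residue range.

    Complete iff every residue in [start, end] has all ``minimal_atoms``.
    Residues missing ``preferred_atoms`` are reported; a glycine missing CB
    is excused and recorded as an exception, not a deficiency.
    """
    residues = model.residue_range(chain, start, end)
    missing_min, missing_pref, gly_exc = [], [], []
    for res in residues:
        for name in sorted(policy.minimal_atoms):
            if name not in res.atoms:
                missing_min.append((res.chain, res.number, name))
        for name in sorted(policy.preferred_atoms - policy.minimal_atoms):
            if name in res.atoms:
                continue
            if name == "CB" and res.is_glycine:
                gly_exc.append((res.chain, res.number))
            else:
                missing_pref.append((res.chain, res.number, name))
    return CompletenessReport(
        complete=not missing_min,
        missing_minimal=missing_min,
        missing_preferred=missing_pref,
        gly_exceptions=gly_exc,
    )


def extract_segment(model: StructureModel, chain: str, start: int, end: int,
                    atom_selection: tuple = DEFAULT_SELECTION,
                    ) -> SegmentCoordinates:
    """Extract ordered coordinates for a residue range.

    Order is deterministic: residue order, then the declared atom-name
    order.  A glycine lacking CB contributes 3 atoms and is recorded in
    ``exceptions``; any other missing selected atom raises
    :class:`ExtractionError` naming the residue and atom.
    """
    residues = model.residue_range(chain, start, end)
    coords, exceptions = [], []
    seq = []
    for idx, res in enumerate(residues):
        seq.append(res.one_letter)
        for name in atom_selection:
            if name in res.atoms:
                coords.append(res.atoms[name].position)
            elif name == "CB" and res.is_glycine:
                exceptions.append(idx)
            else:
                raise ExtractionError(
                    f"residue {res.name} {chain}{res.number} of "
                    f"{model.structure_id} is missing selected atom {name}")
    return SegmentCoordinates(
        source=(model.structure_id, chain, start, end),
        atom_selection=tuple(atom_selection),
        coordinates=np.array(coords, dtype=float),
        residue_sequence="".join(seq),
        exceptions=tuple(exceptions),
    )


def _fmt_coord(x: float) -> str:
    s = f"{x:8.3f}"
    if len(s) > 8:
        raise PDBFormatError(f"coordinate {x} out of PDB numeric range")
    return s


def write_pdb(model: StructureModel) -> str:
    """Serialize to fixed-column PDB text (ATOM/HETATM, TER per chain, END).

    ``read_pdb(write_pdb(m))`` is the identity on retained fields.
    """
    lines = []
    serial = 0
    last_chain = None
    for atom in model.atoms:
        if len(atom.chain) > 1:
            raise PDBFormatError(
                f"chain id {atom.chain!r} does not fit the 1-character "
                "PDB chain column")
        if last_chain is not None and atom.chain != last_chain:
            lines.append("TER")
        last_chain = atom.chain
        serial += 1
        record = "HETATM" if atom.het else "ATOM  "
        name = atom.atom_name
        # standard PDB atom-name justification
        name_field = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = atom.position
        lines.append(
            f"{record}{serial:5d} {name_field}{atom.altloc or ' ':1s}"
            f"{atom.residue_name:>3s} {atom.chain:1s}"
            f"{atom.residue_number:4d}{atom.insertion_code or ' ':1s}   "
            f"{_fmt_coord(x)}{_fmt_coord(y)}{_fmt_coord(z)}"
            f"{atom.occupancy:6.2f}{0.0:6.2f}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def segment_to_model(segment: SegmentCoordinates,
                     structure_id: str | None = None) -> StructureModel:
    """Rebuild a minimal StructureModel from a segment (for writing)."""
    sid, chain, start, _end = segment.source
    atoms = []
    i = 0
    for ridx, aa in enumerate(segment.residue_sequence):
        resname = ONE_TO_THREE.get(aa, "UNK")
        for name in segment.atom_selection:
            if name == "CB" and ridx in segment.exceptions:
                continue
            atoms.append(AtomRecord(
                chain=chain or "A",
                residue_number=(start or 1) + ridx,
                insertion_code="",
                residue_name=resname,
                atom_name=name,
                position=tuple(segment.coordinates[i]),
            ))
            i += 1
    return StructureModel(structure_id=structure_id or sid, atoms=atoms)


# ---------------------------------------------------------------------------
# Instance index: the file-based stand-in for the original database tables.
# Tab-separated columns: structure_id, chain, start, end, sequence.

def write_instance_index(rows, path) -> None:
    import pandas as pd
    df = pd.DataFrame(rows, columns=["structure_id", "chain", "start",
                                     "end", "sequence"])
    df.to_csv(path, sep="\t", index=False)


def read_instance_index(path):
    import pandas as pd
    return pd.read_csv(path, sep="\t")
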