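"""Structure model and domain-hit I/O.

Models are single-chain predicted structures in PDB format with per-residue
confidence (pLDDT, 0-100) stored in the B-factor column, AlphaFold style.
Long proteins may be split into several overlapping fragment files; the
:class:`FragmentSet` records that layout. Domain hits come in a columnar
whitespace-separated table (query id, family id, score, segment string),
the format emitted by HMM-scan resolution tools.

All residue numbering is 1-based and intervals are closed ``[start, stop]``,
matching UniProt numbering and ``UniProt_ID/start-stop`` domain identifiers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "ResidueRecord",
    "StructureModel",
    "FragmentSet",
    "DomainHit",
    "HIT_SOURCES",
    "ModelParseError",
    "parse_model",
    "sequence_md5",
    "load_hits",
    "write_model",
    "write_domain",
    "parse_segments",
    "format_segments",
    "region_filename_stem",
]

#: Hit source categories: experimentally classified, HMM-matched to a
#: classified superfamily, structurally uncharacterised Pfam family, or a
#: domain-sized region matching neither ("NewFam").
HIT_SOURCES = ("CATH-PDB", "CATH-HMM", "Pfam", "NewFam")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class ModelParseError(ValueError):
    """Raised when a PDB model violates the single-chain predicted-model contract."""


@dataclass
class ResidueRecord:
    """One residue: UniProt-numbered index, amino acid, heavy atoms, confidence.

    ``atoms`` maps atom names (N, CA, C, O required; side-chain heavy atoms
    optional) to 3-vectors in Angstrom. ``plddt`` is the per-residue model
    confidence in [0, 100], read from the CA atom's B-factor.
    """

    seq_index: int
    aa: str
    atoms: dict[str, np.ndarray]
    plddt: float

    def __post_init__(self) -> None:
        if "CA" not in self.atoms:
            raise ValueError(f"residue {self.seq_index}: CA atom required")
        if not (0.0 <= self.plddt <= 100.0):
            raise ValueError(
                f"residue {self.seq_index}: pLDDT {self.plddt} outside [0, 100]"
            )
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResidueRecord):
            return NotImplemented
        return (
            self.seq_index == other.seq_index
            and self.aa == other.aa
            and abs(self.plddt - other.plddt) < 1e-4
            and set(self.atoms) == set(other.atoms)
            and all(np.allclose(self.atoms[k], other.atoms[k], atol=1e-3)
                    for k in self.atoms)
        )


@dataclass
class StructureModel:
    """An ordered single-chain structure with provenance.

    ``fragment_index`` is >= 1; whole (unfragmented) proteins use 1.
    """

    protein_id: str
    residues: list[ResidueRecord]
    fragment_index: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("model must contain at least one residue")
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue seq_index must be strictly increasing")

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def sequence_md5(self) -> str:
        return sequence_md5(self.sequence)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def seq_indices(self) -> list[int]:
        return [r.seq_index for r in self.residues]

    @property
    def plddt(self) -> np.ndarray:
        return np.array([r.plddt for r in self.residues], dtype=float)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    def heavy_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """All heavy-atom coordinates and the residue (list) index of each."""
        coords, owner = [], []
        for i, res in enumerate(self.residues):
            for xyz in res.atoms.values():
                coords.append(xyz)
                owner.append(i)
        return np.asarray(coords, dtype=float), np.asarray(owner, dtype=int)

    def residue_by_index(self, seq_index: int) -> ResidueRecord:
        for r in self.residues:
            if r.seq_index == seq_index:
                return r
        raise KeyError(seq_index)

    def subset(self, seq_indices: Iterable[int]) -> "StructureModel":
        wanted = set(seq_indices)
        present = {r.seq_index for r in self.residues}
        missing = sorted(wanted - present)
        if missing:
            raise KeyError(f"residues absent from model: {missing}")
        return StructureModel(
            protein_id=self.protein_id,
            fragment_index=self.fragment_index,
            residues=[r for r in self.residues if r.seq_index in wanted],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureModel):
            return NotImplemented
        return (
            self.protein_id == other.protein_id
            and self.fragment_index == other.fragment_index
            and self.residues == other.residues
        )


@dataclass
class FragmentSet:
    """Fragment layout of one protein under the sliding-window scheme.

    Long proteins are predicted as overlapping windows of
    ``fragment_length`` residues whose starts step by ``step`` residues, so
    consecutive fragments overlap by ``fragment_length - step``.
    """

    protein_id: str
    fragments: list[tuple[int, int, int]]  # (fragment_index, first, last)
    fragment_length: int = 1400
    step: int = 200

    @classmethod
    def for_length(cls, protein_id: str, length: int,
                   fragment_length: int = 1400, step: int = 200) -> "FragmentSet":
        """Fragment layout covering residues 1..length.

        A protein no longer than one window yields a single fragment.
        Otherwise windows start at 1, 1+step, ... while they fit, and a final
        window is pinned to the C-terminus so every residue is covered.
        """
        if length <= fragment_length:
            return cls(protein_id, [(1, 1, length)], fragment_length, step)
        starts = list(range(1, length - fragment_length + 1, step))
        if starts[-1] + fragment_length - 1 < length:
            starts.append(length - fragment_length + 1)
        frags = [(i + 1, s, s + fragment_length - 1) for i, s in enumerate(starts)]
        return cls(protein_id, frags, fragment_length, step)

    def range_of(self, fragment_index: int) -> tuple[int, int]:
        for idx, first, last in self.fragments:
            if idx == fragment_index:
                return first, last
        raise KeyError(fragment_index)


@dataclass
class DomainHit:
    """One candidate domain region on a protein.

    ``segments`` is a sorted list of disjoint closed intervals; discontinuous
    domains have several. ``score`` is an HMM bitscore or equivalent.
    """

    protein_id: str
    source: str
    family_id: str
    segments: list[tuple[int, int]]
    score: float

    def __post_init__(self) -> None:
        if self.source not in HIT_SOURCES:
            raise ValueError(f"unknown hit source {self.source!r}")
        _validate_segments(self.segments)

    @property
    def n_residues(self) -> int:
        return sum(b - a + 1 for a, b in self.segments)

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def stop(self) -> int:
        return self.segments[-1][1]

    def residue_set(self) -> frozenset[int]:
        return frozenset(i for a, b in self.segments for i in range(a, b + 1))


def _validate_segments(segments: Sequence[tuple[int, int]]) -> None:
    if not segments:
        raise ValueError("at least one segment required")
    for a, b in segments:
        if a > b:
            raise ValueError(f"segment start {a} > stop {b}")
        if a < 1:
            raise ValueError(f"segment start {a} < 1")
    for (_, b1), (a2, _) in zip(segments, segments[1:]):
        if a2 <= b1:
            raise ValueError("segments overlap or are unsorted")


def sequence_md5(sequence: str) -> str:
    """MD5 digest of a one-letter amino-acid sequence, as 32 hex chars.

    Used to track identical sequences across naming schemes (model files,
    reference proteomes, pre-existing annotations).
    """
    if not sequence:
        raise ValueError("empty sequence")
    return hashlib.md5(sequence.encode("ascii")).hexdigest()


def parse_segments(text: str) -> list[tuple[int, int]]:
    """Parse a segment string like ``"5-60,80-140"`` into closed intervals."""
    segments = []
    for part in text.split(","):
        a, sep, b = part.partition("-")
        if not sep:
            raise ValueError(f"malformed segment {part!r}")
        segments.append((int(a), int(b)))
    _validate_segments(segments)
    return segments


def format_segments(segments: Sequence[tuple[int, int]]) -> str:
    return ",".join(f"{a}-{b}" for a, b in segments)


def region_filename_stem(protein_id: str, segments: Sequence[tuple[int, int]],
                         sep: str = "_") -> str:
    """Filesystem-safe stem for a ``UniProt_ID/start-stop`` domain identifier.

    The ``/`` of the canonical identifier is replaced by ``sep``; segments of
    a discontinuous domain are joined by ``sep`` as well (a convention choice:
    ``P12345_10-110_150-200``).
    """
    return protein_id + sep + sep.join(f"{a}-{b}" for a, b in segments)


# -- PDB parsing -----------------------------------------------------------

def parse_model(path: str | Path, protein_id: str | None = None,
                fragment_index: int = 1) -> StructureModel:
    """Read a single-chain predicted model from a PDB file.

    All non-ATOM records (HETATM, TER, REMARK, ...) are ignored. pLDDT is
    taken from each residue's CA B-factor. Multi-chain files, alternate
    locations and insertion codes are rejected: they do not occur in
    predicted monomer models and silently accepting them risks mis-numbering.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ModelParseError(f"{path.name}: no model records")
    model = st[0]
    chains = [ch for ch in model if any(r.het_flag == "A" for r in ch)]
    if not chains:
        raise ModelParseError(f"{path.name}: no ATOM records")
    if len(chains) > 1:
        names = ",".join(ch.name for ch in chains)
        raise ModelParseError(f"{path.name}: multiple chains ({names}); "
                              "only single-chain models are supported")
    residues: list[ResidueRecord] = []
    for res in chains[0]:
        if res.het_flag != "A":
            continue  # HETATM
        if res.seqid.icode not in (" ", "\x00", ""):
            raise ModelParseError(
                f"{path.name}: insertion code at residue {res.seqid.num}")
        atoms: dict[str, np.ndarray] = {}
        plddt = None
        for atom in res:
            if atom.altloc not in ("", "\x00", " "):
                raise ModelParseError(
                    f"{path.name}: alternate location at residue {res.seqid.num}")
            if atom.element == gemmi.Element("H"):
                continue
            atoms[atom.name] = np.array(
                [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
            if atom.name == "CA":
                plddt = atom.b_iso
        if "CA" not in atoms:
            raise ModelParseError(
                f"{path.name}: residue {res.seqid.num} ({res.name}) lacks a CA atom")
        aa = _THREE_TO_ONE.get(res.name, "X")
        try:
            residues.append(ResidueRecord(res.seqid.num, aa, atoms, float(plddt)))
        except ValueError as exc:
            raise ModelParseError(f"{path.name}: {exc}") from exc
    if protein_id is None:
        protein_id = path.stem
    try:
        return StructureModel(protein_id, residues, fragment_index)
    except ValueError as exc:
        raise ModelParseError(f"{path.name}: {exc}") from exc


# -- PDB writing -----------------------------------------------------------

def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.protein_id
    gm = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for res in model.residues:
        gr = gemmi.Residue()
        gr.name = _ONE_TO_THREE.get(res.aa, "UNK")
        gr.seqid = gemmi.SeqId(res.seq_index, " ")
        gr.het_flag = "A"
        for name, xyz in res.atoms.items():
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[:1])
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.b_iso = res.plddt
            gr.add_atom(atom)
        chain.add_residue(gr)
    gm.add_chain(chain)
    st.add_model(gm)
    return st


def write_model(model: StructureModel, path: str | Path,
                metadata: Mapping[str, str] | None = None) -> Path:
    """Write a model as PDB, with metadata as ``REMARK 999 KEY value`` lines."""
    path = Path(path)
    st = _to_gemmi(model)
    opts = gemmi.PdbWriteOptions(minimal=True, numbered_ter=False)
    body = st.make_pdb_string(opts)
    lines = []
    for key, value in (metadata or {}).items():
        lines.append(f"REMARK 999 {key.upper()} {value}")
    lines.extend(l for l in body.splitlines() if l.startswith("ATOM"))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_domain(model: StructureModel, region, path: str | Path | None = None,
                 out_dir: str | Path | None = None,
                 metadata: Mapping[str, str] | None = None) -> Path:
    """Chop ``region`` out of ``model`` and write it as an annotated PDB file.

    The header carries the domain sequence MD5, the source file/model it was
    chopped from, and the candidate family label when one exists. Original
    residue numbering is preserved. ``region`` needs ``segments`` and may
    carry ``source``/``candidate_superfamily`` attributes (see
    :class:`foldassign.resolution.DomainRegion`).
    """
    wanted = [i for a, b in region.segments for i in range(a, b + 1)]
    sub = model.subset(wanted)  # raises KeyError listing missing indices
    meta = {
        "DOMAIN_MD5": sub.sequence_md5,
        "SOURCE_FILE": f"{model.protein_id}_F{model.fragment_index}",
        "SEGMENTS": format_segments(region.segments),
    }
    label = getattr(region, "candidate_superfamily", "") or getattr(
        region, "family_id", "")
    if label:
        meta["FAMILY"] = label
    source = getattr(region, "source", "")
    if source:
        meta["HIT_SOURCE"] = source
    if metadata:
        meta.update({k.upper(): str(v) for k, v in metadata.items()})
    if path is None:
        stem = region_filename_stem(model.protein_id, region.segments)
        path = Path(out_dir or ".") / f"{stem}.pdb"
    return write_model(sub, path, meta)


# -- hit tables ------------------------------------------------------------

def _infer_source(family_id: str) -> str:
    """Source category from a family identifier's shape.

    CATH superfamily codes look like ``3.40.50.620``; Pfam accessions like
    ``PF00042``; anything else (or empty) is a NewFam domain-sized region.
    """
    if not family_id or family_id == "-":
        return "NewFam"
    if family_id.upper().startswith("PF"):
        return "Pfam"
    parts = family_id.split(".")
    if len(parts) == 4 and all(p.isdigit() for p in parts):
        return "CATH-HMM"
    return "NewFam"


def load_hits(path: str | Path) -> list[DomainHit]:
    """Load a whitespace-separated hit table.

    Columns: query id, family id (``-`` for none), score, segment string,
    optionally an explicit source category. Malformed rows are rejected with
    their row number.
    """
    hits: list[DomainHit] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ValueError(f"row {lineno}: expected >=4 columns, got {len(fields)}")
        qid, family, score_s, segs_s = fields[:4]
        source = fields[4] if len(fields) > 4 else _infer_source(family)
        try:
            score = float(score_s)
            segments = parse_segments(segs_s)
            hits.append(DomainHit(qid, source, "" if family == "-" else family,
                                  segments, score))
        except ValueError as exc:
            raise ValueError(f"row {lineno}: {exc}") from exc
    return hits


def write_hits(hits: Iterable[DomainHit], path: str | Path) -> Path:
    path = Path(path)
    lines = ["# query_id\tfamily_id\tscore\tsegments\tsource"]
    for h in hits:
        lines.append("\t".join([
            h.protein_id, h.family_id or "-", f"{h.score:g}",
            format_segments(h.segments), h.source,
        ]))
    path.write_text("\n".join(lines) + "\n")
    return path
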