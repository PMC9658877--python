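"""Multi-chain structure I/O: fixed-column PDB, mmCIF, selections, confidence.

Atomic models are kept in a plain nested container (chains -> residues ->
atoms) with author residue numbering treated as authoritative.  Per-residue
prediction confidence (pLDDT, 0-100) travels in the B-factor column, the
convention used by structure-prediction pipelines.  Internal flat indices are
0-based over the concatenated chain order, the same convention the PAE matrix
uses, so a single segmentation object links coordinates and confidence data.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import (
    DomainMapError,
    EmptyInputError,
    EmptySelectionError,
    StructureParseError,
)

DOMAIN_NAMES = ("BTB", "hinge", "CTD", "other")


@dataclass
class AtomRecord:
    """One atom line of a structure file.

    ``bfactor`` holds pLDDT (0-100) when the file is a predicted model.
    """

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("position must be a finite 3-vector")
        if not self.chain_id:
            raise ValueError("chain_id must be nonempty")

    def copy(self) -> "AtomRecord":
        return replace(self, position=self.position.copy())


@dataclass
class Residue:
    name: str
    number: int
    insertion_code: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def ca(self) -> AtomRecord | None:
        for atom in self.atoms:
            if atom.atom_name == "CA":
                return atom
        return None

    def plddt(self) -> float:
        """B-factor of the Calpha, falling back to the mean over all atoms."""
        ca = self.ca()
        if ca is not None:
            return ca.bfactor
        return float(np.mean([a.bfactor for a in self.atoms]))

    def copy(self) -> "Residue":
        return Residue(self.name, self.number, self.insertion_code,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class AssemblyModel:
    """Atomic coordinates of a multi-chain oligomer (one model)."""

    chains: list[Chain]
    model_id: int = 1

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain_ids: {ids}")
        if self.residue_count == 0:
            raise EmptyInputError("assembly contains no residues")

    # -- basic accessors -------------------------------------------------

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def residue_count(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def atom_count(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in assembly {self.chain_ids}")

    def segmentation(self) -> list[tuple[str, int]]:
        """Ordered (chain_id, residue_count) pairs; shared with PaeMatrix."""
        return [(c.chain_id, len(c.residues)) for c in self.chains]

    def residue_numbers(self) -> list[np.ndarray]:
        return [np.array([r.number for r in c.residues]) for c in self.chains]

    def atoms(self) -> Iterator[AtomRecord]:
        for c in self.chains:
            for r in c.residues:
                yield from r.atoms

    def coords(self) -> np.ndarray:
        """All atom positions, (N, 3), concatenated chain order."""
        return np.array([a.position for a in self.atoms()], dtype=float)

    def ca_coords(self, chain_id: str | None = None) -> np.ndarray:
        chains = self.chains if chain_id is None else [self.chain(chain_id)]
        out = []
        for c in chains:
            for r in c.residues:
                ca = r.ca()
                if ca is not None:
                    out.append(ca.position)
        if not out:
            raise EmptySelectionError("no Calpha atoms found")
        return np.array(out, dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms()]

    # -- transformations -------------------------------------------------

    def copy(self) -> "AssemblyModel":
        return AssemblyModel([c.copy() for c in self.chains], self.model_id)

    def with_coords(self, coords: np.ndarray) -> "AssemblyModel":
        """New model with the same inventory and replaced positions."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.atom_count, 3):
            raise ValueError(f"expected {(self.atom_count, 3)} coords, got {coords.shape}")
        out = self.copy()
        for atom, pos in zip(out.atoms(), coords):
            atom.position = pos.copy()
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AssemblyModel":
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return self.with_coords(self.coords() @ R.T + t)


@dataclass(frozen=True)
class DomainSpan:
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.name not in DOMAIN_NAMES:
            raise DomainMapError(f"unknown domain name {self.name!r}; expected one of {DOMAIN_NAMES}")
        if self.start > self.end:
            raise DomainMapError(f"domain {self.name}: start {self.start} > end {self.end}")


@dataclass
class DomainMap:
    """Per-protein residue ranges (1-based inclusive, author numbering).

    One map applies identically to every chain of a homo-oligomer.
    """

    entries: list[DomainSpan]

    def __post_init__(self) -> None:
        covered: set[int] = set()
        for span in self.entries:
            rng = set(range(span.start, span.end + 1))
            if covered & rng:
                raise DomainMapError("overlapping domain ranges")
            covered |= rng

    @property
    def names(self) -> list[str]:
        return sorted({e.name for e in self.entries})

    def has(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    def residues(self, name: str) -> list[int]:
        """Sorted residue numbers mapped to a domain; error if absent."""
        if not self.has(name):
            raise DomainMapError(f"domain {name!r} absent from map (have {self.names})")
        out: set[int] = set()
        for e in self.entries:
            if e.name == name:
                out |= set(range(e.start, e.end + 1))
        return sorted(out)

    def domain_of(self, residue_number: int) -> str | None:
        for e in self.entries:
            if e.start <= residue_number <= e.end:
                return e.name
        return None

    def restricted(self, name: str) -> "DomainMap":
        spans = [e for e in self.entries if e.name == name]
        if not spans:
            raise DomainMapError(f"domain {name!r} absent from map")
        return DomainMap(spans)

    @classmethod
    def from_tsv(cls, path: str | Path, protein: str | None = None) -> "DomainMap":
        """Read a 4-column TSV: protein, domain, start, end."""
        spans = []
        lines = Path(path).read_text().splitlines()
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "protein":  # header
                continue
            if len(parts) != 4:
                raise DomainMapError(
                    f"{path}:{lineno}: expected columns protein, domain, start, end")
            prot, name, start, end = parts
            if protein is not None and prot != protein:
                continue
            try:
                spans.append(DomainSpan(name, int(start), int(end)))
            except ValueError as exc:
                raise DomainMapError(f"{path}:{lineno}: {exc}") from exc
        if not spans:
            raise DomainMapError(f"no domain rows found in {path}"
                                 + (f" for protein {protein!r}" if protein else ""))
        return cls(spans)

    def to_tsv(self, path: str | Path, protein: str = "synthetic") -> None:
        lines = ["protein\tdomain\tstart\tend"]
        for e in self.entries:
            lines.append(f"{protein}\t{e.name}\t{e.start}\t{e.end}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PlddtSeries:
    """Per-residue confidence, concatenated chain order; 0-100 scale."""

    values: np.ndarray
    out_of_range: bool


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_ICODE_ORDER = " " + "".join(chr(c) for c in range(ord("A"), ord("Z") + 1))


def _icode_rank(icode: str) -> int:
    code = icode if icode else " "
    return _ICODE_ORDER.index(code) if code in _ICODE_ORDER else len(_ICODE_ORDER)


def _guess_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _parse_pdb_atom(line: str, lineno: int) -> tuple[AtomRecord, str]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip() or "A"
        resseq = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_s = line[54:60].strip()
        bf_s = line[60:66].strip()
        occ = float(occ_s) if occ_s else 1.0
        bf = float(bf_s) if bf_s else 0.0
        elem = line[76:78].strip() if len(line) >= 77 else ""
    except ValueError as exc:
        raise StructureParseError(
            f"malformed ATOM/HETATM record at line {lineno}: {line.rstrip()!r}") from exc
    record = AtomRecord(
        serial=serial, atom_name=name, element=elem or _guess_element(name),
        residue_name=resname, residue_number=resseq, insertion_code=icode,
        chain_id=chain, position=(x, y, z), occupancy=occ, bfactor=bf)
    return record, altloc


def _assemble(records: list[tuple[AtomRecord, str]], model_id: int) -> AssemblyModel:
    """Group raw records into chains/residues; keep highest-occupancy altloc."""
    chains: dict[str, dict[tuple[int, str], Residue]] = {}
    chain_order: list[str] = []
    # (chain, resnum, icode, atom_name) -> (residue, atom index, altloc occupancy)
    seen: dict[tuple, tuple[Residue, int]] = {}
    for record, altloc in records:
        if record.chain_id not in chains:
            chains[record.chain_id] = {}
            chain_order.append(record.chain_id)
        reskey = (record.residue_number, record.insertion_code)
        resmap = chains[record.chain_id]
        if reskey not in resmap:
            resmap[reskey] = Residue(record.residue_name, record.residue_number,
                                     record.insertion_code)
        residue = resmap[reskey]
        atomkey = (record.chain_id, reskey, record.atom_name)
        if altloc and atomkey in seen:
            prev_res, idx = seen[atomkey]
            if record.occupancy > prev_res.atoms[idx].occupancy:
                prev_res.atoms[idx] = record  # higher occupancy wins; tie keeps first
        else:
            residue.atoms.append(record)
            seen[atomkey] = (residue, len(residue.atoms) - 1)
    built = []
    for cid in chain_order:
        residues = sorted(chains[cid].values(),
                          key=lambda r: (r.number, _icode_rank(r.insertion_code)))
        built.append(Chain(cid, residues))
    return AssemblyModel(built, model_id=model_id)


def _read_pdb_models(path: str | Path) -> list[AssemblyModel]:
    models: list[AssemblyModel] = []
    records: list[tuple[AtomRecord, str]] = []
    model_id = 1
    in_model = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            tag = line[:6]
            if tag == "MODEL ":
                if records:
                    models.append(_assemble(records, model_id))
                    records = []
                try:
                    model_id = int(line[6:].split()[0])
                except (ValueError, IndexError):
                    model_id = len(models) + 1
                in_model = True
            elif tag == "ENDMDL":
                if records:
                    models.append(_assemble(records, model_id))
                records = []
                in_model = False
            elif tag in ("ATOM  ", "HETATM"):
                records.append(_parse_pdb_atom(line, lineno))
    if records:
        models.append(_assemble(records, model_id if in_model else 1))
    if not models:
        raise EmptyInputError(f"no atoms found in {path}")
    return models


def _read_mmcif(path: str | Path, model: int = 1) -> AssemblyModel:
    import biotite.structure.io.pdbx as pdbx

    cif = pdbx.CIFFile.read(str(path))
    try:
        arr = pdbx.get_structure(cif, model=model, altloc="occupancy",
                                 extra_fields=["b_factor", "occupancy", "atom_id"])
    except Exception as exc:  # biotite raises assorted types on malformed input
        raise StructureParseError(f"failed to parse mmCIF {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise EmptyInputError(f"no atoms found in {path}")
    records = []
    ins = (arr.ins_code if "ins_code" in arr.get_annotation_categories()
           else [""] * arr.array_length())
    for i in range(arr.array_length()):
        rec = AtomRecord(
            serial=int(arr.atom_id[i]),
            atom_name=str(arr.atom_name[i]),
            element=str(arr.element[i]) or _guess_element(str(arr.atom_name[i])),
            residue_name=str(arr.res_name[i]),
            residue_number=int(arr.res_id[i]),
            insertion_code=str(ins[i]).strip(),
            chain_id=str(arr.chain_id[i]),
            position=arr.coord[i],
            occupancy=float(arr.occupancy[i]),
            bfactor=float(arr.b_factor[i]),
        )
        records.append((rec, ""))
    return _assemble(records, model_id=model)


def _detect_format(path: str | Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    raise StructureParseError(f"cannot detect format from extension {suffix!r}")


def read_structure(path: str | Path, format: str = "auto",
                   model: int | None = None) -> AssemblyModel:
    """Read one model of a PDB or mmCIF file, B-factors preserved verbatim.

    Parameters
    ----------
    path : file path
    format : ``pdb``, ``mmcif`` or ``auto`` (by extension)
    model : 1-based model index; default is the first model in the file.
    """
    fmt = _detect_format(path, format)
    if fmt == "mmcif":
        return _read_mmcif(path, model=model or 1)
    if fmt != "pdb":
        raise StructureParseError(f"unknown format {fmt!r}")
    models = _read_pdb_models(path)
    if model is None:
        return models[0]
    for m in models:
        if m.model_id == model:
            return m
    raise StructureParseError(f"model {model} not found in {path}")


def read_models(path: str | Path) -> list[AssemblyModel]:
    """All models of a multi-model PDB file, in file order."""
    return _read_pdb_models(path)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _format_atom_line(atom: AtomRecord, serial: int) -> str:
    name = atom.atom_name
    if len(name) < 4:
        name = f" {name:<3s}"  # standard left-offset for short names
    chain = atom.chain_id[:1]
    return (f"ATOM  {serial:5d} {name:4s} {atom.residue_name:>3s} {chain:1s}"
            f"{atom.residue_number:4d}{atom.insertion_code[:1] or ' ':1s}   "
            f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}{atom.position[2]:8.3f}"
            f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}          {atom.element[:2]:>2s}")


def _pdb_body(model: AssemblyModel) -> list[str]:
    lines = []
    serial = 0
    for chain in model.chains:
        for residue in chain.residues:
            for atom in residue.atoms:
                serial += 1
                lines.append(_format_atom_line(atom, serial))
        serial += 1
        lines.append(f"TER   {serial:5d}")
    return lines


def write_structure(model: AssemblyModel, path: str | Path, format: str = "pdb") -> None:
    """Write a model as fixed-column PDB (3-decimal coordinates)."""
    if format not in ("pdb", "auto"):
        raise StructureParseError(f"only PDB output is supported, not {format!r}")
    if model.atom_count == 0:
        raise EmptyInputError("cannot write an empty model")
    lines = _pdb_body(model) + ["END"]
    Path(path).write_text("\n".join(lines) + "\n")


def write_models(models: Sequence[AssemblyModel], path: str | Path) -> None:
    """Write a multi-model PDB (one MODEL/ENDMDL block per frame)."""
    if not models:
        raise EmptyInputError("no models to write")
    lines = []
    for i, model in enumerate(models, start=1):
        lines.append(f"MODEL {i:8d}")
        lines.extend(_pdb_body(model))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Selection and confidence
# ---------------------------------------------------------------------------

def select_atoms(model: AssemblyModel,
                 chain_ids: Iterable[str] | None = None,
                 domain: str | None = None,
                 domain_map: DomainMap | None = None,
                 atom_names: Iterable[str] | None = None) -> AssemblyModel:
    """Project an assembly onto chains, a mapped domain, and/or atom names.

    Order is preserved; applying the same selection twice is a no-op.
    """
    if domain is not None and domain_map is None:
        raise DomainMapError("domain selection requires a DomainMap")
    if chain_ids is not None:
        chain_ids = set(chain_ids)
        missing = chain_ids - set(model.chain_ids)
        if missing:
            raise KeyError(f"chains not in assembly: {sorted(missing)}")
    wanted_residues = None
    if domain is not None:
        wanted_residues = set(domain_map.residues(domain))
    atom_names = set(atom_names) if atom_names is not None else None

    new_chains = []
    for chain in model.chains:
        if chain_ids is not None and chain.chain_id not in chain_ids:
            continue
        residues = []
        for residue in chain.residues:
            if wanted_residues is not None and residue.number not in wanted_residues:
                continue
            atoms = [a.copy() for a in residue.atoms
                     if atom_names is None or a.atom_name in atom_names]
            if atoms:
                residues.append(Residue(residue.name, residue.number,
                                        residue.insertion_code, atoms))
        if residues:
            new_chains.append(Chain(chain.chain_id, residues))
    if not new_chains:
        raise EmptySelectionError(
            f"selection (chains={chain_ids}, domain={domain}, atoms={atom_names}) is empty")
    return AssemblyModel(new_chains, model.model_id)


def extract_plddt(model: AssemblyModel) -> PlddtSeries:
    """Per-residue confidence from B-factors (Calpha, else atom mean)."""
    if model.residue_count == 0:
        raise EmptyInputError("empty model")
    values = np.array([r.plddt() for c in model.chains for r in c.residues])
    out_of_range = bool(np.any((values < 0) | (values > 100)))
    return PlddtSeries(values=values, out_of_range=out_of_range)
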