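"""Atomic data model for helicase-core analysis.

Coordinate files (mmCIF or legacy PDB) are parsed with gemmi and exposed
through a small uniform model: :class:`Structure` -> chains -> residues ->
atoms.  Author residue numbering (``auth_seq_id``) is the convention
throughout, because DEAH-box domain boundaries and motif residues are cited
in author numbers (e.g. RecA1 557-733, motif V serine S837).

Policy applied at parse time:

* hydrogens and zero-occupancy atoms are dropped (they contribute no
  reliable geometry at the 2.7-3.25 A resolutions typical of these entries);
* for alternate conformations only the highest-occupancy conformer is kept,
  ties broken alphabetically by alt-loc id;
* waters and ions are retained but flagged non-polymer.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "PolymerClass",
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "DomainName",
    "DomainDefinition",
    "MotifAnnotation",
    "AtomSet",
    "read_structure",
    "select_atoms",
    "resolved_residue_count",
    "load_domain_definitions",
    "builtin_domain_definitions",
    "builtin_motif_annotations",
]

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
RNA_RESIDUES = {"A", "C", "G", "U"}

BACKBONE_PROTEIN = {"N", "CA", "C", "O"}
BACKBONE_RNA = {"P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "C3'", "O3'"}


class PolymerClass(enum.Enum):
    PROTEIN = "protein"
    RNA = "RNA"
    OTHER = "other"


class AtomFilter(enum.Enum):
    """Atom subset used for superposition / centre-of-mass work."""

    CA_ONLY = "CA-only"
    BACKBONE = "backbone"
    ALL_HEAVY = "all-heavy"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    pos: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    b_iso: float = 0.0

    @property
    def mass(self) -> float:
        return gemmi.Element(self.element).weight

    def coords(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)


@dataclass
class Residue:
    chain_id: str
    seqid: int            # author residue number, 1-based
    icode: str
    name: str
    polymer: PolymerClass
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seqid, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        # hydrogens are already excluded at parse time
        return list(self.atoms)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def residue(self, seqid: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.seqid == seqid and r.icode == icode:
                return r
        return None

    def polymer_residues(self, polymer: PolymerClass) -> list[Residue]:
        return [r for r in self.residues if r.polymer == polymer]


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains
                if any(r.polymer == PolymerClass.PROTEIN for r in c)]

    def rna_chains(self) -> list[Chain]:
        return [c for c in self.chains
                if any(r.polymer == PolymerClass.RNA for r in c)]

    def iter_residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c


class DomainName(enum.Enum):
    NTERM = "Nterm"
    RECA1 = "RecA1"
    RECA2 = "RecA2"
    WH = "WH"
    HB = "HB"
    OB = "OB"

    @classmethod
    def parse(cls, text: str) -> "DomainName":
        for m in cls:
            if m.value.lower() == text.lower():
                return m
        raise ValueError(f"unknown domain name {text!r}")


# sequence order constraint on the C-terminal cassette
_DOMAIN_ORDER = [DomainName.RECA1, DomainName.RECA2, DomainName.WH,
                 DomainName.HB, DomainName.OB]


@dataclass(frozen=True)
class DomainDefinition:
    """Named, inclusive author-numbered residue interval on one chain."""

    name: DomainName
    chain: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"domain {self.name.value}: end < start")

    def __contains__(self, seqid: int) -> bool:
        return self.start <= seqid <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def validate_domain_set(domains: Sequence[DomainDefinition]) -> None:
    """Check non-overlap per chain and canonical sequence order."""
    by_chain: dict[str, list[DomainDefinition]] = {}
    for d in domains:
        by_chain.setdefault(d.chain, []).append(d)
    for chain, ds in by_chain.items():
        ds_sorted = sorted(ds, key=lambda d: d.start)
        for a, b in zip(ds_sorted, ds_sorted[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping domains {a.name.value}/{b.name.value} "
                    f"on chain {chain}")
        order = [d.name for d in ds_sorted if d.name in _DOMAIN_ORDER]
        expected = [n for n in _DOMAIN_ORDER if n in order]
        if order != expected:
            raise ValueError(
                f"domains on chain {chain} violate RecA1<RecA2<WH<HB<OB "
                f"sequence order: {[n.value for n in order]}")


@dataclass
class MotifAnnotation:
    """A conserved sequence motif mapped to author-numbered residues.

    ``unmodeled`` lists annotated residues absent from the structure's
    coordinates (disordered in the density)."""

    motif: str
    residues: list[tuple[int, str]]     # (author number, residue name)
    unmodeled: list[int] = field(default_factory=list)

    def check_against(self, chain: Chain) -> "MotifAnnotation":
        missing = [n for n, _ in self.residues if chain.residue(n) is None]
        return MotifAnnotation(self.motif, list(self.residues), missing)


@dataclass
class AtomSet:
    """Flat, ordered atom selection with provenance keys.

    Keys are (residue seqid, insertion code, atom name); ordering is by
    residue number then atom name, which makes pairings deterministic."""

    structure_id: str
    chain_id: str
    keys: list[tuple[int, str, str]]
    coords: np.ndarray                 # (n, 3) float
    masses: np.ndarray                 # (n,) float
    gaps: list[int] = field(default_factory=list)  # seqids absent from selection

    def __len__(self) -> int:
        return len(self.keys)

    def subset(self, idx: Sequence[int]) -> "AtomSet":
        idx = list(idx)
        return AtomSet(self.structure_id, self.chain_id,
                       [self.keys[i] for i in idx],
                       self.coords[idx], self.masses[idx], list(self.gaps))


def _classify_polymer(resname: str) -> PolymerClass:
    if resname in STANDARD_AMINO_ACIDS:
        return PolymerClass.PROTEIN
    if resname in RNA_RESIDUES:
        return PolymerClass.RNA
    return PolymerClass.OTHER


def _pick_altlocs(raw: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties broken
    alphabetically by alt-loc id."""
    best: dict[str, gemmi.Atom] = {}
    for a in raw:
        prev = best.get(a.name)
        if prev is None:
            best[a.name] = a
        elif (a.occ, _altloc_rank(prev)) > (prev.occ, _altloc_rank(a)):
            # higher occupancy wins; on a tie the earlier altloc letter wins
            if a.occ > prev.occ or (a.occ == prev.occ
                                    and (a.altloc or "~") < (prev.altloc or "~")):
                best[a.name] = a
    return list(best.values())


def _altloc_rank(a: gemmi.Atom) -> str:
    return a.altloc or "~"


def read_structure(source: str | Path) -> Structure:
    """Read an mmCIF or PDB file into the uniform model.

    ``source`` may also be a bare 4-character accession, in which case a
    file ``<accession>.cif`` or ``<accession>.pdb`` is looked up in the
    cache directory (``HELICORE_CACHE`` env var or ``./pdb_cache``).
    Fetching from the wwPDB is a separate explicit action
    (``helicore fetch`` / scripts/fetch_structures.py), never implicit.
    """
    import os

    path = Path(source)
    if not path.exists() and len(str(source)) == 4 and str(source).isalnum():
        cache = Path(os.environ.get("HELICORE_CACHE", "pdb_cache"))
        for ext in (".cif", ".cif.gz", ".pdb", ".ent"):
            cand = cache / f"{str(source).lower()}{ext}"
            if cand.exists():
                path = cand
                break
        else:
            raise FileNotFoundError(
                f"accession {source!r}: no cached file under {cache}/ "
                "(run the explicit fetch step first)")
    if not path.exists():
        raise FileNotFoundError(f"no such coordinate file: {source}")

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: file contains no model")

    model = st[0]
    out = Structure(id=(st.name or path.stem).upper())
    for ch in model:
        chain = Chain(chain_id=ch.name)
        for res in ch:
            kept = _pick_altlocs([a for a in res
                                  if not a.is_hydrogen() and a.occ > 0.0])
            if not kept:
                continue
            r = Residue(
                chain_id=ch.name,
                seqid=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                name=res.name.strip(),
                polymer=_classify_polymer(res.name.strip()),
            )
            for a in sorted(kept, key=lambda a: a.name):
                r.atoms.append(Atom(
                    name=a.name,
                    element=a.element.name,
                    pos=(a.pos.x, a.pos.y, a.pos.z),
                    occupancy=a.occ,
                    altloc=a.altloc or "",
                    b_iso=a.b_iso,
                ))
            chain.residues.append(r)
        if chain.residues:
            chain.residues.sort(key=lambda r: (r.seqid, r.icode))
            out.chains.append(chain)
    if not out.chains:
        raise ValueError(f"{path}: model is empty")
    return out


def _atom_passes(atom: Atom, residue: Residue, atom_filter: AtomFilter) -> bool:
    if atom_filter == AtomFilter.ALL_HEAVY:
        return True
    if residue.polymer == PolymerClass.PROTEIN:
        if atom_filter == AtomFilter.CA_ONLY:
            return atom.name == "CA"
        return atom.name in BACKBONE_PROTEIN
    if residue.polymer == PolymerClass.RNA:
        if atom_filter == AtomFilter.CA_ONLY:
            return atom.name == "C1'"   # representative atom for nucleotides
        return atom.name in BACKBONE_RNA
    return atom_filter == AtomFilter.ALL_HEAVY


def select_atoms(structure: Structure, domain: DomainDefinition,
                 atom_filter: AtomFilter = AtomFilter.CA_ONLY) -> AtomSet:
    """Select atoms of ``domain`` from ``structure``.

    Unmodeled residues in the interval are silently absent from the
    selection but listed in ``AtomSet.gaps``."""
    chain = structure.chain(domain.chain)
    keys: list[tuple[int, str, str]] = []
    coords: list[tuple[float, float, float]] = []
    masses: list[float] = []
    present: set[int] = set()
    for res in chain:
        if res.seqid not in domain:
            continue
        present.add(res.seqid)
        for atom in sorted(res.atoms, key=lambda a: a.name):
            if _atom_passes(atom, res, atom_filter):
                keys.append((res.seqid, res.icode, atom.name))
                coords.append(atom.pos)
                masses.append(atom.mass)
    if not keys:
        raise ValueError(
            f"empty selection: domain {domain.name.value} "
            f"({domain.start}-{domain.end}) on chain {domain.chain} "
            f"of {structure.id}")
    gaps = [s for s in range(domain.start, domain.end + 1) if s not in present]
    return AtomSet(structure.id, domain.chain, keys,
                   np.asarray(coords, dtype=float),
                   np.asarray(masses, dtype=float), gaps)


def resolved_residue_count(structure: Structure, chain_id: str,
                           start: int, end: int,
                           denominator: int | None = None,
                           ) -> tuple[int, int]:
    """Count residues in [start, end] with at least one modeled heavy atom.

    Returns ``(modeled, denominator)``.  The denominator defaults to the
    interval length but is configurable because published per-domain
    residue totals may follow a different bookkeeping than the raw
    interval span."""
    if end < start:
        raise ValueError("invalid range: end < start")
    chain = structure.chain(chain_id)
    modeled = sum(1 for r in chain
                  if start <= r.seqid <= end and r.heavy_atoms())
    denom = denominator if denominator is not None else end - start + 1
    return modeled, denom


# ---------------------------------------------------------------------------
# Built-in domain / motif tables (ctPrp22 author numbering)

_DATA_DIR = Path(__file__).parent / "data"


def load_domain_definitions(path: str | Path,
                            structure_id: str | None = None,
                            chain: str | None = None,
                            ) -> list[DomainDefinition]:
    """Load domain intervals from a TSV with columns
    structure_id, chain, domain, start, end.  ``structure_id`` filters the
    rows (falling back to the ``default`` row set); ``chain`` overrides the
    chain id in the file (useful for NCS copies)."""
    rows: list[tuple[str, str, str, int, int]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sid, ch, dom, start, end = line.split("\t")
        if sid == "structure_id":
            continue
        rows.append((sid.lower(), ch, dom, int(start), int(end)))
    want = (structure_id or "default").lower()
    chosen = [r for r in rows if r[0] == want]
    if not chosen:
        chosen = [r for r in rows if r[0] == "default"]
    defs = [DomainDefinition(DomainName.parse(dom), chain or ch, start, end)
            for _, ch, dom, start, end in chosen]
    validate_domain_set(defs)
    return defs


def builtin_domain_definitions(chain: str = "A",
                               structure_id: str | None = None,
                               ) -> list[DomainDefinition]:
    """The ctPrp22 domain architecture (RecA1 557-733, RecA2 734-909,
    WH 910-977, HB 978-1091, OB 1092-1175) from the packaged table."""
    return load_domain_definitions(_DATA_DIR / "domains.tsv",
                                   structure_id=structure_id, chain=chain)


def builtin_motif_annotations() -> list[MotifAnnotation]:
    """ctPrp22 motif and functional-element residues (author numbering)."""
    table = [
        ("Ia", [(612, "ARG")]),
        ("hook-turn", [(639, "ARG")]),
        ("Ib", [(654, "THR")]),
        ("hook-loop", [(806, "SER")]),
        ("V", [(831, "THR"), (837, "SER")]),
        ("beta-hairpin", [(853, "LYS")]),
        ("stacking-triad", [(1128, "HIS"), (1129, "PRO"), (1134, "PHE")]),
    ]
    return [MotifAnnotation(m, rs) for m, rs in table]
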