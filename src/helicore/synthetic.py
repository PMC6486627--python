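"""Synthetic fixtures with known ground truth.

Every detector and fit in this package is validated against geometry or
data generated here with recorded truth: rigid pairs with a known
rotation/translation, two-lobe pseudo-structures with a known
centre-of-mass separation, idealized stacked single-stranded RNA,
constructed hydrogen-bond and ring geometries, backbone chains built from
prescribed (phi, psi) dihedrals, and noisy kinetics/binding datasets drawn
from stated parameters.

Fixtures are plain in-memory :class:`~helicore.structure.Structure` objects
and can be serialized to genuine PDB/mmCIF text (so the real readers are
exercised, not bypassed).  Each generator takes an explicit seed and owns
its RNG; identical parameters and seed give identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .biochem import (BindingDataset, KineticsDataset, fp_fraction_bound,
                      michaelis_menten)
from .structure import (Atom, AtomSet, Chain, DomainDefinition, DomainName,
                        PolymerClass, Residue, Structure)
from .superpose import RigidTransform, rotation_from_axis_angle

__all__ = [
    "FixtureSpec",
    "gen_rigid_pair",
    "gen_two_lobe_structure",
    "gen_stacked_rna",
    "gen_hbond_geometry",
    "gen_ring_geometry",
    "gen_helix_chain",
    "gen_nadh_trace",
    "gen_mm_data",
    "gen_fp_data",
    "transform_structure",
    "structure_to_gemmi",
    "write_structure",
    "generate_fixture",
]


# --------------------------------------------------------------------------
# serialization

def structure_to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gch = gemmi.Chain(chain.chain_id)
        for res in chain:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seqid, res.icode or " ")
            if res.polymer == PolymerClass.OTHER:
                gres.het_flag = "H"
            else:
                gres.het_flag = "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.pos)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_iso
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path) -> Path:
    """Write as PDB (.pdb/.ent) or mmCIF (.cif) by extension."""
    path = Path(path)
    st = structure_to_gemmi(structure)
    if path.suffix in (".pdb", ".ent"):
        path.write_text(st.make_pdb_string())
    elif path.suffix == ".cif":
        path.write_text(st.make_mmcif_document().as_string())
    else:
        raise ValueError(f"unknown coordinate format: {path.suffix}")
    return path


def transform_structure(structure: Structure,
                        transform: RigidTransform) -> Structure:
    """Rigidly move every atom (full float precision, no file round-trip)."""
    out = Structure(id=structure.id)
    for chain in structure.chains:
        nch = Chain(chain.chain_id)
        for res in chain:
            nres = Residue(res.chain_id, res.seqid, res.icode, res.name,
                           res.polymer)
            for atom in res.atoms:
                x, y, z = transform.apply(np.asarray(atom.pos))
                nres.atoms.append(dataclasses.replace(
                    atom, pos=(float(x), float(y), float(z))))
            nch.residues.append(nres)
        out.chains.append(nch)
    return out


def random_rigid_transform(seed: int, max_translation: float = 20.0,
                           ) -> RigidTransform:
    """Uniform-ish random rotation + bounded random translation."""
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = float(rng.uniform(0.0, 180.0))
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(rotation_from_axis_angle(axis, angle), t)


# --------------------------------------------------------------------------
# rigid pairs

@dataclass
class RigidPairFixture:
    set_a: AtomSet
    set_b: AtomSet
    truth: RigidTransform
    angle_deg: float
    axis: np.ndarray
    translation: np.ndarray
    noise_sigma: float


def _cloud(rng: np.random.Generator, n: int, spread: float = 10.0,
           ) -> np.ndarray:
    """Random point cloud with non-degenerate spread in all 3 directions."""
    while True:
        pts = rng.normal(scale=spread, size=(n, 3))
        if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-6) == 3:
            return pts


def gen_rigid_pair(n_atoms: int, angle_deg: float, axis, translation,
                   noise_sigma: float = 0.0, seed: int = 0,
                   ) -> RigidPairFixture:
    """Pair of CA atom sets related by a known rigid transform
    (B = R A + t + noise)."""
    if n_atoms < 4:
        raise ValueError("need at least 4 atoms")
    rng = np.random.default_rng(seed)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    translation = np.asarray(translation, dtype=float)
    R = rotation_from_axis_angle(axis, angle_deg)
    truth = RigidTransform(R, translation)

    a = _cloud(rng, n_atoms)
    b = truth.apply(a)
    if noise_sigma > 0:
        b = b + rng.normal(scale=noise_sigma, size=b.shape)
    keys = [(i + 1, "", "CA") for i in range(n_atoms)]
    masses = np.full(n_atoms, gemmi.Element("C").weight)
    return RigidPairFixture(
        set_a=AtomSet("SYNA", "A", list(keys), a, masses.copy()),
        set_b=AtomSet("SYNB", "A", list(keys), b, masses.copy()),
        truth=truth, angle_deg=angle_deg, axis=axis,
        translation=translation, noise_sigma=noise_sigma)


# --------------------------------------------------------------------------
# two-lobe pseudo-structure (oracle for the COM-distance protocol)

@dataclass
class TwoLobeFixture:
    structure: Structure
    domains: list[DomainDefinition]
    separation: float         # exact RecA1-RecA2 COM distance
    chain: str


def _grid(x: np.ndarray) -> np.ndarray:
    """Snap to the 0.001 A grid so PDB serialization is lossless."""
    return np.round(x, 3)


def _lobe_points(rng: np.random.Generator, n: int, centre: np.ndarray,
                 spread: float) -> np.ndarray:
    """n grid-snapped points whose mean is exactly `centre` (centre given
    on the 0.001 grid): the first point absorbs the rounding residual."""
    pts = _grid(rng.normal(scale=spread, size=(n, 3)) + centre)
    target_sum = np.round(centre * n, 3)
    residual = np.round(target_sum - pts.sum(axis=0), 3)
    pts[0] = _grid(pts[0] + residual)
    return pts


def gen_two_lobe_structure(lobe_sizes: tuple[int, int] = (80, 80),
                           com_separation: float = 30.0,
                           spread: float = 6.0,
                           seed: int = 0,
                           chain: str = "A") -> TwoLobeFixture:
    """Two pseudo-domains of CA atoms on one chain, labeled with the
    RecA1/RecA2 author-number ranges, with lobe centres of mass at an
    exactly known separation.  All atoms are carbon, so uniform and
    mass-weighted centres coincide."""
    if com_separation <= 0:
        raise ValueError("separation must be positive")
    n1, n2 = lobe_sizes
    if n1 < 4 or n2 < 4 or n1 > 177 or n2 > 176:
        raise ValueError("lobe sizes must be in [4, 176]")
    rng = np.random.default_rng(seed)
    sep = round(com_separation, 3)
    c1 = np.zeros(3)
    c2 = np.array([sep, 0.0, 0.0])
    pts1 = _lobe_points(rng, n1, c1, spread)
    pts2 = _lobe_points(rng, n2, c2, spread)

    ch = Chain(chain)
    for i, p in enumerate(pts1):
        r = Residue(chain, 557 + i, "", "ALA", PolymerClass.PROTEIN)
        r.atoms.append(Atom("CA", "C", tuple(p)))
        ch.residues.append(r)
    for i, p in enumerate(pts2):
        r = Residue(chain, 734 + i, "", "ALA", PolymerClass.PROTEIN)
        r.atoms.append(Atom("CA", "C", tuple(p)))
        ch.residues.append(r)
    st = Structure(id="2LOB", chains=[ch])
    domains = [
        DomainDefinition(DomainName.RECA1, chain, 557, 733),
        DomainDefinition(DomainName.RECA2, chain, 734, 909),
    ]
    true_sep = float(np.linalg.norm(pts1.mean(axis=0) - pts2.mean(axis=0)))
    return TwoLobeFixture(st, domains, true_sep, chain)


# --------------------------------------------------------------------------
# idealized stacked ssRNA

_RING_NAMES = ("N1", "C2", "N3", "C4", "C5", "C6")
_RING_ELEMENTS = ("N", "C", "N", "C", "C", "C")


def gen_stacked_rna(n: int, rise: float = 3.4, twist: float = 33.0,
                    unstack_after: int | None = None,
                    unstack_offset: float = 6.0,
                    with_interrupting_protein: bool = False,
                    chain: str = "R") -> Structure:
    """Idealized continuously stacked single strand of n uridines.

    Base six-rings are stacked coaxially (centroids on the helix axis,
    spacing ``rise``, in-plane rotation ``twist`` per step) with a minimal
    sugar-phosphate backbone whose O3'(i)-P(i+1) links encode 5'->3'
    connectivity.  ``unstack_after=k`` displaces nucleotides k+1..n
    laterally so the stack breaks into runs of k and n-k;
    ``with_interrupting_protein`` drops a glycine CA between the flanking
    bases of the break, mimicking the beta-hairpin that interrupts the
    bound stack."""
    if n < 2:
        raise ValueError("need >= 2 nucleotides")
    if unstack_after is not None and not (1 <= unstack_after < n):
        raise ValueError("unstack_after must be in [1, n-1]")

    ring_r = 1.38
    backbone_r = 9.0
    ch = Chain(chain)
    p_pos = []
    for i in range(n):
        theta = np.deg2rad(twist * i)
        p = np.array([backbone_r * np.cos(theta + 0.6),
                      backbone_r * np.sin(theta + 0.6),
                      i * rise + 0.8])
        p_pos.append(p)

    centroids = []
    for i in range(n):
        res = Residue(chain, i + 1, "", "U", PolymerClass.RNA)
        theta = np.deg2rad(twist * i)
        z = i * rise
        centroid = np.array([0.0, 0.0, z])
        centroids.append(centroid)
        for k, (name, elem) in enumerate(zip(_RING_NAMES, _RING_ELEMENTS)):
            phi = theta + k * np.pi / 3.0
            pos = centroid + ring_r * np.array([np.cos(phi), np.sin(phi), 0.0])
            res.atoms.append(Atom(name, elem, tuple(pos)))
        # minimal backbone: P (+ nonbridging O), C1' anchor, O3' placed on
        # the covalent link toward the next P
        p = p_pos[i]
        res.atoms.append(Atom("P", "P", tuple(p)))
        res.atoms.append(Atom("OP1", "O", tuple(p + np.array([1.5, 0, 0]))))
        res.atoms.append(Atom("OP2", "O", tuple(p + np.array([0, 1.5, 0]))))
        c1 = centroid + ring_r * 2.2 * np.array(
            [np.cos(theta - 0.9), np.sin(theta - 0.9), 0.0])
        res.atoms.append(Atom("C1'", "C", tuple(c1)))
        if i + 1 < n:
            nxt = p_pos[i + 1]
            u = nxt - p
            u = u / np.linalg.norm(u)
            o3 = nxt - 1.6 * u
        else:
            u = p - p_pos[i - 1]
            u = u / np.linalg.norm(u)
            o3 = p + (np.linalg.norm(p_pos[i - 1] - p) - 1.6) * u \
                if n > 1 else p + np.array([0, 0, 1.6])
        res.atoms.append(Atom("O3'", "O", tuple(o3)))
        ch.residues.append(res)

    if unstack_after is not None:
        shift = np.array([unstack_offset, 0.0, 0.0])
        for res in ch.residues[unstack_after:]:
            res.atoms = [dataclasses.replace(
                a, pos=tuple(np.asarray(a.pos) + shift)) for a in res.atoms]

    st = Structure(id="SRNA", chains=[ch])
    if with_interrupting_protein and unstack_after is not None:
        k = unstack_after
        mid = (np.asarray(ch.residues[k - 1].atom("N1").pos)
               + centroids[k] + np.array([unstack_offset, 0, 0])) / 2.0
        pch = Chain("P")
        res = Residue("P", 853, "", "GLY", PolymerClass.PROTEIN)
        res.atoms.append(Atom("CA", "C", tuple(mid)))
        pch.residues.append(res)
        st.chains.append(pch)
    return st


# --------------------------------------------------------------------------
# constructed contact geometries

def gen_hbond_geometry(distance: float = 3.0, angle_deg: float = 160.0,
                       ) -> Structure:
    """Single candidate N-H...O=P hydrogen bond: a glycine backbone N
    (antecedent CA) donating to a uridine OP1 (antecedent P), at the given
    donor-acceptor distance and antecedent-donor-acceptor angle."""
    prot = Residue("A", 1, "", "GLY", PolymerClass.PROTEIN)
    n = np.zeros(3)
    acceptor = np.array([distance, 0.0, 0.0])
    th = np.deg2rad(angle_deg)
    ca = n + 1.46 * np.array([np.cos(th), np.sin(th), 0.0])
    prot.atoms.append(Atom("N", "N", tuple(n)))
    prot.atoms.append(Atom("CA", "C", tuple(ca)))
    rna = Residue("R", 1, "", "U", PolymerClass.RNA)
    rna.atoms.append(Atom("OP1", "O", tuple(acceptor)))
    rna.atoms.append(Atom("P", "P", tuple(acceptor + np.array([1.5, 0.8, 0]))))
    return Structure(id="HBND", chains=[Chain("A", [prot]), Chain("R", [rna])])


def gen_ring_geometry(vertical: float = 3.5, lateral: float = 0.0,
                      tilt_deg: float = 0.0) -> Structure:
    """A phenylalanine ring at the origin (normal = z) and a uridine base
    ring at (lateral, 0, vertical) tilted by ``tilt_deg`` about y."""
    ring_r = 1.39
    phe = Residue("A", 1, "", "PHE", PolymerClass.PROTEIN)
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    for k, name in enumerate(names):
        phi = k * np.pi / 3.0
        phe.atoms.append(Atom(name, "C", (ring_r * np.cos(phi),
                                          ring_r * np.sin(phi), 0.0)))
    R = rotation_from_axis_angle(np.array([0.0, 1.0, 0.0]), tilt_deg)
    centre = np.array([lateral, 0.0, vertical])
    u = Residue("R", 1, "", "U", PolymerClass.RNA)
    for k, (name, elem) in enumerate(zip(_RING_NAMES, _RING_ELEMENTS)):
        phi = k * np.pi / 3.0
        local = ring_r * np.array([np.cos(phi), np.sin(phi), 0.0])
        u.atoms.append(Atom(name, elem, tuple(centre + R @ local)))
    return Structure(id="RING", chains=[Chain("A", [phe]), Chain("R", [u])])


def gen_backbone_contact_complex(n_reca1: int = 3, n_reca2: int = 6,
                                 spacing: float = 12.0) -> Structure:
    """Protein-RNA complex with a planted number of backbone-contacting
    residues per RecA-like domain.

    Each planted contact is one glycine whose backbone N donates to a
    uridine OP1 at 2.9 A / 165 deg; successive pairs are spaced far apart
    so no accidental contacts arise.  Protein residues are numbered into
    the RecA1 (557+) and RecA2 (734+) author ranges; the study-scale
    condition is RecA1: 3 versus RecA2: 6."""
    prot_chain = Chain("A")
    rna_chain = Chain("R")
    groups = [(557, n_reca1), (734, n_reca2)]
    idx = 0
    for start, count in groups:
        for i in range(count):
            base = np.array([idx * spacing, 0.0, 0.0])
            idx += 1
            res = Residue("A", start + i, "", "GLY", PolymerClass.PROTEIN)
            th = np.deg2rad(165.0)
            res.atoms.append(Atom("N", "N", tuple(base)))
            res.atoms.append(Atom(
                "CA", "C",
                tuple(base + 1.46 * np.array([np.cos(th), np.sin(th), 0.0]))))
            prot_chain.residues.append(res)
            nt = Residue("R", idx, "", "U", PolymerClass.RNA)
            acc = base + np.array([2.9, 0.0, 0.0])
            nt.atoms.append(Atom("OP1", "O", tuple(acc)))
            nt.atoms.append(Atom("P", "P",
                                 tuple(acc + np.array([1.5, 0.8, 0.0]))))
            rna_chain.residues.append(nt)
    return Structure(id="BBCX", chains=[prot_chain, rna_chain])


# --------------------------------------------------------------------------
# backbone chain from prescribed dihedrals

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329}
_ANGLE = {"C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF atom placement: position D with |CD| = bond, angle(B,C,D) and
    dihedral(A,B,C,D) as given."""
    th = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    nrm = np.cross(ab, bc)
    nrm = nrm / np.linalg.norm(nrm)
    m = np.cross(nrm, bc)
    d2 = bond * np.array([-np.cos(th),
                          np.sin(th) * np.cos(chi),
                          np.sin(th) * np.sin(chi)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * nrm


def gen_helix_chain(n: int, phi: float = -57.0, psi: float = -47.0,
                    chain: str = "A", start_seqid: int = 1) -> Structure:
    """Poly-alanine backbone (N, CA, C per residue) built from uniform
    (phi, psi) dihedrals with ideal bond geometry and omega = 180.
    phi/psi = (-57, -47) gives a canonical alpha helix; (-120, 120) an
    extended strand."""
    if n < 4:
        raise ValueError("need >= 4 residues")
    coords: list[tuple[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    th = np.deg2rad(_ANGLE["N-CA-C"])
    c0 = ca0 + _BOND["CA-C"] * np.array([-np.cos(th), np.sin(th), 0.0])
    coords += [("N", n0), ("CA", ca0), ("C", c0)]
    for i in range(1, n):
        prev_n, prev_ca, prev_c = (coords[-3][1], coords[-2][1], coords[-1][1])
        ni = _place(prev_n, prev_ca, prev_c, _BOND["C-N"],
                    _ANGLE["CA-C-N"], psi)
        cai = _place(prev_ca, prev_c, ni, _BOND["N-CA"],
                     _ANGLE["C-N-CA"], 180.0)
        ci = _place(prev_c, ni, cai, _BOND["CA-C"],
                    _ANGLE["N-CA-C"], phi)
        coords += [("N", ni), ("CA", cai), ("C", ci)]
    ch = Chain(chain)
    for i in range(n):
        res = Residue(chain, start_seqid + i, "", "ALA", PolymerClass.PROTEIN)
        for name, pos in coords[3 * i:3 * i + 3]:
            res.atoms.append(Atom(name, name[0], tuple(pos)))
        ch.residues.append(res)
    return Structure(id="HLIX", chains=[ch])


# --------------------------------------------------------------------------
# kinetics / binding / absorbance data

def gen_nadh_trace(rate_uM_per_s: float, a0: float = 1.0,
                   epsilon: float = 6220.0, pathlength_cm: float = 1.0,
                   duration_s: float = 600.0, n_points: int = 120,
                   noise_sigma: float = 0.0, seed: int = 0,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """A340 progress curve for NADH consumption at a stated initial rate.

    In the coupled assay the regeneration enzymes keep NADH oxidation
    zero-order in NADH until the pool nears exhaustion, so the trace is
    near-linear initially and rolls off hyperbolically (half-saturation at
    5% of the pool) as NADH depletes.  The initial slope equals
    -rate * epsilon * l, so the initial-window fit of
    :func:`~helicore.biochem.nadh_rate` recovers the stated rate."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration_s, n_points)
    drop_total = 0.8 * a0
    ks = 0.05 * drop_total
    # consumption rate in absorbance units, scaled so the t=0 slope is exact
    r_abs = rate_uM_per_s * 1e-6 * epsilon * pathlength_cm
    r_abs /= drop_total / (drop_total + ks)
    # integrate dS/dt = -r_abs * S/(S+ks) on a fine grid
    fine_t = np.linspace(0.0, duration_s, 20 * n_points)
    dt = fine_t[1] - fine_t[0]
    s = np.empty_like(fine_t)
    s[0] = drop_total
    for i in range(1, fine_t.size):
        s[i] = max(s[i - 1] - dt * r_abs * s[i - 1] / (s[i - 1] + ks), 0.0)
    a = (a0 - drop_total) + np.interp(t, fine_t, s)
    if noise_sigma > 0:
        a = a + rng.normal(scale=noise_sigma, size=a.shape)
    return t, a


def gen_mm_data(kcat: float = 2.0, km_mM: float = 0.1, e_uM: float = 0.4,
                s_grid_mM: np.ndarray | None = None,
                noise_sigma_rel: float = 0.0, replicates: int = 3,
                seed: int = 0) -> KineticsDataset:
    """Michaelis-Menten initial velocities on the assay's substrate grid
    (0-2 mM ATP) with Gaussian noise scaled to Vmax."""
    if s_grid_mM is None:
        s_grid_mM = np.array([0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.2, 1.6, 2.0])
    rng = np.random.default_rng(seed)
    s = np.tile(np.asarray(s_grid_mM, dtype=float), replicates)
    v = michaelis_menten(s, kcat, km_mM, e_uM)
    if noise_sigma_rel > 0:
        vmax = kcat * e_uM
        v = v + rng.normal(scale=noise_sigma_rel * vmax, size=v.shape)
    rep = np.repeat(np.arange(replicates), len(s_grid_mM))
    return KineticsDataset(s_mM=s, v0=v, e_uM=e_uM, replicate=rep)


def gen_fp_data(kd_uM: float = 2.0, lt_uM: float = 0.006,
                rt_max_uM: float = 70.0, n_points: int = 12,
                noise_sigma: float = 0.0, replicates: int = 3,
                p_free: float = 60.0, p_bound: float = 220.0,
                normalized: bool = False, seed: int = 0) -> BindingDataset:
    """Fluorescence-polarization titration: 6 nM labeled RNA (default)
    titrated with protein up to 70 uM on a log-spaced grid, signal from
    the exact quadratic isotherm plus Gaussian noise (sigma in fraction-
    bound units, scaled to the plateau span for raw polarization)."""
    rng = np.random.default_rng(seed)
    grid = np.concatenate([[0.0],
                           np.geomspace(rt_max_uM / 2000.0, rt_max_uM,
                                        n_points - 1)])
    rt = np.tile(grid, replicates)
    fb = fp_fraction_bound(rt, kd_uM, lt_uM)
    if normalized:
        y = fb
        if noise_sigma > 0:
            y = y + rng.normal(scale=noise_sigma, size=y.shape)
        return BindingDataset(rt_uM=rt, polarization=y, lt_uM=lt_uM,
                              normalized=True)
    y = p_free + (p_bound - p_free) * fb
    if noise_sigma > 0:
        y = y + rng.normal(scale=noise_sigma * (p_bound - p_free),
                           size=y.shape)
    return BindingDataset(rt_uM=rt, polarization=y, lt_uM=lt_uM)


# --------------------------------------------------------------------------
# declarative fixture interface (CLI `helicore simulate`)

_KINDS = ("rigid-pair", "two-lobe", "stacked-rna", "hbond-geometry",
          "ring-geometry", "helix-dihedrals", "mm-data", "fp-data")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    parameters: dict
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"choose from {_KINDS}")


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Materialize a fixture to disk (coordinates as PDB text, data as
    CSV) with a JSON sidecar recording the ground truth.  Returns the
    sidecar dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = dict(spec.parameters)
    truth: dict = {"kind": spec.kind, "seed": spec.seed, "parameters": p}
    if spec.kind == "rigid-pair":
        fx = gen_rigid_pair(seed=spec.seed, **p)
        np.savetxt(out / "set_a.csv", fx.set_a.coords, delimiter=",")
        np.savetxt(out / "set_b.csv", fx.set_b.coords, delimiter=",")
        truth["truth"] = {"angle_deg": fx.angle_deg,
                          "axis": fx.axis.tolist(),
                          "translation": fx.translation.tolist()}
    elif spec.kind == "two-lobe":
        fx = gen_two_lobe_structure(seed=spec.seed, **p)
        write_structure(fx.structure, out / "two_lobe.pdb")
        truth["truth"] = {"separation_A": fx.separation}
    elif spec.kind == "stacked-rna":
        st = gen_stacked_rna(**p)
        write_structure(st, out / "stacked_rna.pdb")
        n = p.get("n")
        k = p.get("unstack_after")
        truth["truth"] = {"max_stack": n if k is None else max(k, n - k)}
    elif spec.kind == "hbond-geometry":
        st = gen_hbond_geometry(**p)
        write_structure(st, out / "hbond.pdb")
        truth["truth"] = p
    elif spec.kind == "ring-geometry":
        st = gen_ring_geometry(**p)
        write_structure(st, out / "rings.pdb")
        truth["truth"] = p
    elif spec.kind == "helix-dihedrals":
        st = gen_helix_chain(**p)
        write_structure(st, out / "helix.pdb")
        truth["truth"] = {"phi": p.get("phi", -57.0),
                          "psi": p.get("psi", -47.0)}
    elif spec.kind == "mm-data":
        ds = gen_mm_data(seed=spec.seed, **p)
        _write_csv(out / "mm_data.csv", ["s_mM", "v0", "e_uM", "rep"],
                   zip(ds.s_mM, ds.v0,
                       [ds.e_uM] * len(ds.s_mM), ds.replicate))
        truth["truth"] = {k: p.get(k, d) for k, d in
                          (("kcat", 2.0), ("km_mM", 0.1), ("e_uM", 0.4))}
    elif spec.kind == "fp-data":
        ds = gen_fp_data(seed=spec.seed, **p)
        _write_csv(out / "fp_data.csv", ["rt_uM", "polarization"],
                   zip(ds.rt_uM, ds.polarization))
        truth["truth"] = {"kd_uM": p.get("kd_uM", 2.0),
                          "lt_uM": p.get("lt_uM", 0.006)}
    sidecar = out / "truth.json"
    sidecar.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return truth


def _write_csv(path: Path, header: list[str], rows) -> None:
    lines = [",".join(header)]
    for row in rows:
        lines.append(",".join(f"{x:.10g}" if isinstance(x, float)
                              else str(x) for x in row))
    path.write_text("\n".join(lines) + "\n")
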