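"""Hydrogen bonds, ring interactions, stack segmentation, helicity."""

import dataclasses

import numpy as np
import pytest

import helicore.contacts as hc
from helicore.contacts import (HBondCriteria, StackCriteria,
                               count_backbone_contact_residues,
                               hydrogen_bonds, motif_helicity,
                               ring_interactions, rna_moiety, rna_strand_order,
                               stack_segments, triad_present)
from helicore.structure import Atom, Chain, PolymerClass, Residue, Structure
from helicore.synthetic import (gen_backbone_contact_complex,
                                gen_hbond_geometry, gen_helix_chain,
                                gen_ring_geometry, gen_stacked_rna,
                                random_rigid_transform, transform_structure)


def _residues(st):
    return [r for c in st.chains for r in c]


def _split(st):
    prot = [r for r in _residues(st) if r.polymer == PolymerClass.PROTEIN]
    rna = [r for r in _residues(st) if r.polymer == PolymerClass.RNA]
    return prot, rna


# --------------------------------------------------------------------------
# hydrogen bonds

class TestHydrogenBonds:
    def test_constructed_geometry_is_one_phosphate_hbond(self):
        prot, rna = _split(gen_hbond_geometry(3.0, 160.0))
        recs = hydrogen_bonds(prot, rna)
        assert len(recs) == 1
        r = recs[0]
        assert r.kind == "hbond"
        assert r.rna_moiety == "phosphate"
        assert r.distance == pytest.approx(3.0, abs=1e-9)
        assert r.angle == pytest.approx(160.0, abs=1e-6)

    def test_beyond_distance_cutoff_gives_nothing(self):
        prot, rna = _split(gen_hbond_geometry(4.2, 160.0))
        assert hydrogen_bonds(prot, rna) == []

    def test_acute_antecedent_angle_rejected(self):
        prot, rna = _split(gen_hbond_geometry(3.0, 80.0))
        assert hydrogen_bonds(prot, rna) == []

    def test_moiety_table(self):
        assert rna_moiety("OP1") == "phosphate"
        assert rna_moiety("O3'") == "phosphate"
        assert rna_moiety("C1'") == "ribose"
        assert rna_moiety("O2'") == "ribose"
        assert rna_moiety("N3") == "base"

    def test_monotone_under_tighter_distance_cutoff(self):
        st = gen_backbone_contact_complex(3, 6)
        prot, rna = _split(st)
        loose = hydrogen_bonds(prot, rna, HBondCriteria(max_da_distance=3.5))
        tight = hydrogen_bonds(prot, rna, HBondCriteria(max_da_distance=2.95))
        keys = lambda rs: {(r.donor, r.acceptor) for r in rs}
        assert keys(tight) <= keys(loose)

    def test_matches_brute_force_all_pairs_oracle(self):
        """Independent nested-loop scan with its own geometry code, over
        the same donor/acceptor chemistry tables."""
        st = gen_backbone_contact_complex(3, 6, spacing=4.5)  # crowded
        prot, rna = _split(st)
        crit = HBondCriteria()
        got = {(r.donor, r.acceptor) for r in hydrogen_bonds(prot, rna, crit)}

        expected = set()
        for da, aa, d_res, a_res in _oracle_pairs(prot, rna):
            dv = np.asarray(d_res.atom(da[0]).pos)
            av = np.asarray(a_res.atom(aa).pos)
            dist = float(np.sqrt(((dv - av) ** 2).sum()))
            if dist > crit.max_da_distance:
                continue
            ok = True
            if da[1] is not None and d_res.atom(da[1]) is not None:
                ant = np.asarray(d_res.atom(da[1]).pos)
                v1, v2 = ant - dv, av - dv
                ang = np.degrees(np.arccos(
                    np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2)))
                ok = ang >= crit.min_antecedent_angle
            if ok:
                expected.add((
                    hc.ResidueRef(d_res.chain_id, d_res.seqid, d_res.name,
                                  da[0]),
                    hc.ResidueRef(a_res.chain_id, a_res.seqid, a_res.name,
                                  aa)))
        assert got == expected

    def test_contact_list_invariant_under_rigid_motion(self):
        st = gen_backbone_contact_complex(3, 6)
        moved = transform_structure(st, random_rigid_transform(99))
        a = hydrogen_bonds(*_split(st))
        b = hydrogen_bonds(*_split(moved))
        assert [(r.donor, r.acceptor) for r in a] == \
            [(r.donor, r.acceptor) for r in b]
        for x, y in zip(a, b):
            assert x.distance == pytest.approx(y.distance, abs=1e-9)


def _oracle_pairs(group_a, group_b):
    """All (donor_atom_spec, acceptor_atom, donor_res, acceptor_res)
    candidates in both directions, straight from the chemistry tables."""
    out = []
    for ra in group_a:
        for rb in group_b:
            for d_res, a_res in ((ra, rb), (rb, ra)):
                for d_name, ant in hc._donors(d_res):
                    for a_name in hc._acceptors(a_res):
                        out.append(((d_name, ant), a_name, d_res, a_res))
    return out


def test_backbone_contact_residue_counts_match_planted_truth():
    st = gen_backbone_contact_complex(n_reca1=3, n_reca2=6)
    assert count_backbone_contact_residues(st, 557, 733, "A", "R") == 3
    assert count_backbone_contact_residues(st, 734, 909, "A", "R") == 6
    st2 = gen_backbone_contact_complex(n_reca1=0, n_reca2=2)
    assert count_backbone_contact_residues(st2, 734, 909, "A", "R") == 2


# --------------------------------------------------------------------------
# ring interactions

class TestRingInteractions:
    def test_coplanar_offset_rings_are_parallel_displaced(self):
        st = gen_ring_geometry(vertical=3.5, lateral=0.0, tilt_deg=0.0)
        recs = ring_interactions(_residues(st))
        assert [r.kind for r in recs] == ["pi-pi-parallel-displaced"]
        assert recs[0].distance == pytest.approx(3.5, abs=1e-9)

    def test_steep_interplanar_angle_is_edge_to_face(self):
        st = gen_ring_geometry(vertical=4.0, lateral=3.0, tilt_deg=80.0)
        recs = ring_interactions(_residues(st))
        assert [r.kind for r in recs] == ["pi-pi-edge-to-face"]
        assert recs[0].angle == pytest.approx(80.0, abs=1e-6)

    def test_distant_rings_report_nothing(self):
        st = gen_ring_geometry(vertical=8.0)
        assert ring_interactions(_residues(st)) == []

    def test_cation_pi_from_arginine_to_base(self):
        st = gen_ring_geometry(vertical=3.5)
        arg = Residue("A", 1012, "", "ARG", PolymerClass.PROTEIN)
        # guanidinium carbon 4 A above the uridine base ring
        arg.atoms.append(Atom("CZ", "C", (0.0, 0.0, 7.5)))
        arg.atoms.append(Atom("NH1", "N", (1.0, 0.0, 8.0)))
        st.chains[0].residues.append(arg)
        recs = ring_interactions(_residues(st))
        cp = [r for r in recs if r.kind == "cation-pi"]
        assert len(cp) >= 1
        assert any(r.donor.seqid == 1012 and r.acceptor.name == "U"
                   and r.rna_moiety == "base" for r in cp)

    def test_stacking_triad_detected(self):
        """His, Pro, Phe rings stacked in sequence form the triad."""
        def pentagon(names, centre, elems="CNCCN"):
            res_atoms = []
            for k, n in enumerate(names):
                phi = 2 * np.pi * k / len(names)
                res_atoms.append(Atom(n, elems[k % len(elems)],
                                      tuple(centre + 1.35 * np.array(
                                          [np.cos(phi), np.sin(phi), 0]))))
            return res_atoms

        his = Residue("A", 1128, "", "HIS", PolymerClass.PROTEIN)
        his.atoms = pentagon(("CG", "ND1", "CD2", "CE1", "NE2"),
                             np.array([0.0, 0.0, 0.0]))
        pro = Residue("A", 1129, "", "PRO", PolymerClass.PROTEIN)
        pro.atoms = pentagon(("N", "CA", "CB", "CG", "CD"),
                             np.array([0.5, 0.0, 3.4]))
        phe = Residue("A", 1134, "", "PHE", PolymerClass.PROTEIN)
        phe.atoms = pentagon(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                             np.array([1.0, 0.0, 6.8]), elems="CCCCCC")
        recs = ring_interactions([his, pro, phe])
        assert triad_present(recs, "A", (1128, 1129, 1134))
        # breaking the chain breaks the triad
        recs2 = ring_interactions([his, phe])
        assert not triad_present(recs2, "A", (1128, 1129, 1134))

    def test_matches_brute_force_ring_scan(self):
        """Oracle: direct pairwise centroid/normal computation."""
        st = gen_stacked_rna(6)
        residues = _residues(st)
        crit = StackCriteria()
        got = {(r.donor.seqid, r.acceptor.seqid): r.kind
               for r in ring_interactions(residues, crit)
               if r.kind.startswith("pi-pi")}
        expected = {}
        for i, ra in enumerate(residues):
            for rb in residues[i + 1:]:
                ga = hc._ring_geometry(ra)
                gb = hc._ring_geometry(rb)
                if ga is None or gb is None:
                    continue
                d = float(np.linalg.norm(ga[0] - gb[0]))
                if d > crit.pipi_max_centroid_distance:
                    continue
                ang = np.degrees(np.arccos(
                    min(abs(float(np.dot(ga[1], gb[1]))), 1.0)))
                kind = ("pi-pi-parallel-displaced"
                        if ang < crit.parallel_displaced_split_angle
                        else "pi-pi-edge-to-face")
                expected[(ra.seqid, rb.seqid)] = kind
        assert got == expected


# --------------------------------------------------------------------------
# stack segmentation

class TestStackSegments:
    @pytest.mark.parametrize("n", range(2, 13))
    def test_ideal_strand_is_one_run(self, n):
        st = gen_stacked_rna(n)
        rep = stack_segments(st, "R")
        assert rep.max_stack == n
        assert rep.runs == [(0, n - 1)]

    def test_break_topology_mirrors_bound_stack(self):
        """A 9-mer broken after the 5th nucleotide: runs of 5 and 4."""
        st = gen_stacked_rna(9, unstack_after=5)
        rep = stack_segments(st, "R")
        assert rep.runs == [(0, 4), (5, 8)]
        assert rep.max_stack == 5
        assert len(rep.order) == 9

    def test_interrupting_protein_reported(self):
        st = gen_stacked_rna(9, unstack_after=5,
                             with_interrupting_protein=True)
        rep = stack_segments(st, "R")
        assert rep.interrupting_residues == [("P", 853, "GLY")]

    def test_strand_order_from_connectivity_not_numbering(self):
        st = gen_stacked_rna(5)
        ch = st.chains[0]
        # scramble author numbers; O3'-P connectivity still defines 5'->3'
        renum = {1: 41, 2: 17, 3: 99, 4: 5, 5: 60}
        for r in ch.residues:
            r.seqid = renum[r.seqid]
        ordered = rna_strand_order(list(ch))
        assert [r.seqid for r in ordered] == [41, 17, 99, 5, 60]
        rep = stack_segments(st, "R")
        assert rep.max_stack == 5

    def test_runs_are_disjoint_ordered_and_cover(self):
        st = gen_stacked_rna(12, unstack_after=7)
        rep = stack_segments(st, "R")
        flat = [i for s, e in rep.runs for i in range(s, e + 1)]
        assert flat == list(range(12))
        assert rep.max_stack == max(e - s + 1 for s, e in rep.runs)

    def test_invariant_under_rigid_motion(self):
        st = gen_stacked_rna(9, unstack_after=4)
        moved = transform_structure(st, random_rigid_transform(55))
        assert stack_segments(st, "R").runs == \
            stack_segments(moved, "R").runs

    def test_single_nucleotide_rejected(self):
        st = gen_stacked_rna(2)
        st.chains[0].residues = st.chains[0].residues[:1]
        with pytest.raises(ValueError):
            stack_segments(st, "R")


# --------------------------------------------------------------------------
# helicity

class TestMotifHelicity:
    def test_ideal_alpha_helix(self):
        st = gen_helix_chain(12, phi=-57.0, psi=-47.0)
        rep = motif_helicity(st, "A", 1, 12)
        assert rep.fraction_helical == pytest.approx(1.0)
        assert rep.label == "helical"

    def test_extended_strand_is_distorted(self):
        st = gen_helix_chain(12, phi=-120.0, psi=120.0)
        rep = motif_helicity(st, "A", 1, 12)
        assert rep.fraction_helical == 0.0
        assert rep.label == "distorted"

    def test_chain_break_reduces_assessable_count(self):
        st = gen_helix_chain(12)
        full = motif_helicity(st, "A", 1, 12)
        st.chains[0].residues = [r for r in st.chains[0] if r.seqid != 6]
        broken = motif_helicity(st, "A", 1, 12)
        assert broken.n_assessable < full.n_assessable
        assert broken.label == "helical"    # remaining residues still helical

    def test_fraction_is_ratio_of_helical_to_assessable(self):
        st = gen_helix_chain(12)
        rep = motif_helicity(st, "A", 1, 12)
        n_hel = sum(1 for phi, psi in rep.dihedrals.values()
                    if phi is not None and psi is not None
                    and -100 <= phi <= -30 and -80 <= psi <= -5)
        assert rep.fraction_helical == pytest.approx(n_hel
                                                     / rep.n_assessable)

    def test_too_short_range_rejected(self):
        st = gen_helix_chain(12)
        with pytest.raises(ValueError):
            motif_helicity(st, "A", 1, 3)

    def test_dihedral_sign_convention_matches_independent_oracle(self):
        """Cross-check the torsion computation (IUPAC sign convention)
        against biotite's dihedral on random atom quadruples."""
        import biotite.structure as struc
        rng = np.random.default_rng(77)
        for _ in range(25):
            q = rng.normal(size=(4, 3)) * 3
            mine = hc._dihedral(*q)
            ref = float(np.degrees(struc.dihedral(*q)))  # float32 precision
            assert mine == pytest.approx(ref, abs=2e-3)

    def test_helix_builder_dihedrals_round_trip(self):
        """The chain generator reproduces its prescribed (phi, psi)."""
        from helicore.contacts import backbone_dihedrals
        st = gen_helix_chain(8, phi=-65.0, psi=-40.0)
        dihedrals = backbone_dihedrals(list(st.chains[0]))
        for seqid, (phi, psi) in dihedrals.items():
            if phi is not None:
                assert phi == pytest.approx(-65.0, abs=1e-6)
            if psi is not None:
                assert psi == pytest.approx(-40.0, abs=1e-6)
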