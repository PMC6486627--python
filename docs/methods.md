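# Methods

This note documents the models, conventions and numerical choices behind
`helicore`, what the synthetic fixtures do and do not emulate, and known
limitations.

## Coordinate model and conventions

Structures are parsed with gemmi from mmCIF or legacy PDB. Author residue
numbering (`auth_seq_id`) is used throughout, because DEAH-box domain
boundaries and motif residues are conventionally cited in author numbers
(RecA1 557–733, RecA2 734–909, WH 910–977, HB 978–1091, OB 1092–1175 for
ctPrp22; motif V serine S837). Hydrogens and zero-occupancy atoms are
excluded from all geometry: at the 2.7–3.25 Å resolutions typical of
these structures hydrogens are not observed and zero-occupancy atoms are
placeholders. For alternate conformations the highest-occupancy conformer
is kept, ties broken alphabetically by alt-loc id. Waters and ions are
retained but flagged non-polymer and take no part in selections.

Domain tables ship as versioned TSV (`structure_id, chain, domain, start,
end`). Only the ctPrp22 architecture is packaged; ranges for Prp43/Prp2
homologs must be supplied by the user (derived from a sequence alignment
onto the ctPrp22 ranges), since this package deliberately does not compute
alignments — equivalence tables are inputs, passed as residue-number maps
to the pairing and protocol functions.

Published per-domain residue totals can follow a different bookkeeping
than the raw interval span (e.g. a 173-residue RecA2 count against the
176-residue 734–909 interval), so `resolved_residue_count` reports the
modeled count against a configurable denominator rather than guessing any
particular convention.

## Superposition and decomposition

Weighted least-squares superposition is the Kabsch/SVD solution with the
standard reflection correction (sign flip of the smallest singular
direction); improper rotations are never returned, and collinear inputs
raise instead of producing an ill-determined rotation (the second
singular value must exceed 1e-9 of the first). RMSD is the weighted RMS
of post-fit pair distances. Pairing is by identical (residue number,
insertion code, atom name) keys, or through a supplied equivalence table
for cross-protein comparisons; fewer than 3 pairs is an error.

The axis–angle decomposition takes the angle from the rotation-matrix
trace (clipped into [−1, 1] against round-off) and the axis from the
antisymmetric part, sign-fixed so the angle lies in [0°, 180°]; near 0°
the axis is ill-defined and reported as +z by convention, near 180° it is
recovered from the symmetric part. The displacement of a caller-named
reference point (typically a domain COM) under the full transform
completes statements like "rotated by 19°, displaced by 1.8 Å".

Default atom set for superposition and COM work is CA-only with uniform
weights: robust to side-chain disorder at these resolutions. Backbone,
all-heavy and atomic-mass-weighted variants exist so results can be
bracketed when the atom set used for a published number is unknown; on
rigid fixtures all variants agree exactly, and the bracketing width on
real data is an empirical error bar.

## The centre-of-mass distance protocol

For each RecA-like domain, atoms common to the reference and target
domain are paired, the reference domain is fitted onto the target, the
full reference domain is transformed, and its COM taken; d_com is the
distance between the two transplanted COMs. Because both COMs are
computed over the reference's atom set, the measure is insensitive to
which residues happen to be modeled in the target — important when the
mobile RecA2 domain is partially disordered. A useful exact property:
the Kabsch fit maps the weighted centroid of the paired reference atoms
onto the paired target centroid, so d_com degrades gracefully even when
the rotational part of a superposition is poor (such cases are logged
when the per-domain RMSD exceeds a 5 Å sanity ceiling; the result is
still returned, flagged, never silently dropped).

The open/closed boundary defaults to 29.5 Å — the midpoint between the
largest nucleotide-bound distance (27.7 Å) and the smallest fully open
apo distance (≈31 Å) in this family — and is configurable everywhere; the
boundary value itself classifies as open. Multi-copy structures are
analyzed per chain and reported per chain.

Inter-state domain shifts superpose the anchor domains (RecA1) first,
then fit the anchor-aligned mobile domain (RecA2) of one state onto the
other and decompose the residual with the mobile COM as reference point.
Per-residue displacement tables (for conserved RNA-contact residues) use
the same anchor alignment and compare CA positions; residues unmodeled in
either state map to None, never silently dropped.

## Contact chemistry and geometry

Hydrogen bonds are detected between heavy atoms from explicit
donor/acceptor tables (protein backbone and side chains; RNA 2′-OH, base
exo-amines and ring nitrogens as donors; phosphate/ribose/base oxygens and
ring nitrogens as acceptors). Criteria: donor–acceptor distance ≤ 3.5 Å
and, where the donor's covalent antecedent exists, antecedent–donor–
acceptor angle ≥ 90° — conventional crystallographic practice in the
absence of hydrogens. Contacts are typed by RNA moiety from atom-name
tables (P/OP1/OP2/O5′/O3′ → phosphate; C1′–C5′/O4′/O2′ → ribose; ring
atoms → base); backbone-contact residue counts (the RecA2:6 vs RecA1:3
fingerprint) tally distinct protein residues with ≥1 bond to phosphate or
ribose moieties. These counts are criteria-sensitive by nature, which is
why every threshold is config-exposed and echoed into outputs.

Ring geometry uses one convention: the six-membered ring for all bases
(purines contribute their pyrimidine-type ring), best-fit plane normals
via SVD. π–π contacts within 5.5 Å centroid distance are classified
parallel-displaced below a 50° interplanar angle and edge-to-face above;
cation–π runs from the Arg guanidinium carbon or Lys NZ to a ring
centroid within 6.0 Å. The proline ring is included in the stacking
tables although not aromatic, because the His-Pro-Phe triad that clamps
the RNA 5′ end stacks through it; the triad is "present" when both
His–Pro and Pro–Phe are in π contact.

Base stacking between consecutive nucleotides requires centroid distance
≤ 4.5 Å, interplanar angle ≤ 30° and lateral centroid offset (component
of the centroid–centroid vector perpendicular to the mean normal)
≤ 2.0 Å. The 5′→3′ order is recomputed from O3′(i)–P(i+1) connectivity
(< 2.5 Å), falling back to author numbering when the backbone is not
traceable; maximal stacked runs give max_stack, and protein atoms within
4 Å of the axis between the flanking base centroids of a break are
reported as the interrupting element (the RecA2 β-hairpin in the bound
complexes).

Helicity: backbone (φ, ψ) in the IUPAC sign convention (verified against
biotite), residues helical within φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°];
a motif is labeled helical at ≥ 80% helical fraction among assessable
residues. Chain breaks (C–N > 1.8 Å) make the flanking dihedrals
undefined and those residues non-assessable rather than non-helical.

## Biochemical fits

NADH-coupled rates: the initial velocity is the negative slope of a
linear fit over the window covering the first 10% of total NADH
consumption (≥ 5 points), divided by ε·l with ε(NADH, 340 nm) =
6220 M⁻¹cm⁻¹ (standard literature value, overridable). Non-decreasing
traces return zero with a warning.

Michaelis–Menten and the exact quadratic (ligand-depletion) binding
isotherm are fitted by nonlinear least squares (lmfit) with three
jittered starts (fixed jitter RNG) to avoid local minima; initial guesses
are Vmax = max(v) with Km at the half-max substrate level, and Kd at the
half-transition protein level. Standard errors are the asymptotic
(covariance-based) errors; non-convergence is flagged, never replaced by
a fallback. Polarization plateaus (P_free, P_bound) can be fixed or
co-fit — both modes exist because either normalization convention is
defensible; pre-normalized data fixes them at 0 and 1. Fits run on pooled
replicate points, not replicate means, matching a triplicate assay
design. A fitted Kd outside the titrated protein range triggers a
wide-confidence-interval warning. Measured catalytic and binding
constants of any particular enzyme are properties of the wet experiment;
this module's contract is parameter recovery, verified on simulated data
(median relative error < 5% for kcat, Km, Kd at 2% Gaussian noise over
200 replicates).

CD conversion: [θ] = θ_obs(mdeg)·MRW/(10·l·c) with l in cm and c in
mg/ml, yielding deg·cm²·dmol⁻¹.

## Synthetic fixtures: what they emulate, and what not

The generators produce: rigid point-set pairs with known
rotation/translation and optional Gaussian coordinate noise; two-lobe
pseudo-domains whose COM separation is exact by construction (coordinates
snapped to the 0.001 Å PDB grid, residual absorbed into one atom, all
atoms carbon so uniform and mass weighting coincide); idealized coaxially
stacked uridine strands (rise 3.4 Å, twist 33°, minimal backbone encoding
connectivity) with optional stack breaks and an intercalated protein
atom; single constructed H-bond and ring geometries at chosen
distances/angles; poly-alanine backbones built by NeRF from prescribed
(φ, ψ) with ideal bond geometry; near-linear NADH progress curves with a
hyperbolic roll-off as the pool depletes; and Michaelis–Menten /
FP datasets on the assay grids (0–2 mM ATP; 6 nM labeled RNA titrated to
70 µM protein, triplicates) with Gaussian noise. Each generator owns a
seeded RNG and records its ground truth; identical spec + seed is
byte-identical on disk.

These fixtures validate geometry, bookkeeping and estimators exactly, but
they are not crystal structures: no side-chain chemistry beyond the
planted groups, no disorder correlated with B-factors, no NCS, no
water-mediated contacts, idealized rather than refined RNA geometry.
Passing tests therefore demonstrate correctness of the measurements and
fits, not the values any particular deposited entry will yield; measuring
those requires the real coordinate files (one-time cached download via
`scripts/fetch_structures.py`), after which the same pipeline applies
unchanged.

## Problem sizes and determinism

Default test and acceptance runs use 40–80-atom point sets, 80-residue
lobes, 2–12-nt strands, 100 random rigid motions for invariance checks
and 200 replicate fits — sizes at which every check is exact or
statistically stable while the whole suite completes in seconds. All
randomness flows from explicit seeds; the acceptance script derives all
sub-seeds from its `--seed` argument.

## Known limitations

- No sequence-alignment computation: cross-protein comparisons need a
  user-supplied residue equivalence table.
- Water-mediated hydrogen-bond networks are out of scope (direct pairs
  only); no electrostatics or stacking-energy scoring.
- The stacking-interruption report is geometric (atoms between flanking
  base planes), not a secondary-structure assignment of the intercalated
  element.
- B-factor-based mobility statistics and crystallographic refinement
  metadata are not analyzed.
- The open/closed threshold is a family-level default; outlier
  architectures may need recalibration against their own
  nucleotide-bound references.
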