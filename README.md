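# helicore

Structural and biochemical analysis of the DEAH-box ATPase helicase core:
how the tandem RecA-like domains toggle between a **closed** (ATP-bound)
and an **open** (adenosine-nucleotide-free) conformation, and how that
cycle translocates single-stranded RNA in the 3′→5′ direction at one
nucleotide per hydrolyzed ATP.

The package is aimed at structural biologists comparing crystal or cryo-EM
models of DEAH/DExH helicases (Prp22, Prp43, Prp2 and relatives) across
catalytic states, and at anyone fitting the accompanying solution
biochemistry (ATPase kinetics, RNA-binding isotherms, CD spectra).

## What it computes

**Conformational state.** The helicase core's openness is measured as the
RecA1–RecA2 centre-of-mass distance *d*<sub>COM</sub>, using a
reference-transplant protocol: for each RecA-like domain the corresponding
domain of a reference structure is least-squares superposed
(Kabsch, proper rotations only) onto the target, the *full* reference
domain is transformed, and its centre of mass taken — so the two COMs are
always computed over identical atom sets regardless of which residues are
disordered in each crystal form. Cores with
*d*<sub>COM</sub> below a configurable threshold (default 29.5 Å) are
classified **closed** (nucleotide-bound geometries cluster at
27.3–27.7 Å), the rest **open** (≈31 Å apo, 31.7 Å when RNA-bound).

**Inter-state motions.** Rigid transforms between states are decomposed
into rotation angle, rotation axis and the displacement of a named
reference point (a domain COM): after RecA1 superposition the residual
RecA2 transform yields quantities such as a 19° rotation with a 1.8 Å COM
displacement (ATP→ADP) or a 5.8 Å RecA2 shift (ATP binding to the RNA
complex), and per-residue displacements of conserved RNA-contact residues.

**RNA-binding fingerprint.** Hydrogen bonds are detected from heavy-atom
donor/acceptor geometry (D···A ≤ 3.5 Å, antecedent angle ≥ 90°) and typed
by RNA moiety (phosphate / ribose / base); π–π stacking is classified
parallel-displaced vs edge-to-face, cation–π contacts run from Arg/Lys
charge centres to base rings, and the OB-fold His-Pro-Phe stacking triad
is detected as a mutual stacking chain. Consecutive nucleotides are
segmented into stacked runs (centroid distance ≤ 4.5 Å, interplanar angle
≤ 30°, lateral offset ≤ 2.0 Å), giving the 4-nt (closed) vs 5-nt (open)
stack counts and the protein element (the RecA2 β-hairpin) interrupting
the stack. Motif V helicity is assessed from backbone (φ, ψ) dihedrals.

**Biochemistry.** Initial ATPase velocities from NADH-coupled A340 traces
(v = −slope/(ε·l), ε = 6220 M⁻¹cm⁻¹); Michaelis–Menten fits
v = k<sub>cat</sub>[E][S]/(K<sub>m</sub>+[S]); fluorescence-polarization
binding via the exact quadratic single-site isotherm

FB = ((K<sub>d</sub> + L<sub>t</sub> + R<sub>t</sub>) −
√((K<sub>d</sub> + L<sub>t</sub> + R<sub>t</sub>)² −
4 L<sub>t</sub> R<sub>t</sub>)) / (2 L<sub>t</sub>)

which accounts for labeled-ligand depletion; and conversion of observed
ellipticity to mean residue ellipticity [θ] = θ·MRW/(10·l·c).

All fits report asymptotic standard errors and a convergence flag.

## Worked example

Classify a core as open or closed (here on two synthetic two-lobe
fixtures with known 27.5 Å and 31.7 Å lobe separations; with real data,
pass mmCIF/PDB files and a domain TSV):

```sh
$ helicore conform --target closed.pdb --reference open.pdb
structure,chain,d_com_A,state
CLOSED,A,27.50,closed
```

The printed 27.50 Å is the RecA1–RecA2 centre-of-mass distance measured
through the reference-transplant protocol; below the 29.5 Å boundary the
core is labeled closed, i.e. in the geometry competent for nucleotide
binding.

Generate a noisy kinetics dataset with known truth and fit it:

```sh
$ helicore simulate mm-data --seed 3 --out mm -p noise_sigma_rel=0.02
$ helicore fit-mm mm/mm_data.csv
{
  "params": { "kcat": 1.9966..., "km_mM": 0.1018... },
  "stderr": { "kcat": 0.0183..., "km_mM": 0.0045... },
  "converged": true, "n_points": 27
}
```

The generator's truth was k<sub>cat</sub> = 2.0 s⁻¹, K<sub>m</sub> =
0.1 mM: the fit recovers both within one standard error at 2% noise.

A full run over a manifest of structures
(`helicore run --manifest manifest.toml`) writes `conformation.csv`
(per-chain *d*<sub>COM</sub> and state), `shifts.csv` (pairwise RecA2
rotation/shift), `contacts.csv`, `stacks.csv` and a `summary.json` that
echoes every criterion used. Deposited entries can be cached once with
`python scripts/fetch_structures.py` (explicit opt-in download).

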