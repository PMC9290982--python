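# Methods

This note documents the models, conventions and calibrations behind
`helixweak`, and what the synthetic-structure tests do and do not show
about real crystal structures.

## Structure model

Input files (PDB or mmCIF, parsed with gemmi) are reduced to a
single-conformer, hydrogen-free model: alternate locations resolve to the
highest-occupancy conformer (ties by altloc label order), hydrogens are
discarded and rebuilt uniformly, waters/heteroatoms are retained but
flagged.  Author residue numbering is preserved verbatim; every residue
also carries a 0-based sequential index per chain, and all i → i±k
arithmetic uses that index, because GPCR entries routinely contain
numbering gaps and fusion constructs.  Only the first model of NMR
entries is read.

## Hydrogen bonds

Amide hydrogens are placed 1.0 Å from N along the direction opposite the
preceding residue's O→C vector (the convention of the DSSP energy model);
prolines and chain-initial residues are donor-incapable.  Bond energy is
the Kabsch–Sander electrostatic model,

    E = 27.888 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)   kcal/mol,

evaluated donor amide against acceptor carbonyl.  For every donor the
acceptors at offsets −3/−4/−5 are evaluated (the 3₁₀/α/π registers); a
donor is counted once its canonical −4 acceptor exists.  The best
(lowest-energy) partner and the canonical −4 record are both kept.

Classes: **normal** for E ≤ −1.2, **weak** for −1.2 < E ≤ −0.5,
**missing** otherwise (the +∞ sentinel of a proton-less donor is always
missing).  The weak/normal boundary has no citable numeric definition;
the defaults are calibrated so that ideal-helix bonds (≈ −2.2 kcal/mol)
are normal and bonds over-stretched by roughly 0.4–0.8 Å fall in the weak
band.  Both thresholds are parameters (`HBondOptions`).

Side-chain-to-backbone bonds use a pure 3.5 Å distance criterion between a
polar side-chain atom (Ser OG, Thr OG1, Asn OD1/ND2, Asp OD1/OD2, Cys SG,
Tyr OH) and a backbone O or N within i−4…i+4.  The residue's own backbone
is excluded — those distances are fixed by covalent geometry — but i±1
partners are kept, because the Ser/Thr contact to the preceding turn's
carbonyl is precisely the textbook backbone clamp.  No angular term is
applied; angular refinement is future work.  Cysteine records are flagged
as weak donors.

## Weak spots and mechanisms

Helices are maximal runs with φ ∈ [−120, −20], ψ ∈ [−80, +10] (single
off-window residues are bridged), length ≥ 6, and ≥ 70 % of donors having
some non-missing helical partner.  π-bulges are ≥ 2 consecutive donors
preferring −5; 3₁₀ constrictions ≥ 2 preferring −3; kinks are axis breaks
> 20° between principal axes fitted to the 7 residues on either side
(window and threshold configurable; segments under 9 residues skip the
kink check and say so).

Every interior canonical bond classified weak/missing becomes a weak
spot.  Mechanism attribution runs in a fixed priority order: proline at
the donor → `proline`; a side-chain bond clamping the weakened bond's own
carbonyl or amide → `sidechain_clamp`; glycine within donor±1 →
`glycine_flex`; heavy-atom contact < 3.8 Å from another helix at donor±1
→ `pushed_backbone`; else `unexplained`.  The proximity rules (donor±1;
clamp must touch the affected bond) are this package's operationalization
of "caused by" and are echoed in the report metadata.  TM3 receives no
special casing: helices without weakening motifs simply yield no rows.

## Generic numbering

Numbering is linear from a user-supplied x50 anchor per helix:
position = 50 + (index − anchor index), inside detected segments only.
The full structure-based GPCRdb scheme additionally renumbers across
bulges; reproducing it would require family-wide alignment
infrastructure, so instead any π-bulge or 3₁₀ constriction lying between
the anchor and a numbered residue raises a warning that linear numbering
may be shifted there.  Anchor residue-type mismatches (mutated anchors)
warn but never fail.

## Cavity and escape channel

A regular grid (default 1 Å) covers the structure; a voxel is open when
its distance to the nearest atom surface exceeds the 1.4 Å water probe.
The default `vdw` mode uses per-element radii (C 1.70, N 1.55, O 1.52,
S 1.80 Å); the historical `literal` mode (probe distance to atom centers
alone) is kept for fidelity with the original density-contouring recipe
but ignores atomic size, so open/closed decisions default to `vdw`.
Components use 6-connectivity so channels cannot leak diagonally through
one-voxel walls.  A component is an enclosed cavity (no boundary
contact), a channel (≥ 2 disjoint boundary patches) or an open cleft.
Minimum pore radius is the bottleneck clearance along the widest path,
found by binary search over clearance thresholds with connectivity
relabeling.

The escape test seeds at the open voxel nearest to a point 2 Å below
(−z) the side-chain centroid of the start residue (default 2x46; offset
configurable) and asks whether that component reaches the cytosolic grid
face through a bottleneck ≥ the ion radius (Na⁺ 1.02 Å).  If no open
voxel lies within 5 Å of the seed point the verdict is closed with a
diagnostic — the gate itself occludes the passage.  The membrane
convention is configuration: helix axes along z, cytosol at −z; the
default grid pads x/y by probe + 2 Å but clips z to the atom extent, so a
transmembrane lumen touches the z faces without the verdict
short-circuiting around the protein's exterior.  Experimental structures
must be oriented into this frame first (e.g. by superposition onto an
oriented reference).

## Rotamers and the gate

χ angles use IUPAC atom quadruples; labels bin each χ to m(−60°)/t(180°)/
p(+60°) by nearest circular center.  Side chains are rebuilt at stated χ
from ideal internal coordinates without refinement — deliberately the
same level of modeling as "residue modeled in the alternative rotamer".
The gate assessment runs the escape test with the observed Leu 2x46 side
chain and again with the side chain rebuilt at the alternative χ pair,
reports both verdicts, and lists blocking contacts: atoms of any residue
within (vdW sum − 0.4 Å) of the rebuilt side chain.  "Open" and "closed"
rotamers are defined functionally, by the channel verdict, not by fixed χ
values; canonical labels are reported alongside.  A rebuilt side chain
driven inside another residue's backbone (< 1.5 Å) is a modeling error,
not a blocked rotamer.

The pentamer search superposes database fragments (backbone N/CA/C/O of
five consecutive residues, same middle residue type) onto the query with
the Kabsch module and returns hits under an RMSD threshold (default
0.5 Å) with the middle side chain carried into the query frame; hit
labels histogram into the rotamer distribution.

## Conservation

Column information is R = log₂20 − H with gaps excluded and no
small-sample correction (alignments here are synthetic or large; the
correction is available as an option would be, but determinism of the
closed-form examples was preferred).  Weak-spot aggregation counts, per
generic position, the number of structures weakened there and the
mechanism breakdown; positions of one helix are additionally grouped by
helix face using the canonical 100°/residue α-helix phase with a ±1
residue window.

## Synthetic structures: what they emulate

Backbone geometry is grown NeRF-style from internal coordinates (N–CA
1.458, CA–C 1.525, C–N 1.329 Å; ideal angles; ω = 180°), with full side
chains for L/S/T/N/D/C/Y/W and CB stubs otherwise.  Canonical torsions:
α (−57, −47), 3₁₀ (−49, −26), π (−57, −70).  Builders are deterministic;
seeds only drive optional noise and background randomization.

Planted mechanisms: *proline* renames the donor (its missing bond follows
from the physics, not from bookkeeping); *sidechain_clamp* places a
serine at donor−3 with χ1 aimed so OG sits ≈ 2.9 Å from the acceptor
carbonyl, and displaces the donor amide N by 0.9 Å away from that
carbonyl — the displacement magnitude is calibrated once so the bond
lands mid-way in the weak band (≈ −0.95 kcal/mol) and is a parameter of
the distortion.  Displacing the donor N (rather than the acceptor O) is
what keeps the perturbation local: every amide H is constructed from the
*preceding* carbonyl, so moving an O would silently re-aim the next
residue's H.

Bundles place seven such helices with axes along z on an 11 Å ring
(inter-axis ≥ 8 Å enforced); helix 3 never receives a weakener, serving
as the TM3 control.  Channel phantoms are double-shelled carbon tubes
whose expected open-voxel count is computed by an independent brute-force
evaluation of the marking rule; the gate phantom embeds a leucine at the
tube's cytosolic mouth whose frozen χ pairs (closed (45°, 60°), open
(−90°, −60°), selected by a one-time geometric scan) seal or clear the
exit, with optional Asp/Tyr blockers filling the open-rotamer volume.

**What passing does not show.**  The phantoms have ideal geometry, no
waters, no ligands, no thermal disorder and stub side chains outside the
mechanism set; real structures add coordinate error, alternative
conformers, genuine π-bulges at the numbering anchors, and membrane
orientation uncertainty.  Recovery rates of 1.0 on the synthetic ensemble
certify the algorithms and their wiring, not the error statistics to be
expected on crystallographic data.

## Problem sizes

The test suite and the acceptance script use 20–30-residue helices,
50-bundle ensembles (26-residue helices), 100 random 50-atom clouds for
the marking oracle, 20 fragment databases of 103 pentamers, and grids of
≤ ~10⁵ voxels — sizes chosen so each property is measured with zero
sampling ambiguity while a full run stays in the tens of seconds on one
CPU.

## Known limitations

* No angular term in side-chain hydrogen-bond detection.
* Linear generic numbering shifts by one across unflagged bulges
  (flagged bulges warn).
* The escape test requires a pre-oriented membrane frame.
* `pushed_backbone` attribution uses a contact distance, not forces.
* The literal cavity mode reproduces the historical recipe but should not
  be used for open/closed decisions.
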