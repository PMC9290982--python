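# helixweak

Backbone hydrogen-bond **weak-spot analysis** for G protein-coupled
receptors (GPCRs) and other helical membrane proteins.

Class A GPCRs carry conserved Pro/Gly/Asp/Asn/Ser/Thr (PGDNST) residues in
six of their seven transmembrane helices.  These residues weaken or remove
particular backbone i → i+4 hydrogen bonds — proline because its amide
nitrogen has no proton, glycine by licensing off-helical torsions, and the
small polar residues by hydrogen-bonding the local backbone and pulling it
out of register.  The resulting *weak spots* give the helices the local
plasticity that activation requires, and their **location** (expressed as a
GPCRdb-style generic residue number such as 5x43) is more conserved across
receptors than the sequence motifs that cause them.  The same machinery
feeds the sodium-escape logic: Leu 2x46, Leu 3x43 and Ile 6x40 form a
hydrophobic barrier above the cytosolic exit of the sodium pocket, and a
small rotamer change of Leu 2x46 — blocked in the inactive state by
Asp 2x50 and Tyr 7x53 — opens a channel wide enough for a sodium ion
(radius 1.02 Å) to escape to the cytosol.

The package implements that analysis as a reusable, tested pipeline:

| module | what it does |
|---|---|
| `structures_io` | PDB/mmCIF ↔ uniform Atom/Residue/Structure model (via gemmi); altloc resolution, hydrogen stripping |
| `synthetic_structures` | deterministic generators: ideal/distorted helices, 7-helix bundles with planted weak spots, channel/sphere/gate phantoms, pentamer fragment databases |
| `hbond` | amide-H placement, Kabsch–Sander energies `E = 27.888 (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol, normal/weak/missing classes |
| `weakspots` | helix detection, π-bulge / 3₁₀ / kink annotation, weak-spot calling with mechanism attribution |
| `numbering` | x50-anchored generic residue numbers (2x46, 5x50, …) |
| `superpose` | Kabsch superposition with robust trimming |
| `cavity` | 1 Å-grid cavity/channel detection (1.4 Å probe), escape-channel test below 2x46 |
| `rotamer` | χ angles, canonical rotamer labels, Leu 2x46 gate assessment, pentamer rotamer-distribution search |
| `conservation` | cross-structure weak-spot profiles, motif scanning, sequence-logo information content |
| `pipeline` / `cli` | orchestration, caching, TSV/JSON reports; `helixweak` command |

## Worked example

Build a synthetic 7-helix bundle with two planted weak spots — a proline
at 2x58 and a serine backbone-clamp at 5x43 — then recover them:

```sh
$ cat spec.yaml
planted:
- helix: 5
  position: 43
  mechanism: sidechain_clamp
- helix: 2
  position: 58
  mechanism: proline

$ helixweak synth --kind bundle --spec spec.yaml --out bundle.pdb
$ printf '%s\n' "1 A 14" "2 B 14" "3 C 14" "4 D 14" "5 E 14" "6 F 14" "7 G 14" > anchors.cfg
$ helixweak weakspots --in bundle.pdb --anchors anchors.cfg
chain   donor_seqnum  generic  class    energy  mechanism        causal
B       22            2x58     missing  inf     proline          B:PRO:22
E       7             5x43     weak     -0.977  sidechain_clamp  E:SER:4
```

Reading the rows: in chain B the bond donated by residue 22 (generic
position 2x58) is *missing* — a proline donor has no amide proton, so the
energy is the +∞ sentinel.  In chain E the bond donated by residue 7
(5x43) still exists but is over-stretched to −0.98 kcal/mol, inside the
*weak* band (−1.2 … −0.5 kcal/mol); the causal residue is the serine at
position 4 whose OG clamps the acceptor carbonyl.  Helix C (the TM3
stand-in) reports nothing: TM3 carries no weakening motif.

The same bundle can be pushed through the full pipeline
(`helixweak run --config run.yaml`) to get per-structure weak-spot tables,
escape-channel verdicts and a cross-structure conservation profile, or
probed interactively (`helixweak hbonds`, `helixweak cavity`,
`helixweak gate`, `helixweak logo`, …).

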