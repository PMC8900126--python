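# cmcnano

Coarse-grained modelling toolkit for carboxymethyl-cellulose (CMC)
amphiphiles and their N-octylamide derivative (CMC-8): statistically
realistic substituted-chain generation, screened electrostatics, density-
specified multi-chain packing with self-assembly cluster detection, and the
two bespoke assay computations (critical aggregation concentration and
amide degree of substitution).

## What it does

- **composition** — enumerates the 27-state monomer library (ring positions
  2/3/6, each OH / carboxymethyl / octyl-amidated carboxymethyl), reconciles
  the published positional and substitution-class marginals for DS ≈ 0.9
  CMC into a single samplable 8-pattern distribution by constrained least
  squares, and generates seeded chains with exact-count enforcement
  (900 CM per 1000-mer, 200 amidated at the default 200/900 fraction;
  100-mers carry −90 e as CMC, −70 e as CMC-8).
- **structure** — freely-rotating-chain bead embedding (one backbone bead
  per monomer, charge/alkyl side beads) and persistence-length estimation
  from tangent correlations.
- **fields** — linearized Debye–Hückel screened-Coulomb potential on a
  regular grid (εr = 80, I = 0.1 M defaults), negative-potential hotspot
  detection, greedy Zn²⁺ placement with per-hotspot capacities.
- **assembly** — seeded rejection packing of conformers into a periodic
  cubic box, bulk density under sodium-salt or free-acid mass conventions,
  hydrophobic (alkyl) and acidic (carboxylate) cluster detection with
  minimum-image distances; acidic clusters 10–15 Å from an alkyl cluster
  are flagged as candidate Zn²⁺ binding sites.
- **assays** — CAC as the intersection of a two-line breakpoint fit to a
  pyrene I3/I1 titration curve, and amide-DS inversion of the molar N/C
  ratio from TOC/TN elemental readings.
- **synthetic** — seeded generators (titration curves, elemental readings,
  planted cluster fixtures) that emit a `.truth.json` sidecar so every
  recovery test reads ground truth from the sidecar only.

## CLI

All subcommands take `--seed` where randomness is involved and write a
`<output>.config.yaml` sidecar echoing the effective configuration.

```sh
cmcnano fit-dist --out dist.json
cmcnano generate --length 1000 --seed 1 --out chain.json
cmcnano stats chain.json --out stats.tsv
cmcnano sites chain.json --rule tri_full --out sites.tsv
cmcnano embed chain.json --lp 5 --out conf.xyz
cmcnano grid chain.json --spacing 0.2 --out pot.dx        # OpenDX output
cmcnano hotspots pot.dx --threshold -10 --out hotspots.tsv
cmcnano zn-place pot.dx --max-ions 8 --out zn.tsv
cmcnano pack --length 100 --n-chains 27 --box-edge 150 --seed 2 --out packed.pdb
cmcnano clusters packed.pdb --box-edge 150 --out clusters.tsv
cmcnano simulate pyrene --seed 3 --out titration.csv
cmcnano cac-fit titration.csv --out cac.json
cmcnano ds-estimate --toc 469.2 --tn 10.55 --out ds.json
```

## Units and conventions

Conformer coordinates are in nm; packed systems, PDB files and cluster
cutoffs in Å; potentials in mV. Monomer masses default to the sodium-salt
convention (charged carboxymethyls counted with a Na⁺ counter-ion); the
free-acid convention is available everywhere a mass enters. Virtual bond
length defaults to 0.515 nm per glucose unit.
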