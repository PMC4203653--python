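# selsites

Integrate, filter and structurally map site-level selection analyses.

Molecular-evolution studies of protein-coding genes routinely combine three
programs to identify codon sites under natural selection: **codeml** (PAML
site models, with likelihood-ratio tests and Bayes Empirical Bayes site
identification), the **Datamonkey** server's site methods (SLAC, FEL, REL,
MEME, FUBAR) and **TreeSAAP** (radical changes in 31 physicochemical
amino-acid properties, scored in magnitude categories 1–8 with Z-statistics).
Each program emits its own text tables, and combining them — applying each
method's significance cutoff, intersecting the site lists, counting radical
property changes per site and painting the consensus sites onto a protein
structure — is tedious and error-prone by hand. `selsites` is a scriptable
library and CLI that automates exactly that integration step. It does **not**
re-run the selection analyses; it consumes their result files.

## The statistics it applies

* **LRT**: for the nested site-model pairs (M0, M3), (M1a, M2a), (M7, M8) the
  statistic 2·(ℓ₁ − ℓ₀) is compared to χ²_df with df = np₁ − np₀ (2 for
  M1a/M2a and M7/M8, 4 for M0/M3). A negative difference is clamped to zero.
* **Per-method site filters**, boundary-inclusive, with the standard
  defaults: p ≤ 0.1 (SLAC, FEL, MEME), posterior ≥ 0.9 (FUBAR), Bayes factor
  ≥ 50 (REL), BEB posterior ≥ 0.95 (codeml M2a/M8). Direction of selection
  for the rate-based methods comes from the sign of dN − dS (β − α).
* **TreeSAAP summaries**: properties in magnitude categories 7–8 with
  |Z| ≥ 3.09 (one-tailed p = 0.001) build the Properties-By-Site (PBS) and
  Properties-By-Range (PBR) tables; negative selection is Z ≤ −3.09.
* **Merged Results (MR) table**: union of sites over sources with a
  common-sites flag (detected by every supplied source) and a per-site count
  NP of radical properties, classified red (NP < 2), green (2 ≤ NP ≤ 5),
  blue (NP > 5) for 3D rendering.
* **Structure mapping**: the translated reference sequence is globally
  aligned (BLOSUM62, gap open 11 / extend 1) against the chain sequence taken
  from a PDB file's coordinate records; sites inherit author residue numbers
  and are colored via generated PyMOL/Jmol scripts.

## Worked example

The package ships seeded generators for every input family (codeml result
files, the five method tables, a TreeSAAP Evpthwy/Substs tree, codon
alignments, a toy PDB), with known selected sites planted. The `demo`
subcommand generates such a workspace and runs the whole pipeline on it:

```sh
$ selsites demo --seed 0 --out-dir demo_run
common sites: 110, 172, 202, 231
```

Those four sites were called by **all** of SLAC, FEL, REL, MEME, FUBAR, the
M8 BEB analysis and TreeSAAP, so they carry the strongest consensus evidence
of positive selection. The MR table (`demo_run/merged_results.csv`) begins:

```
Codon,Datamonkey,PAML M8Site,TreeSAAP,Common Sites,Total,Properties (7-8) (+),ColorClass
90,False,True,True,False,3,Average number of surrounding residues (+); ...,green
110,True,True,True,True,6,Beta-structure tendencies (+); ...,blue
172,True,True,True,True,4,Buriedness (+); Composition (+); ...,green
202,True,True,True,True,1,Hydropathy (+),red
231,True,True,True,True,2,Compressibility (+); ...,green
```

Site 90 was found by codeml and TreeSAAP but not by the Datamonkey consensus,
so its common flag is false; site 110 changes six radical properties (NP = 6,
blue class), site 202 only one (red class). Running the LRT stage on the
generated M7/M8 pair:

```sh
$ selsites paml demo_run/workspace/codeml_M7.txt demo_run/workspace/codeml_M8.txt --out-dir paml_out
INFO LRT M7 vs M8: 2dL=24.6422 df=2 p=4.46e-06 -> significant
```

i.e. the selection model M8 fits significantly better than its null M7
(2Δℓ = 24.64, df = 2, p ≈ 4.5·10⁻⁶), so the BEB sites may be trusted.
The remaining subcommands (`datamonkey`, `treesaap`, `merge`, `map3d`,
`filter-aln`, `fixtures`) expose each stage individually; `selsites --help`
lists them.

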