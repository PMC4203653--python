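# Methods

## What the package computes

`selsites` integrates the site-level outputs of three families of selection
analyses on protein-coding genes and carries the consensus through to a 2D
alignment view and a 3D structure coloring. The stages are independent and
composable; the `pipeline.run_integration` helper chains them.

### Likelihood-ratio tests on codeml site models

The parser extracts, from a codeml main result file, the log-likelihood ℓ and
the number of free parameters np from the `lnL(ntime: .. np: ..):` line, the
model identity from the `Model N:` header, the maximum-likelihood parameter
estimates (κ, ω values, class proportions, beta shape p/q) and the Bayes
Empirical Bayes (BEB) positively-selected-site block of the alternative
models M2a and M8. Only site models are in scope (M0, M1a, M2a, M3, M7, M8);
branch and branch-site models are not parsed.

For a nested pair the LRT statistic is 2·(ℓ_alt − ℓ_null), clamped at zero:
the alternative nests the null, so a negative difference can only be
optimizer noise and clamping avoids p > 1. Degrees of freedom are computed
from the parsed np values rather than hard-coded; with canonical codeml
parameterizations this yields df = 2 for M1a vs M2a and M7 vs M8 and df = 4
for M0 vs M3, which the tests assert on generated files. The p-value is the
χ² upper-tail probability (scipy). BEB significance is recomputed from the
numeric posterior against the cutoff (default 0.95, the level codeml marks
with `*`); the asterisks themselves are ignored. The significance levels
offered for the LRT are 0.05 (default), 0.01, 0.001, or any user value.

### Datamonkey method tables

Each of SLAC, FEL, REL, MEME and FUBAR exports one delimited per-site table.
Header wording has drifted across server versions, so parsing goes through a
**dialect**: a mapping from logical roles (site, p-value, synonymous and
nonsynonymous rates, per-direction Bayes factors, per-direction posteriors)
to concrete header names. The built-in dialects describe one frozen layout —
the one the package's own fixture writers emit — and a user-supplied dialect
adapts any other export. Filtering rules, all boundary-inclusive:

| method | statistic | default cutoff | direction |
|--------|-----------|----------------|-----------|
| SLAC   | p-value   | 0.1            | sign of dN − dS |
| FEL    | p-value   | 0.1            | sign of β − α |
| MEME   | p-value   | 0.1            | positive only (episodic) |
| REL    | Bayes factor | 50          | per-direction BF column |
| FUBAR  | posterior | 0.9            | per-direction posterior, sign from β − α |

Boundary inclusivity matters: a REL site with BF exactly 50 passes. Rows
where the rates tie are excluded from both directions. The *common sites*
operation intersects the significant-site sets of all provided methods
(ascending order); with a single method it degenerates to that method's set.
The dataset-size guidance (`recommend_methods`) encodes the published usage
bounds: SLAC above 40 sequences, REL for 20–40, FEL above 50, FUBAR for very
large datasets, MEME with no stated bound.

### TreeSAAP property results

TreeSAAP bins the effect of each non-synonymous change on 31 physicochemical
properties into magnitude categories 1–8 and reports per-property Z-scores.
The 31-name registry ships as a data file (`data/aa_properties.txt`) with
case- and whitespace-insensitive lookup, so individual names can be corrected
without code changes; it includes hydrophobicity, polarity, solvent
accessible reduction ratio and buriedness among the 31.

TreeSAAP's legacy on-disk grammar varies by version, so this package defines
a documented TSV dialect (one file per property, a `# property:` header,
comment lines allowed) that the fixture writer emits and the parser consumes;
adapting a real TreeSAAP output tree means converting it to this dialect.

The **PBS** (Properties By Site) table keeps records in categories 7–8 (the
most radical changes) with |Z| ≥ 3.09 — the upper 0.001 quantile of the
standard normal; the *negative*-selection rule is Z ≤ −3.09, i.e. the cutoff
is applied to the magnitude with the sign giving direction. Per codon, the
table counts *distinct* qualifying properties: a property significant on two
branches at one codon counts once. The PBS statistics table counts, per
property, the number of codons at which it qualifies, so its column sum
equals the sum of PBS totals (a conservation law the tests check on 200
random record sets). The **PBR** table is the per-window analogue computed
from the Evpthwy sliding-window series, with positive and negative property
lists split; window plot data (midpoint vs Z per category) export as TSV for
any plotting tool.

### Merged results and the color scheme

The MR table takes the union of (i) M8 BEB sites (M2a optionally instead),
(ii) the Datamonkey common-sites set and (iii) PBS codons; `common` is the
conjunction of presence over the sources actually supplied (at least two
required). The per-site radical-property count NP is copied from PBS (zero
when absent, so codeml/Datamonkey-only sites still render) and classified:

* red — NP < 2
* green — 2 ≤ NP ≤ 5 (both boundaries green)
* blue — NP > 5

### Alignment handling and structure mapping

All user-facing coordinates are 1-based codon positions, matching codeml and
Datamonkey numbering. FASTA I/O uses Biopython; the PHYLIP dialect is the
relaxed *sequential* layout PAML accepts (names up to 50 characters,
whitespace-delimited), implemented directly because the interleaved/strict
writers of general libraries do not produce it. The alignment filter either
highlights masked codon columns under a marker row or keeps only those
columns, each labeled with its original position; labels round-trip through
the CSV export. `column_to_reference_position` converts alignment columns to
ungapped reference codon indices (None over reference gaps), and
`translate_reference` produces the ungapped protein (standard genetic code;
terminal stop dropped, internal stop an error unless overridden).

For 3D mapping the chain sequence is read from the PDB **coordinate records**
(gemmi), not SEQRES: a site mapped to an unresolved residue could not be
colored anyway. The reference protein is globally aligned to the chain with
BLOSUM62, affine gaps, open 11 / extend 1 (configurable; end gaps are
penalized, which keeps deletions located where they occur). The mapping is a
monotone one-to-one pairing by construction; sites opposite gaps are listed
as unmapped, and an aligned-identity fraction below 0.30 (configurable)
raises a warning. Viewer scripts (PyMOL `.pml`, Jmol `.spt`) are
deterministic: fixed setup, then one select+color command per class with
residues ascending, selecting on author residue numbers.

## The synthetic-data generators

The fixture writers exist so that every parser and the whole pipeline are
testable offline, without running codeml, HyPhy or TreeSAAP. A `FixtureSpec`
plants sites: for each planted site it lists the methods that must call it,
the direction of selection and (for TreeSAAP) the number of radical
properties. Planted statistics are drawn on the significant side of the
default cutoffs (e.g. p in [0.005, 0.09], BF in [55, 800], posterior in
[0.91, 0.995], |Z| in [3.3, 6.0]); all other sites fail with a wide margin
(e.g. p ≥ 0.3, BF ≤ 20, posterior ≤ 0.45, |Z| ≤ 2.5, or a radical Z placed in
a category below 7). The wide margins make recovery exact rather than
probabilistic — that is deliberate: the fixtures test the integration
machinery, not the statistical power of the upstream methods. The same seed
yields byte-identical files (per-file generators derive their streams from
the seed and a stable label).

Default generator conditions: alignments of 25 sequences × 300 codons (the
demo), codeml likelihoods placed so every LRT is significant with canonical
np differences, sliding windows of width 20 at step 10. The demo plant puts
sites 110, 172, 202 and 231 in *every* method — so the cross-method common
set is exactly those four — with property counts 6, 4, 1 and 2, exercising
all three color classes, plus extras detected by only one or two methods and
one negatively selected site.

What the generators do **not** emulate: real sequence evolution (fixtures
plant result statistics, not alignments with genuine selection signal),
codeml's full result-file verbosity, real Datamonkey header variation (one
frozen dialect is emitted), TreeSAAP's legacy layouts, multi-chain or
altloc-rich PDB files. Passing tests therefore demonstrate that parsing,
filtering, intersection, merging, classification and mapping are correct on
well-formed inputs; they say nothing about the biological sensitivity of the
upstream methods, and adapting to a new export layout may require a custom
dialect.

## Numerical and design choices

* χ² survival and the normal quantile are scipy's (`chi2.sf`, `norm.isf`);
  tests verify them against trapezoid integration of the density and
  round-trip identities.
* All threshold comparisons are inclusive; filters are monotone in their
  thresholds (property-tested).
* `common` in the MR table is defined over supplied sources only, so a
  two-source merge is meaningful.
* Rate ties give no direction and are excluded from both signs.
* Problem sizes in the test suite and the acceptance script (50 seeded
  pipeline workspaces, 100 random indel structures, 200 random property
  record sets) were chosen as the smallest sizes that exercise every code
  path and edge case convincingly.

## Known limitations

* codeml branch/branch-site models, NEB sites and the auxiliary rst files are
  out of scope.
* No network features: structures are local PDB files (no mmCIF yet), and
  homology modeling is not provided; `structmap` documents where a fetcher
  could plug in.
* The Datamonkey parser handles the server-era CSV tables, not HyPhy's JSON.
* Insertion codes are carried through mapping and scripts but the toy PDB
  writer never generates them, so they are exercised only at the unit level.
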