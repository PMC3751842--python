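# plastomics

Comparative chloroplast-genome analysis for closely related plants, with a
plastome-evolution simulator that gives every stage a verifiable ground
truth.

Chloroplast (cp) genomes of most angiosperms are ~150-160 kb circles with a
quadripartite layout: a large and a small single-copy region (LSC, SSC)
separated by two ~26 kb inverted repeats (IRa, IRb). Between congeneric
species the sequences are highly conserved (p-distances around 1e-3), so
resolving species relationships needs genome-scale data: which regions vary,
where the divergence hotspots are, and how much phylogenetic signal each
genomic partition carries. `plastomics` implements that analysis as a
pipeline:

* **Structure** — detect the LSC/IRb/SSC/IRa layout (seed-and-extend over
  the reverse complement), report genes straddling the four IR junctions,
  base/coding composition, and the gene inventory (unique vs IR-duplicated
  genes, intron counts).
* **Repeats** — find all direct and inverted repeat pairs >= 30 bp at >= 90%
  ungapped identity (IR masked), merge overlapping hits, and classify them
  as tandem, dispersed, palindromic (inverted, gap <= 3 kb) or
  gene-similarity, with tandem taking priority; an exhaustive brute-force
  scanner serves as an oracle.
* **Divergence** — extract every homologous region (coding exons, introns,
  intergenic spacers), align them with a built-in progressive affine-gap
  aligner, compute the percentage of variable characters per region, flag
  hotspots (> 1% variable), pairwise p-distances excluding indels
  (p = differing sites / compared sites), and per-partition tallies of
  transitions, transversions and indel events.
* **Phylogenetics** — partitioned maximum parsimony on six datasets
  (complete genome, coding exons, LSC, SSC, IR, introns+spacers): Fitch
  counting, exhaustive / branch-and-bound / TBR-heuristic searches,
  nonparametric bootstrap, and the consistency, retention and rescaled
  consistency indices (CI = sum m_i / sum s_i,
  RI = (sum g_i - sum s_i)/(sum g_i - sum m_i), RC = CI x RI).
* **Simulator** — generates annotated quadripartite plastomes (123 unique
  genes, 23 duplicated in the IRs; AT ~62.7%) with planted repeats and
  evolves them along a known 11-taxon tree with region-specific rates
  (SSC > spacers/introns > LSC > coding > IR), a transition bias, rare
  indels, and a conspecific pair differing at exactly 16 sites — so
  boundary detection, repeat recovery, hotspot calls, variant tallies and
  tree inference can all be checked against planted truth.

See `docs/methods.md` for models, parameter defaults, and numerical choices.

## Worked example

The numbered scripts under `analysis/` run each stage on the simulated
study system and write tables under `results/`:

```bash
python analysis/01_simulate.py 1
python analysis/02_structure.py 1
python analysis/03_repeats.py 1
python analysis/04_divergence.py 1
python analysis/05_phylogeny.py 1 200
```

Output (seed 1):

```
seed 1: 11 genomes of 156,572 bp (146 gene copies), 2640 mutation events
planted repeats: 45; conspecific pair differs at 16 sites by construction

boundary recovery: 11/11 genomes exact
ancestor composition: AT 62.6%, GC 37.4%, coding 60.6% (protein 52.90, tRNA 1.92, rRNA 5.78)
gene inventory: 146 functional copies = 123 unique + 23 IR-duplicated;
    classes {'protein': 81, 'tRNA': 38, 'rRNA': 4}; 18 intron-containing genes

planted repeats recovered on ancestor: 45/45
pooled over 11 genomes: 495 repeats (tandem 42.2%, dispersed 33.3%,
    palindromic 20.0%, gene-similarity 4.4%)

289 homologous regions; 46 exceed 1% variable characters (top: trnA-UGC_exon2 at 3.33%)
p-distances (ingroup): all 0.001435, between-species 0.001501, within-species 0.000123
conspecific pair differs at 16 sites (planted: 16)
variant tallies equal realized event counts exactly: True

complete         len= 2608 PI= 616 clades 5/5 min BS 100.0
coding_exons     len= 1277 PI= 301 clades 5/5 min BS 100.0
LSC              len= 1755 PI= 408 clades 5/5 min BS 100.0
SSC              len=  687 PI= 171 clades 5/5 min BS 87.5
IR               len=  166 PI=  37 clades 5/5 min BS 59.5
introns_spacers  len= 1331 PI= 315 clades 5/5 min BS 100.0
```

Reading this: every genome's IR boundaries were recovered to the base pair;
the genomes carry the canonical plastome inventory (146 gene copies = 123
unique + 23 IR-duplicated); the repeat scanner recovers the planted
tandem-heavy mixture exactly; within-species divergence sits far below
between-species divergence, with the conspecific pair at its planted 16
differing sites; and variant tallies equal the simulator's realized event
counts exactly. Every partition recovers the true ingroup topology, and
bootstrap support rises with partition size — the short, conserved IR
partition resolves the tree weakly (minimum support 59.5) while the
complete genome saturates at 100.

The same stages run from the command line (`plastomics all --outdir run
--seed 1`, or `simulate` / `structure` / `repeats` / `hotspots` /
`distances` / `tree` individually; `--genbank-dir` switches from the
simulator to user-supplied annotated GenBank records, e.g. deposited cp
genomes with accession lists of your choosing).

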