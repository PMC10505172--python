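# phagescan

Analysis pipeline for discovering chemokine-binding peptide pharmacophores
from phage-display screens of tick-evasin-derived peptide libraries.

Tick evasins bind many CC- and CXC-chemokines at once, which makes them a
template for broad-spectrum anti-inflammatory peptides. One route to such
peptides is to deconstruct evasin proteins into overlapping hexadecapeptides
(16-mers), display them on phage, pan against a panel of chemokines in
parallel, and read out binding by deep sequencing. `phagescan` implements the
computational side of that workflow end to end:

* **Library design** — tile mature parent proteins into 16-mers overlapping
  by a single residue; add companions with every Cys mutated jointly to Ala
  and to Ser; design NNK saturation-mutagenesis libraries at the protein
  level; design maximally-scrambled controls (50 seeded shuffles, pick the
  maximal OSA string distance); back-translate each peptide into a 48-nt
  insert flanked by the cloning arms `GCAGCCTCTTCATCTGGC…GGTGGAGGATCCGGA`
  (81-mer oligos).
* **NGS counting** — join paired FASTQ mates by read id, require the demux
  motifs (`CTAGCGCT`, `CGCAGACG`) and both constant regions, reject
  mate-discordant / ambiguous / wrong-size (≠ 48 nt) inserts, translate and
  count only peptides present in the designed library.
* **Enrichment** — per peptide and chemokine, `log2E = log2(freq_out /
  freq_in)` with floor substitution of missing frequencies so no value is
  infinite; residue-level profiles `rlog2E` (sum of log2E > 0 of peptides
  overlapping a residue), rolling-median smoothing (k = 7), a
  distribution-free 95% CI of the protein-wide median, and regions of
  interest (ROIs) where the smoothed profile exceeds the CI's upper bound;
  promiscuity filtering (≥ 3 chemokines with log2E > 5) and mutational
  Δlog2E.
* **Scan statistics** — substitution classes (anionic E/D, cationic K/R,
  hydrophobic L/I/M/V, alanine, PAM250-conservative), seeded Monte-Carlo
  Dunnett many-to-one tests against the parental peptide, one-way ANOVA,
  migration-count normalisation (chemokine-alone median = 10000) and
  Spearman correlation of binding vs function.
* **Structure proximity** — aggregate docked pose ensembles
  (AlphaFold-Multimer confidences, AutoDock-CrankPep energies, or equally
  weighted NMR-restrained poses) into per-residue weighted proximity scores
  normalised to a maximum of 100, plus 5 Å proximal-contact profiles.
* **Synthetic data** — a seeded generator producing parent proteins with
  planted binding intervals, affinity-weighted three-round panning with
  multinomial read noise, amplicon FASTQ, and synthetic pose ensembles, with
  ground truth for recovery testing.

## Worked example

Simulate a small study (three evasin-like parents, three chemokines,
three panning rounds, 20k reads per sample), count one selected sample
against the input library, score enrichment and map ROIs:

```bash
phagescan simulate --out-dir sim --seed 4 --depth 20000
phagescan count --fastq1 sim/input_R1.fastq --fastq2 sim/input_R2.fastq \
    --library sim/library.tsv --sample-id input --out input.tsv
phagescan count --fastq1 sim/CK1_R1.fastq --fastq2 sim/CK1_R2.fastq \
    --library sim/library.tsv --sample-id CK1 --out ck1.tsv
phagescan enrich --input-table input.tsv --output-table ck1.tsv --out enrich.tsv
phagescan map-residues --enrichment-table enrich.tsv --library sim/library.tsv \
    --fasta sim/parents.fasta --out-profile prof.tsv --out-roi roi.tsv
head -3 roi.tsv
```

prints

```
parent_id	start	end
EVS1	45	72
EVS2	4	22
```

i.e. each parent shows one region of interest whose residues' smoothed
rlog2E exceeds the upper 95% CI bound of the protein-wide median. The
simulator's ground truth (`sim/truth.json`) planted the binding intervals at
EVS1 49–66 and EVS2 2–19: the detected ROIs recover them (with the expected
shoulder from 16-mer tiles that partially overlap the interval). The `count`
step reports `20000 reads counted over 823 peptides` for the error-free
input sample — every emitted read passes the demux/constant/size filters and
maps back to a designed peptide.

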