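# Methods

This note documents the models, conventions and numerical choices behind
`phagescan`, and what the synthetic-data generator does and does not
emulate.

## Library design

Parents are mature protein sequences (signal peptide removed, 20 standard
residues). Tiling produces every contiguous 16-mer, so a parent of length L
yields L − 15 wild-type tiles with 1-based start coordinates. Because
unpaired cysteines can impair phage display, each Cys-containing tile gets
two companions in which **all** Cys residues are replaced simultaneously —
one all-Ala, one all-Ser. Per-Cys single mutants are not generated: the
variants model a Cys-free version of the same tile, not a mutational scan,
and joint replacement is consistent with the printed Cys-to-Ala/Ser mutant
peptides of the exemplar region.

Back-translation uses a fixed one-codon-per-amino-acid table (the most-used
E. coli codon for each residue). Codon optimisation is deliberately out of
scope: downstream matching is at the translated-protein level, so any total,
stop-free table gives identical analysis results; the fixed table makes
oligos deterministic. Each 48-nt insert is flanked by the 18-nt and 15-nt
cloning arms, giving exactly 81-mer oligos.

The NNK saturation library is defined at the protein level: each of the 16
positions is substituted by every amino acid encodable by an NNK codon
(N ∈ {A,C,G,T}, K ∈ {G,T}; all 20 amino acids, with TAG the only stop,
which is dropped). Variants are deduplicated by sequence, and the parental
peptide is kept as the control member.

Scrambled controls draw `n_shuffles = 50` seeded random permutations and
keep the one with the maximal optimal-string-alignment (OSA) distance to the
wild-type; ties go to the first maximal candidate in generation order. OSA
(restricted Damerau–Levenshtein: insertions, deletions, substitutions,
adjacent transpositions, no substring edited twice) is implemented directly
as the O(|a|·|b|) dynamic programme and cross-checked in the tests against
an independent memoised recursive definition.

## Read processing

Counting assumes amplicon reads long enough to span the full insert
context, as produced by amplicon sequencing services; partial-overlap
merging is not implemented. Mate 2 is taken as the reverse complement of
the amplicon (standard Illumina paired-end orientation). Both mates must
contain the forward and reverse demultiplexing motifs and both constant
regions as **exact** substrings — the strictest reading of the filtering
protocol; the insert is delimited by the constant-region boundaries, which
fixes the translation frame. Each read pair receives exactly one status, in
the fixed order

`MISSING_DEMUX → MISSING_CONSTANT → MATE_MISMATCH → AMBIGUOUS_BASE →
WRONG_SIZE (≠ 48 nt) → NOT_IN_LIBRARY → OK`,

so attrition tables sum to the read-pair count. Matching against the
designed library is at the translated peptide level; synonymous codon
variants of the same peptide are pooled. Cloning efficiency is the fraction
of designed distinct peptides observed at least once in the input sample.

## Enrichment model

`E = freq_out / freq_in` per peptide and selection, reported as `log2E`.
Two floor rules keep every value finite:

* a peptide absent from the input library inherits the smallest positive
  input frequency of the experiment (one input pool plus its output
  samples);
* in mutagenesis screens, a peptide absent from an output sample inherits
  the smallest positive output frequency of that sample.

In plain selection screens a peptide absent from an output sample is
treated as *not recovered* and omitted for that sample (it is unknown
whether it was depleted or simply not sampled), which is also what keeps
the selection-mode table free of −∞.

Residue mapping sums `log2E` over all **enriched** entries (`log2E > 0`,
strict) of peptides overlapping a residue; mutant tiles map to the
coordinates of their originating wild-type tile. The profile is smoothed
with a centered rolling median, window 7 (the first and last 3 residues have
no smoothed value). The protein-wide median of rlog2E gets a
distribution-free CI from binomial order statistics: the symmetric interval
[x(d), x(n+1−d)] with the largest d whose Binomial(n, ½) coverage is at
least the level. This conservative exact interval can differ marginally
from interpolated variants of the same construction; n ≥ 6 is required at
the 95% level. ROIs are maximal runs of residues whose **smoothed** value
strictly exceeds the CI's upper bound (comparison on the raw profile is
available behind a flag; the smoothed choice follows the
smoothing-then-thresholding description of the mapping procedure).
Unsmoothed end residues never qualify, and no minimum ROI length is
imposed.

Promiscuity: peptides with `log2E > 5` (strict) in at least 3 chemokines.
Total log2E sums over whatever chemokine entries a peptide has; missing
combinations contribute 0. Δlog2E is mutant minus parental, per chemokine;
positive means improved binding.

## Scan statistics

Substitution classes: anionic {E, D}, cationic {K, R}, hydrophobic
{L, I, M, V}, alanine {A}; classes are evaluated independently, so one
substitution may carry several labels. "Conservative" means a strictly
positive Dayhoff PAM250 score (the matrix names no cut-off; > 0 is the
conventional reading). Group sizes exclude the wild-type identity of the
position, reproducing the design counts of a 24-chemokine scan: 48 for
anionic/cationic, 96 for hydrophobic, 72 where the wild-type residue is
itself hydrophobic (e.g. Leu), 24 for wild-type/alanine groups and for the
one-conservative-residue-per-position mode (`top_conservative=1`, highest
PAM250 score, alphabetical tie-break).

The Dunnett many-to-one comparison uses the pooled-variance model: t
statistics against the control, adjusted by P(maxⱼ |Tⱼ| ≥ |tᵢ|) under the
equicorrelated multivariate t implied by the group sizes. The adjustment is
evaluated by seeded Monte Carlo (default 200,000 draws), making adjusted
p-values deterministic given the seed and independent of any statistics
package's internals; with 200k draws the p-value noise is ≈ 0.001–0.002.
The same null sample yields family-wise critical values
(`dunnett_critical_value`), so large null-calibration experiments reuse one
draw instead of re-integrating per dataset. One-way ANOVA is the classical
between/within decomposition. Migration counts are scaled per experiment so
the chemokine-alone median is 10000 cells. Binding–function correlation is
Spearman's rank correlation with average ranks for ties.

## Pose-ensemble proximity

Interface residues are those with any atom (side chains and hydrogens
included when present) within 5 Å of the other chain, all-atom distances via
a k-d tree (brute-force-verified in tests). Pose weights: AlphaFold-Multimer
confidence as-is; AutoDock-CrankPep free energies negated and floored at 0
(energies are negative; lower energy ⇒ larger weight — the floor only
matters for unphysical positive energies); NMR-restrained poses weighted
equally at 1. The per-residue score sums the weights of poses in which the
residue is at the interface, then scales so the maximum is 100; no per-pose
weight normalisation happens before the final step, so the profile is
invariant to uniform weight rescaling. An ensemble with an empty interface
returns all zeros with a warning rather than dividing by zero. Residues are
keyed by PDB residue number; poses must share the target numbering
(ensembles are assumed pre-aligned — superposition is upstream
visualisation, not analysis). Contact profiles count cross-chain atom pairs
per binder residue (a residue-pair mode is available), averaged over poses;
bond-type classification is out of scope.

## Synthetic-data generator

The generator encodes the qualitative structure the analysis assumes, not a
biophysical simulation:

* **Parents** — seeded random sequences (default 3 parents, 90–130
  residues, 6–10 Cys) with one planted binding interval (default 18
  residues) per parent, shared across the chemokine panel and optionally
  carrying the conserved EEDDY/LTCYF motifs; Cys outside the interval.
* **Affinities** — `log a = α·overlap + β·cys_intact + ε`,
  `ε ~ N(0, σ)`; defaults α = 6 ln 2, β = 2 ln 2, σ = 0.5, i.e. a 64-fold
  affinity span between fully overlapping and non-overlapping tiles and a
  4-fold wild-type advantage over Cys-mutant tiles — large enough to be the
  dominant signal, small enough that multinomial noise matters at realistic
  depth.
* **Panning** — deterministic proportional enrichment `p ← p·a` per round
  (default 3 rounds), multinomial sequencing noise of the requested depth
  (default 200,000 reads, a typical amplicon-service yield) at the input
  pool and final round only. This is the simplest model in which expected
  enrichment is monotone in affinity; phage amplification noise between
  rounds is intentionally not modelled (an option hook exists).
* **Reads** — one pair per counted molecule, insert wrapped in the true
  demux/constant context (206-nt amplicon), mate 2 reverse-complemented,
  seeded per-base substitution errors, constant base quality.
* **Poses** — an extended pseudo-backbone target and a binder placed 4 Å
  off the designated epitope, rigid per-pose displacement ~ N(0, jitter),
  raw scores improving as displacement shrinks.

All randomness flows from one master seed through named substreams, so each
stage is independently reproducible and FASTQ/PDB outputs are byte-identical
across reruns.

Consequently, passing recovery tests show that the pipeline inverts its own
generative assumptions — exact filtering round-trips, ROI detection
recovering planted intervals (the detected ROI systematically carries a
shoulder of up to 15 residues where partially overlapping tiles spill
enrichment past the interval edge), enrichment tracking latent affinity, and
scan statistics flagging planted key positions. They do not show robustness
to features of real screens that are not modelled: amplification bias and
jackpot effects between rounds, PCR chimeras, quality-correlated errors,
cross-reactive baits, or peptides whose display level differs from their
affinity.

## Problem sizes

The test suite and the acceptance script run the recovery experiments at 2
parents × 3 chemokines × 200k reads × 10 seeds (end-to-end through FASTQ),
the saturation-scan experiments at 24 chemokines × 100k reads, Dunnett
calibration at 200k Monte-Carlo draws and 1000 null datasets — sizes chosen
to match the study conditions while keeping a desk-scale run in minutes.
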