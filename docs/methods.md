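# Methods

## Clone definition and ingestion

A clonotype is the set of cells carrying an identical CDR3 amino-acid
sequence on one chain; the clone key is (chain, cdr3_aa). V and J gene
calls and the distinct nucleotide CDR3s behind a clone are recorded but
do not split it — nucleotide variation within an amino-acid clone is
the object of the convergence analysis, not a clone boundary. TRA and
TRB are analysed as separate repertoires throughout.

Ingestion retains a contig only if it is productive, on a TRA/TRB
locus, carries non-empty nucleotide and amino-acid CDR3s with
`len(nt) = 3·len(aa)`, contains only A/C/G/T, and translates exactly to
the annotated amino-acid sequence under the standard genetic code
(internal stops are rejected; productive junctions are stop-free).
Every drop is counted by reason. Cells with multiple contigs on one
locus keep the highest-UMI contig, ties broken by lexicographically
smallest nucleotide sequence — the dominant single-cell convention,
chosen for determinism. No paired-chain requirement is imposed:
barcodes with only one chain participate in all single-chain analyses
and are excluded (and counted) only from α–β pairing. All reported
CDR3 coordinates are 1-based inclusive.

## Hydrophobicity

The score of a sequence is the arithmetic mean of per-residue hydropathy
values. Two scales are built in: Kyte-Doolittle (1982 values, I = 4.5,
R = −4.5) and the Wimley-White water→POPC interface scale (kcal/mol,
pH-7 charge states). The published Wimley-White orientation is
negative-favourable, so its values are negated at load; after loading,
both scales read higher = more hydrophobic, and they rank hydrophobic
vs hydrophilic homopolymers concordantly. Kyte-Doolittle is the
default for headline statistics, with Wimley-White reported alongside.
The raw published values remain available on the scale object, and a
user scale can be loaded from a two-column text file.

The mid-hypervariable region is the CDR3 after trimming `trim_n`
residues from the N-terminus and `trim_c` from the C-terminus, both
defaulting to 3: this removes the conserved cysteine-anchored motif and
the J-encoded C-terminal residues, isolating the junctional loop apex.
The trim widths are free parameters, echoed in every output table, and
any reproduction claim must state them; whether a symmetric width of 3
matches any particular published analysis cannot be verified from text
alone. A sequence no longer than the combined trims has an *empty* mid
region, which is treated as missing data (NaN), never as a zero score —
a zero is a legitimate mean and would bias group comparisons.

## Expansion, dominance and sharing

The clonal expansion index of a clone is
`100 · freq_case / freq_control`. A pseudocount (default one cell) is
substituted for a zero cell count only, so clones observed in both
conditions are compared on raw frequencies, equal frequencies give
exactly 100 for any pseudocount, and the pseudo-free index is
antisymmetric under condition swap (`idx(a→b)·idx(b→a) = 10⁴`). The
raw (pseudo-free) index is emitted alongside and is undefined for
clones absent from the control.

Copy-number bins default to {1, 2, 3–5, 6–10, >10} cells and a clone is
called *expanded* at ≥2 cells in a condition; both are configurable,
as no canonical values exist. Dominance per sample is the
Berger-Parker index `max(nᵢ)/N`, computed per sample and compared
across condition groups. The headline case/control comparison —
mid-region hydrophobicity of expanded clones — is made at the clone
level (each clone contributes one value per condition in which it is
expanded), because clone-level values are exchangeable draws under the
null; a cell-weighted comparison duplicates values within large clones
and is anticonservative.

Sharing matrices count cells per clone × phenotypic subset (or any
other grouping column); a clone is shared when present in ≥2 groups and
cross-lineage when its subsets span both CD4- and CD8-prefixed labels,
with lineage read from the label's first token.

## Codon redundancy (convergent recombination)

Clones are classed by their number of distinct nucleotide CDR3s:
CrE-1, CrE-2, CrE-3 with the top class open-ended (k ≥ 3), so class
percentages always sum to 100 over three classes; the bin edge is
configurable. Classification is per condition by default, with pooled
(all-cells) scope available, and both clone-weighted and cell-weighted
percentages are emitted since either weighting is defensible.
Hydrophobicity is compared across classes within mid-length strata
(Kruskal-Wallis; strata with fewer than two classes are flagged, not
tested). The multi-V table lists converging clones whose variants use
≥2 distinct V genes. α–β pairing reports, for each expanded β clone,
the multiset of α partners with cell (not distinct-sequence) counts,
plus the Spearman association of β and α mid-lengths over paired cells.

## Statistics

Two-sample comparisons use the two-sided Kolmogorov-Smirnov test
(scipy's exact/asymptotic switching) or Mann-Whitney U; U follows the
U₁ convention (pairs won by the first sample), documented in the API.
Single-feature ROC is computed directly on scores — for one predictor,
logistic regression is monotone in the score, so the ranking and hence
the ROC are identical — with AUROC as the tie-corrected rank statistic
and its p-value from the normal approximation to U. The identity
AUROC = U/(n₊·n₋) is enforced by test to 1e−12 across random data with
ties. Benjamini-Hochberg q-values are emitted as a clearly-labelled
extension beyond the per-comparison p-values. Spearman confidence
intervals use the Fisher-z approximation.

## Synthetic repertoire generator

The generator emulates exactly the statistical features the analyses
measure, with planted ground truth; it does not model V(D)J generation
probabilities (no IGoR/OLGA-style inference) or sequencing error.

**Skeletons.** A clone's CDR3 is V stub + random junction insert +
J stub. The stubs are short invented sequences of exactly 3 aa: V stubs
begin with the conserved cysteine (e.g. `TGTGCCAGC` → CAS) and J stubs
end on phenylalanine, so every CDR3 is canonical C…F. With the default
trims (3, 3) the mid region is therefore purely junctional — insert
residues drawn uniformly over the 20 amino acids with uniform synonymous
codons — which keeps the mid-hydrophobicity distribution identical
across length modes. Two TRB V stubs (TRBV19, TRBV6-5) encode the same
amino acids through different codons, letting convergence arise through
distinct V segments. Target amino-acid lengths are drawn from a
per-condition mixture (`length_modes`; case default 12/15 bimodal,
control 15), jittered ±1 with probability 0.1 per side; the insert
length is derived from the target, and infeasible mode/stub
combinations raise.

**Sizes and coupling.** Clone sizes are zipf draws (default exponent
2.5, capped at 10% of the condition's cells) accumulated to the exact
cell budget. In each condition the drawn size multiset is allocated to
skeletons by weighted sampling without replacement with weights
`exp(β·hydro_mid)`, implemented by the Gumbel-top-k trick (sort by
`β·h + Gumbel noise`, assign sizes in decreasing order). This couples
copy number to mid-region hydrophobicity (case default β = 0.5) while
leaving the marginal clone-size law *identical* across conditions —
so the clone-size power law is verifiable against the planted CDF, and
with β = 0 the case/control comparison is an exact null. A
deliberate consequence is that the generator plants no
condition difference in dominance (Berger-Parker) or in total expansion,
only in *which* clones expand.

**Convergence and pairing.** An expanded clone gains 1–2 extra
synonymous nucleotide variants with per-condition probability
(`convergence_rate`, default case 0.35 / control 0.15 to plant the
case enrichment of converging clones), and with probability
`multi_v_prob` one variant swaps to the synonymous alternative V stub.
Cells sample variants with the primary variant weighted double. Every
cell receives a TRA partner whose target length tracks the β length
with slope `pairing_coupling` (default 0.6) plus unit Gaussian noise;
a clone has a secondary α chain with probability 0.15. About 5% of
case clones reuse control skeletons (public clones) so cross-condition
expansion indices are defined on a shared subset. Samples (3 per
condition), subsets (five CD4/CD8 labels with fixed proportions),
barcodes and shifted-geometric UMI counts complete the per-cell
records. All randomness flows from one `numpy` Generator seeded by
`SimulationConfig.seed`; output is byte-deterministic.

**What the generator does not emulate.** Realistic V/J germline
diversity and usage bias, thymic selection, sequencing/assembly error,
condition differences in overall clonality, and non-uniform amino-acid
composition of junctions. Passing tests therefore demonstrate the
correctness and calibration of the pipeline's statistics, not that any
particular biological effect exists in real cohorts.

## Problem sizes and numerical choices

Simulation studies in the test suite use 2,000 cells per condition
(roughly 1,100 TRB clones), with 100 replicate seeds for the
coupling-recovery check and 200 for the β = 0 type-I calibration,
sizes at which the planted β = 0.5 coupling is detected in ≈99% of
replicates while each replicate runs in well under a second. Unit
fixtures use 100–150 cells per condition. Vectorised hydropathy
scoring is checked against plain per-residue summation to 1e−12;
discrete goodness-of-fit of clone sizes uses a randomised
probability-integral transform before the KS comparison (a step-CDF
fed to a continuous KS test would be grossly miscalibrated). Report
bundles sort all tables, fix float formats, and serialise JSON with
sorted keys so repeated runs are byte-identical.
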