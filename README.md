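# tcrphys

Physicochemical analysis of single-cell TCR CDR3 repertoires.

T cells recognise antigen through the hypervariable CDR3 loops of the
T-cell receptor, and the physical character of the CDR3β loop — in
particular its length and the hydrophobicity of its junction-encoded
mid-region — has been linked to self-reactive and pathogenic T-cell
behaviour, including the cardiac immune-related adverse events seen
under immune-checkpoint-inhibitor therapy. `tcrphys` implements the
repertoire-level analyses needed to probe that link in single-cell
V(D)J data:

* **Clone construction** from 10x-style per-contig CSVs or AIRR
  Rearrangement TSVs: productive TRA/TRB contigs only, translation
  validated against the annotated amino-acid CDR3, one contig per
  (barcode, chain), clones keyed by identical CDR3 amino-acid sequence
  per chain.
* **Hydrophobicity scoring**: mean per-residue hydropathy of the full
  CDR3 or of its mid-hypervariable region (default trims of 3 residues
  from each end remove the conserved C-anchored N-terminal motif and the
  J-proximal residues), on the Kyte-Doolittle scale and the
  Wimley-White interface scale (sign-flipped at load so both scales read
  higher = more hydrophobic). For a CDR3 `s` of length `L`,
  `H(s) = (1/L) Σᵢ h(sᵢ)`.
* **Clonal expansion and dominance**: per-clone expansion index
  (case:control frequency ratio × 100, with a one-cell pseudocount
  rescuing clones absent from one condition), Berger-Parker dominance
  `max(nᵢ)/N` per sample, copy-number-binned hydrophobicity summaries
  and the Spearman correlation between copy number and mid-region
  hydrophobicity.
* **Codon-redundancy (convergent recombination) analysis**: clones
  backed by k distinct nucleotide CDR3s are classed CrE-1 (k = 1),
  CrE-2 (k = 2) or CrE-3 (k ≥ 3); class percentages per condition
  (clone- and cell-weighted), hydrophobicity by class within mid-length
  strata, convergent clones recombined through ≥2 V genes, and α-chain
  pairing of expanded β clones.
* **Cross-subset sharing**: clone × phenotypic-subset count matrices
  with shared and cross-CD4/CD8-lineage flags.
* **Statistics**: two-sample Kolmogorov-Smirnov and Mann-Whitney
  comparisons, Kruskal-Wallis across CrE classes, Spearman correlations,
  and single-score ROC where AUROC = U/(n₊·n₋).
* **A synthetic V(D)J repertoire generator** with planted ground truth
  (power-law clone sizes, hydrophobicity-coupled expansion, bimodal
  length mixtures, synonymous convergence, β–α pairing), so the whole
  pipeline is testable without access-restricted patient data.

## Worked example

The numbered scripts under `analysis/` run the full study on a
simulated cohort (2,000 cells per condition, seed 0). `python
analysis/01_simulate.py` writes the raw contig files, then
`analysis/03_score_hydrophobicity.py` prints:

```
expanded-clone mid hydrophobicity (TRB, Kyte-Doolittle): case mean 0.043 vs control -0.445; KS D = 0.209, p = 8.59e-06
case full-CDR3 top-2 length bins: [12, 15]
```

Expanded case clones are markedly more hydrophobic in the mid-region
than expanded control clones (a Kyte-Doolittle shift of ~0.5 units,
two-sample KS p < 1e-5), and the case length histogram is bimodal with
modes at 12 and 15 amino acids — the planted disease-condition
signature. `analysis/04_clonality_convergence.py` adds the expansion
and convergence view:

```
Spearman(copy number, hydro_mid): rho = 0.273, p = 1.79e-20, 95% CI (0.217, 0.326)
codon-redundancy class percentages (TRB, clone-weighted):
cre_class  CrE-1  CrE-2  CrE-3
case       93.73   5.64   0.63
control    97.65   1.90   0.45
```

i.e. hydrophobicity rises with clonal copy number, and converging
clones (CrE-2/3) are enriched in the case condition.

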