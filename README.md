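# cicerchip

SNP-array candidate selection, Axiom-style genotype quality control,
recombinant-inbred-line (RIL) linkage mapping and ICIM-ADD QTL scanning —
a tested, reusable re-implementation of the computational pipeline behind a
high-density chickpea genotyping array, exercised end to end on a synthetic
data generator with known ground truth.

## Who this is for

Breeders and genomicists who design genotyping arrays from resequencing
panels, run array QC, build dense genetic maps from biparental populations,
and map QTLs — and who want each of those steps as an inspectable,
scriptable library rather than a chain of vendor tools.

## What the pipeline computes

**Array design** (`cicerchip.array_design`). From a variant panel (VCF), a
reference genome (FASTA) and gene models (GFF3), candidate probes are 71-mer
windows centred on SNPs that survive a flanking-uniqueness rule (no other
SNP within 35 bp on either side) and seven sequential quality filters: no
SSR in the window (perfect tandem repeats, motif length 1–6, MISA-style copy
minima), no indel in the window, biallelic only, minor allele frequency
≥ 0.05, window GC in 40–70%, no IUPAC ambiguity code, site QUAL ≥ 30.
Survivors are deduplicated, optionally filtered by a pluggable probe-
conversion score (threshold 0.3), and annotated as
intergenic / coding / intronic with coding effects (synonymous,
nonsynonymous, stop gained/lost, start lost, synonymous start/stop, splice
donor/acceptor) via strand-aware codon reconstruction. A per-filter
attrition report conserves counts.

**Genotype QC** (`cicerchip.genotype_qc`). Samples with dish QC < 0.82 or
call rate < 97% are removed. Per SNP, genotype-cluster summaries in
(contrast *x*, size *y*) space yield FLD (het–hom separation in pooled-SD
units), HetSO (size offset of the het cluster from the hom–hom chord) and
HomRO (signed hom-cluster distance from zero contrast); a fixed decision
tree assigns each SNP one category — PolyHighResolution,
MonoHighResolution, NoMinorHom, HomHomResolution, OTV,
CallRateBelowThreshold, the four AA/BB variance classes, or Other — at the
diploid defaults (CR ≥ 97, FLD ≥ 3.6, HetSO ≥ −0.1, HetSO-OTV ≥ −0.3,
HomRO ≥ 0.6 / 0.3).

**Linkage mapping** (`cicerchip.linkage_map`). Parent-polymorphic markers
are tested against 1:1 segregation (χ² = (n_A−n_B)²/(n_A+n_B), removal at
p < 0.01), duplicate call vectors are binned, pairwise recombination is
estimated with the selfed-RIL correction r = R/(2(1−R)) (observed
R = 2r/(1+2r)) and LOD = n[R log₁₀R + (1−R)log₁₀(1−R) + log₁₀2], groups
form by transitive closure over r ≤ 0.35 and LOD ≥ 6, each group is ordered
by greedy seriation plus a window-4 ripple minimising the sum of adjacent
recombination fractions, and distances use the Kosambi function
d = 25 ln((1+2r)/(1−2r)) cM.

**QTL scanning** (`cicerchip.qtl_icim`). ICIM-ADD: stepwise forward–backward
regression (entry p = 0.001, exit p = 0.002) picks cofactor markers; the
phenotype, adjusted for all cofactors except the flanking pair, is scanned
at a 1-cM step with LOD = (n/2) log₁₀(RSS₀/RSS₁), additive effect from the
±1 coding, and PVE = 100(1 − RSS₁/RSS₀). The genome-wide threshold is the
95th percentile of the max-LOD over 1000 seeded phenotype permutations.
Called QTLs (1-LOD support, 5-cM peak merge) are flagged robust (PVE > 10%),
stable (≥ 2 locations within 10 cM) and consistent (≥ 2 years).

**Synthetic data** (`cicerchip.syndata`) generates every input with known
truth: genomes with planted genes and SSR tracts, variant panels with
"filter-killer" variants that each violate exactly one design filter, RIL
populations recombining at R = 2r/(1+2r) per interval under a known map,
phenotypes with planted additive QTLs, and cluster signals with
controllable separation and off-target-variant contamination.

## Worked example

```python
from cicerchip.config import PipelineConfig
from cicerchip.pipeline import run_pipeline

cfg = PipelineConfig.model_validate({
    "seed": 11,
    "simulate": {"n_chrom": 4, "chrom_length": 120_000, "gene_count": 12,
                 "ssr_count": 8, "snp_rate": 5e-4, "n_ril": 120,
                 "markers_per_group": 10,
                 "traits": {"t1": [("G01", 20.0, 1.0)]},
                 "environments": [("L1", "2016", 0.0), ("L2", "2016", 0.0)]},
    "qtl": {"n_perm": 100},
})
log = run_pipeline(cfg, "out")
print(log["stages"]["map"], log["stages"]["qtl"])
```

prints

```
{'groups': 4, 'markers_mapped': 40, 'total_cm': 184.83}
{'n_qtls': 2, 'n_robust': 2, 'n_stable': 2, 'n_consistent': 0}
```

— the four simulated linkage groups are rebuilt (40 markers, 184.83 cM,
close to the 4 × 45 cM truth), and the single planted QTL at 20 cM on group
1 is detected in both environments (hence flagged stable), with PVE near
the planted a²/(a²+σ²) = 50%. The same run writes `attrition.tsv`,
`qc_summary.tsv`, `map_summary.tsv` and `qtl_results.tsv` under `out/`.

The same stages are available from a shell:

```bash
cicerchip run --config config.yaml --seed 11 --out-dir out
cicerchip report --out-dir out
```

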