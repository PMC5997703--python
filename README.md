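# mtcontinuity

Population-genetic analysis of serially sampled ancient mitochondrial
genomes: summary statistics (ΦST with Slatkin's linearization and
permutation tests, haplotype diversity and sharing, haplogroup-frequency
PCA and NMDS), ancient-DNA authenticity estimators (mtDNA contamination
point estimate, Ry genetic sex), and a serial-coalescent test of
maternal population continuity.

## The scientific problem

Archaeogenetic surveys sequence mitogenomes from individuals spread over
thousands of years and ask whether the region hosted one resident
maternal gene pool or saw turnover and gene flow.  Because a pair of
samples from different centuries will differ even under perfect
continuity — genetic drift alone moves haplotype frequencies — the
question has to be posed quantitatively: *could drift alone, at any
plausible effective population size, produce the differentiation we
observe?*

The core test works on two samples (sizes n₁, n₂) taken at two times
separated by Δ generations.  Differentiation is measured as ΦST, the
AMOVA estimator on pairwise nucleotide differences, linearized as
FST/(1−FST) where needed.  The null hypothesis — a single population of
haploid female effective size N(t) evolving by drift — is simulated with
a heterochronous (serial) coalescent under exponential growth between an
ancient size N_a and a recent size N_r, with growth rate
r = ln(N_r/N_a)/Δ, mutation rate μ = 3.4×10⁻⁷ per site per generation
over the 16,569-bp molecule, and a 25-year generation time.  Since N_a
and N_r are unknown, an 11 × 11 grid of size pairs is scanned, each cell
holding 1000 simulated ΦST replicates (121,000 simulations per
comparison).  Continuity is rejected at level α only if the proportion
of replicates with simulated ΦST ≥ observed is below α in *every* cell.

A synthetic-data module generates complete study-design datasets
(alignment + metadata + QC fixtures) with known ground truth, so every
stage is testable without any sequence download.

## Worked example

```python
from mtcontinuity import (SyntheticScenario, make_dataset, haplotype_diversity,
                          pairwise_distances, fst_permutation_test,
                          DemographicModel, SamplingSchedule, run_grid, verdict)
from mtcontinuity.continuity import default_axis

scenario = SyntheticScenario(seed=1)          # 41 ancients + 20 moderns
aln, meta, tree = make_dataset(scenario)

ancients = meta.loc[meta.temporal_group != "Modern", "sample_id"].tolist()
hd, se = haplotype_diversity(aln.subset(ancients), return_se=True)
print(f"haplotype diversity (41 ancients): {hd:.3f} +/- {se:.3f}")

early = meta.loc[meta.temporal_group == "Early", "sample_id"].tolist()
late = meta.loc[meta.temporal_group == "Late", "sample_id"].tolist()
dist = pairwise_distances(aln.subset(early + late))
res = fst_permutation_test(dist, [early, late], n_perm=10_000, seed=1,
                           labels=("Early", "Late"))
print(f"PhiST(Early, Late) = {res.fst:.3f}  linearized = {res.linearized:.3f}  "
      f"p = {res.p_value:.3f}")

model = DemographicModel(n_recent=1000, n_anchor=1000, anchor_gen=160.0)
schedule = SamplingSchedule((("Early", len(early), 160.0), ("Late", len(late), 0.0)))
grid = run_grid(model, schedule, observed_fst=res.fst,
                ne_axis_ancient=default_axis(), ne_axis_recent=default_axis(),
                n_reps=1000, seed=1)
v = verdict(grid, alpha=0.05)
print(f"simulations: {grid.n_simulations}   max exceedance proportion: "
      f"{v.max_proportion:.3f}   reject continuity: {v.reject}")
```

Output:

```
haplotype diversity (41 ancients): 0.979 +/- 0.010
PhiST(Early, Late) = -0.064  linearized = 0.000  p = 0.688
simulations: 121000   max exceedance proportion: 0.992   reject continuity: False
```

Reading it: the 41 simulated ancients are highly diverse (two random
individuals almost never share a haplotype); the Early and Late epoch
samples are not measurably differentiated (a slightly negative ΦST is a
finite-sample outcome, and 69% of label permutations do as well); and
across all 121 demographic scenarios drift readily produces
differentiation at least this large (max cell proportion 0.992), so the
continuity null stands — as it should, because this dataset was
simulated from a single continuous population.

The same stages are scriptable from the shell:

```
mtcontinuity synth --seed 1 --out-dir data/
mtcontinuity qc --pileups data/pileups.tsv --sex-counts data/sex_counts.tsv
mtcontinuity stats --alignment data/alignment.fasta --metadata data/metadata.tsv \
    --group-scheme spatial --out-dir stats/
mtcontinuity continuity --alignment data/alignment.fasta --metadata data/metadata.tsv \
    --group-a Early --group-b Late --out-dir cont/
mtcontinuity run --out-dir full_run/      # synth -> stats -> continuity + manifest
```

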