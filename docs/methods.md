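# Methods

## Ploidy from flow cytometry

2C DNA content is the ratio of the sample fluorescence peak to the
internal *Pisum sativum* standard times 9.09 pg. Classification uses
closed, disjoint windows per class — 2x: [1.10, 1.55] pg, 3x: [1.75, 2.15]
pg, 4x: [2.20, 2.70] pg — chosen as the realized per-class ranges of the
packaged collection (1.22–1.30, 1.86–1.99, 2.28–2.56 pg) padded by at
least 0.08 pg while kept disjoint. Values between windows are reported
indeterminate rather than force-classified. Mixoploidy is called when at
least two peaks, each carrying ≥ 20% of nuclei (configurable), fall in
different windows; the 20% floor keeps debris and replication shoulders
from triggering the call. No peak-finding from raw event data is
attempted: inputs are peak statistics.

## Genomic constitution from ITS PCR-RFLP

The model maps an (a, b) count of A and B genome sets to band intensities:
the 530 bp A fragment is STRONG whenever a > 0 (the A fragment amplifies
preferentially at every observed dose, so dose information lives in the B
bands); the 350/180 bp B fragments are ABSENT for b = 0, STRONG when
b/(a+b) ≥ 2/3 (or when a = 0), WEAK otherwise. The 2/3 threshold is a
modeling choice fitted to the qualitative gel codes: AAB (1/3 B) and AB
(1/2 B) print "+", ABB (2/3) and BB print "++". It is configurable.

The inverse decision table returns *sets* of candidate compositions:
profiles are invariant under total-set count within a B-dose class, so
without ploidy {AB, AAB, AAAB} or {ABB, ABBB} are returned whole, and with
ploidy the single length-matching composition. Two profile families cannot
arise from pure A/B dosage — a B-majority pattern in a diploid, and
disagreeing 350 vs 180 bp levels — and are flagged anomalous but still
called with their nearest candidates; homeologous A/B recombination is a
documented biological source of such patterns, and the package reports
rather than corrects them.

## SSR diversity statistics

Binary (dominant) statistics treat each observed (locus, allele size) band
as present/absent: PICᵢ = 2fᵢ(1−fᵢ) with band frequency fᵢ over
non-missing rows (maximum 0.5), β the fraction of bands present in at
least one and absent in at least one accession (no 95% criterion),
EMR = Na·β and MI = mean-PIC·EMR per locus. Codominant PIC uses the
Botstein form 1 − Σpᵢ² − Σᵢ<ⱼ2pᵢ²pⱼ², with carrier-based allele
frequencies; observed heterozygosity is the fraction of non-missing
diploid genotypes with two distinct alleles. Absence of all bands at a
locus is treated as missing data, not as a shared null allele.

## Binary distances and Neighbor-joining

Jaccard dissimilarity d = 1 − a/(a+b+c) ignores joint absences and uses
pairwise deletion for missing loci (a pair with no mutually determined
band is an error, not a silent zero). Neighbor-joining is the saturated
algorithm on the Q-criterion Q(i,j) = (m−2)d(i,j) − rᵢ − rⱼ with
deterministic tie-breaking (lowest index pair) and negative branch lengths
clamped to zero with the deficit moved to the sister edge; on additive
input the generating topology and lengths are reproduced exactly (checked
to 1e-9 against generating trees, and cross-checked against an independent
NJ implementation). Duplicate accessions are zero-distance pairs grouped
transitively.

## Triploid standardization (Analysis I / II)

Peak scoring is dosage-blind, so a genotype is a set of distinct alleles,
and ploidies 2–4 must be coerced to a fixed three slots: one distinct
allele is triplicated; three are kept; two are completed by duplicating
the smaller (Analysis I) or larger (Analysis II) allele; more distinct
alleles than the coding can hold (diploids with 3+, triploids/tetraploids
with 4) set the locus missing. For tetraploids with four observed alleles
there is no principled choice of a discard, so the default is missing,
with an optional drop-largest policy. Accessions without a determinate
ploidy are excluded (the encoding is ploidy-driven). The two variants
yield two membership matrices downstream whose per-group Pearson
correlation (after label alignment) measures how much the arbitrary
duplication choice matters.

## Admixture model and Gibbs sampler

The model: each of n individuals carries a membership vector q over K
populations with prior Dir(α, ..., α); each observed allele copy draws its
source population z from q and its allele from that population's frequency
vector at the locus. Population frequencies follow the correlated
(F-model) prior P_kl ~ Dir(PA_l·(1−F_k)/F_k) around ancestral frequencies
PA_l, with per-population divergence F_k (F is approximately the
population's Fst against the ancestral pool).

One sweep updates, in order: Z (multinomial ∝ q_ik·p_klj), P (Dirichlet
posterior under the F-model prior plus assignment counts), Q
(Dir(α + per-population copy counts)), α (log-scale random-walk
Metropolis, step 0.1, uniform prior on (0, 10)), each F_k (log-scale
random walk, step 0.2, Beta prior with mean 0.01 and sd 0.05), and PA per
locus (pairwise mass-transfer Metropolis under a flat Dirichlet prior).
Missing slots contribute to no count (marginalized by omission). The
composite log-likelihood Σ log Σ_k q_ik·p_klj over observed copies is
recorded each sweep; LnP(K) is estimated as mean(lnL) − var(lnL)/2 (the
standard model-evidence approximation from a likelihood trace; sample
variance). The kernel is compiled with numba; a given seed yields
bitwise-identical output.

Two label-switching safeguards: within a chain, each recorded Q sample is
aligned to the running mean by greedy column matching before accumulation;
across chains, membership matrices are aligned to a reference run by
greedy matching on column-wise Pearson correlation (ties to the lowest
index pair, undefined correlations last). Point estimates at a given K
average the aligned replicate runs (reference: highest LnP).

Model size selection follows ΔK = |L″(K)| / sd(L(K)) with L′(K) =
meanL(K) − meanL(K−1) and |L″(K)| = |L′(K+1) − L′(K)|; sd is the sample
(n−1) standard deviation over runs, ΔK is undefined at the grid ends and
where sd = 0, and ties select the smallest K. Membership bins follow the
reporting convention (0.24–0.60], (0.60–0.80], (0.80–0.90], (0.90–1] with
admixture flagged at q* ≤ 0.90 (strict boundary).

Chain-length defaults in `PipelineConfig` are the full-study protocol
(150,000 burn-in + 70,000 recorded sweeps, K = 2..30, ten runs per K);
the recovery studies and tests use reduced chains (2,000 + 2,000,
K = 2..6, ten runs), sizes at which the reduced-chain sampler already
mixes on n = 60 problems. Per-run seeds are base + 1000·K + run.

## Synthetic data: what it emulates and what it does not

`generate_population` mirrors the inference model exactly (F-model
frequencies, Dirichlet memberships, per-copy population draws) and then
applies the observation process: null-allele copies deleted (default rate
0.02), whole-locus missingness (0.02), codominant collapsing to distinct
sizes. 2C readings are Normal per ploidy class (means 1.26/1.93/2.45 pg,
CV 3.31%, the collection's replicate CV); ITS profiles derive from the
accession's true A:B set counts. Defaults: 16 loci with 7–15 alleles
(sizes random in 80–350 bp), n = 60, ploidy proportions 0.35/0.50/0.15,
K = 3 at F = 0.05, membership concentration α_q = 0.1 (a germplasm
collection profile: mostly near-pure accessions, a minority of admixed
hybrids), seed 20130312.

Not emulated: electropherogram artifacts (stutter, size drift), linkage
between loci, aneuploidy, and real allele-size distributions (undeposited
for the motivating collection). Passing recovery tests therefore show the
statistical machinery is correct under the model's own assumptions, not
that real collections carry this much signal.

`generate_dosage_population` builds genome-dosage groups from two
*disjoint* ancestral allele pools, for the dosage-trend and two-cluster
properties: an A-pool allele with pool frequency f has expected carrier
frequency 1 − (1−f)^a in a group with a A sets, monotone in dosage.

## Known limitations and measured behavior

At the reduced-chain study conditions (K = 3, F = 0.05, n = 60, L = 16),
ΔK selects the true K in 8/10 replicates, but membership recovery against
the simulated truth averages r ≈ 0.83 and the Analysis I/II per-group
correlations spread over roughly 0.55–0.99 (about half the groups reach
r ≥ 0.9). This is an information limit, not a sampler defect: fixing the
population frequencies at their generating values lifts recovery only to
r ≈ 0.93, so the residual gap is posterior uncertainty in the frequencies
at n = 60 under F = 0.05, which is weak divergence (Fst ≈ 0.05). At
moderately strong divergence (F = 0.2, see `examples/05`), recovery
exceeds r = 0.97 and ΔK selection is unambiguous. The per-group
correlation spread under weak divergence closely parallels what the
duplication-variant comparison produces on real collection data.

Numerical details: Dirichlet draws floor components at 1e-12 and
renormalize; Metropolis steps reject proposals outside their support;
frequencies in log-density evaluations are floored at 1e-9; the Jaccard
step defines a pair with a non-empty shared column set but empty union as
distance 0. All tie-breaks (NJ pair choice, top-allele ranking, label
matching, K selection) resolve to the lowest index or smallest value so
every pipeline output is deterministic for a given seed.
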