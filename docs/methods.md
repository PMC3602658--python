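# Methods

## The problem

Transcription factor binding sites (TFBSs) are often not globally
over-represented in the promoters of co-regulated genes, yet concentrate in
a narrow window at a preferred distance from the transcription start site
(TSS) — the TATA box around −30 to −25 is the textbook case.  Window- or
bin-counting detectors treat every site inside the window equally and are
fragile to window placement.  This package scores *local* enrichment with a
Parzen window instead: each predicted site contributes a smooth kernel of
its distance to the scored base, and significance is assessed against
promoter sets resampled from the genome with a matched GC-content profile.

## Scoring model

For a set *S* of *N* promoter sequences with TSS-relative site positions
*l*<sub>*s*,1</sub> … *l*<sub>*s*,*m*<sub>s</sub></sub> per sequence, the
local enrichment score at integer base *x* is

    S_local(x) = Σ_s p_s(x) / Z_s
    p_s(x)     = Σ_i φ(x, l_{s,i}, h)
    Z_s        = max(1, Σ_{x=x_start}^{x_stop} p_s(x))

with φ either a Gaussian of standard deviation *h*/2 or a uniform box of
width *h* (1/*h* inside |x − l| ≤ h/2, boundary inclusive).  The ZOOPS-style
("zero or one occurrence per sequence") factor *Z*<sub>s</sub> caps any one
sequence's total contribution over the scored region at 1, so a repeat-rich
promoter cannot dominate the profile; a sequence with a single interior site
has *Z*<sub>s</sub> = 1 and contributes exactly one unit of kernel mass.

Defaults follow the method's standard operating point:

| parameter | default | meaning |
|---|---|---|
| scan span | [−3000, +2000) bp | window scanned for sites |
| scored region | [−2000, +1000] bp | grid where S_local and p-values are computed |
| h/2 | {10, 20, 50, 100, 200} bp | kernel half-widths, narrow to broad |
| Gaussian truncation | 6·(h/2) | per-site mass error < 1e−8 |

Scores are computed at 1-bp resolution.  Sites outside the scored region but
inside the scan span still contribute near the region boundary, which
removes edge artefacts.  The ZOOPS sum runs over the same scored region.

## Site prediction

Motifs are count matrices (JASPAR PFM or TRANSFAC dialect, parsed with
Bio.motifs).  A pseudocount (default 0.8, split by the background
composition) is added before columns are normalised; windows are scored on
both strands as log2-odds against the background (uniform by default) and
classified by the MATCH-style relative score
(score − min)/(max − min): *strong* at ≥ `strong_fraction` (default 0.85),
*weak* in [`weak_fraction`, `strong_fraction`) (default 0.70).  A site is
anchored at the floor of its match midpoint, which keeps Gaussian peaks
centred on the biological site irrespective of motif width; windows
containing `N` never score.  All overlapping hits are kept — multiplicity is
handled by *Z*<sub>s</sub> — and weak hits whose window intersects a strong
hit of the same motif are flagged so the weak-site test can exclude them.

## Significance: GC-matched resampling

GC-rich motifs hit GC-rich sequence more often, and promoter GC content is
strongly structured around the TSS, so nulls drawn uniformly from the
genomic promoter universe would mis-calibrate.  The null model therefore:

1. represents every genomic promoter by 20 GC fractions over 100-bp bins in
   [−1000, +1000) (N bases excluded; all-N bins imputed with the genomic
   bin mean), scaled per bin to mean 0, SD 1;
2. clusters the universe by k-means for k = 2…10 (best total
   within-cluster sum of squares over 100 random restarts, ≤ 100 iterations
   each; scikit-learn's Lloyd updater — the contract is the best-of-restarts
   criterion, not a particular updater);
3. chooses k\* per input set: for each k, 1000 stratified samples matching
   the input's per-cluster counts c\_i are drawn, and the RMSD between the
   sampled-mean and input-mean 20-bin profiles is summarised; k\* is the
   smallest k with RMSD\_k ≤ RMSD\_{k+1} + SD\_{k+1} (k = 1 is never
   considered; if no k ≤ 9 qualifies, k\* = 10, the largest considered k,
   since RMSD tends to decrease with k);
4. draws sampled sets of size N matching c\_i, without replacement within a
   sample (input genes stay in the pool), and scores them with the same
   Parzen machinery.

Two empirical p-values result: P_dep(x), the proportion of sampled sets
whose profile at *x* reaches the observed score, and P_ind(x), the
proportion whose profile *maximum* reaches it.  Both are plain proportions;
a (r+1)/(n+1) conservative variant is available behind a flag.  Per-gene
normalised contributions p\_s/Z\_s are computed once for the universe, so
each sampled profile is a row sum (implemented as a sparse selector
product); memory stays O(genes × positions + samples).

Default sample counts are 25 000 for local enrichment (resolution 4e−5,
below the strictest P_dep threshold) and 10 000 for ORI; a warning is
emitted when fewer samples cannot resolve the strictest threshold.

## Region calling

A position is significant when P_dep(x) < t(h/2) — t = {200: 1e−3,
100: 5e−4, 50: 2e−4, 20: 1e−4, 10: 5e−5}, stricter for narrow kernels to
absorb the larger effective number of tests — and P_ind(x) < 0.01.  Each
maximal run [x₁, x₂] of significant positions becomes the region
[x₁ − h/2, x₂ + h/2].  Runs separated by even one non-significant base stay
separate; the subsequent same-width merge unions regions whose expansions
overlap (coordinates are unioned; the reported p-values are the members'
minimum P_dep and that member's peak P_ind).  Across widths, every
transitively-overlapping group is collapsed to one region: keep the largest
(by bp span, ends inclusive) unless a smaller member contains strictly more
than 2/3 of its strong sites, in which case keep the smallest such member.
Ties on span go to the member with more sites, then the smaller start —
the rule is deterministic.  Strong sites only are counted; weak sites are
the subject of a separate test.

## Global statistics

**ORI** (Over-Representation Index): with sites counted in the half-open
upstream window [−1000, 0),

    ORI = (Density_S / Density_genomic) × (Proportion_S / Proportion_genomic)

where Density is sites per sequence and Proportion the fraction of
sequences with ≥ 1 site.  P_ORI is the fraction of GC-matched samples with
*strictly* higher ORI (threshold 0.01); the strictness is a deliberate
asymmetry with P_dep's "≥".  A motif with no genomic upstream sites has no
defined ORI and is reported as an error, not zero.

**Weak-site enrichment**: for a called region, the count of weak sites
inside it (excluding weak hits overlapping strong hits of the same motif)
is compared against GC-matched sampled sets; p is the fraction of samples
with a count ≥ observed.

**Conservation Z**: given any per-base score track (gene, TSS-relative
position, score), the mean score over the bases covered by the region's
sites is compared with a null that keeps each base's TSS-relative offset
and redraws the promoter uniformly from the genomic set (not stratified —
positional structure in the track is what is being controlled for).
z = (mean_obs − null_mean)/null_SD over 1000 draws by default; regions with
fewer than 10 sites are rejected as underpowered, and a constant track has
no defined z.

## Synthetic data

`synthdata.generate_universe` draws promoters i.i.d. per position with a
class-specific GC probability: baseline + bump·exp(−x²/(2·w²)).  The shipped
two-class composition (50% "gc_high": baseline 0.52, bump +0.18 over
~300 bp; 50% "gc_low": baseline 0.38) mimics the CpG-island/non-island
bimodality of mammalian promoters that the GC-matched null exists for.
`synthdata.implant` overwrites the background with one word per selected
sequence, sampled column-wise from the motif's probability matrix, at a
midpoint drawn around a configurable centre (`round(rate·N)` sequences,
chosen without replacement); a multi-pass application produces the
multi-site sequences that exercise Z_s > 1.

Two reference motifs fix the simulation operating points.  `common6`
(consensus TGACGT, strong/weak cutoffs 0.92/0.90) yields ~2 strong hits per
5-kb promoter — a realistic density for a 6-mer — and drives the
calibration and false-positive studies.  `sharp8` (consensus TATAAATA,
cutoffs 0.95/0.90) has rare background hits (~0.4 per promoter); roughly
half the words sampled from its own matrix score strong and most of the
rest land in the weak band, so implants create both the strong peak and the
accompanying weak sites seen in real data.  These cutoffs were chosen from
the relative-score distributions on the synthetic background to hit those
densities, before any downstream result was inspected.

What the generator does *not* model: dinucleotide structure, repeats, CpG
dinucleotide depletion, multiple TSSs, and correlated site co-occurrence.
Passing tests therefore demonstrate the correctness and calibration of the
machinery under a controlled promoter-like null, not performance on real
genomes.

## Verification strategy and problem sizes

The statistical checks run at sizes chosen to give stable answers on a
single CPU in minutes:

- **Calibration**: 2000-promoter two-class universe; 200 input sets of 50
  drawn from the universe itself; P_dep at x = −500 (h/2 = 100) from 400
  samples per set must be consistent with Uniform(0,1)
  (Kolmogorov–Smirnov, α = 0.01).  Stratification uses the k = 2 model —
  the value the k* rule itself selects on this universe.
- **False-positive budget**: 20 random 100-gene inputs × all five widths at
  2000 samples; the fraction of (input, width) combinations with any called
  region must stay below 5%.
- **Power**: 5000-promoter universe; 20 runs implanting `sharp8` at
  −30 ± 5 bp into half of 100 GC-poor promoters; a region overlapping
  [−40, −20] must be called at h/2 = 10 in ≥ 90% of runs (2000 samples,
  where passing the 5e−5 threshold requires zero exceedances).
- **GC matching**: k* = 2 must be selected on the two-class universe
  (1000-rep RMSD protocol), and stratified sampling must beat unstratified
  sampling on profile RMSD in ≥ 95% of 200 trials.
- **Exact rules**: kernel values, counting-oracle equivalence (uniform
  kernel with ZOOPS disabled equals a sliding count exactly), ZOOPS mass
  bound, threshold maps, region expansion/merging and the 2/3 rule are
  checked against hand-computed or brute-force oracles.

`scripts/acceptance.py` re-runs the same battery from scratch with a
user-supplied seed.

## Numerical and design notes

- Half-open integer intervals everywhere ([start, end)), except region
  bounds and the uniform kernel's box, which are inclusive as defined.
- Gaussian truncation at 6σ is configurable (`KernelSpec.truncation`).
- GC-bin scaling uses the sample SD (ddof = 1).
- k-means is seeded; identical seeds give identical cluster models.
- All resampling is reproducible bit-exactly given (seed, n_samples,
  genomic set order).
- `local_enrichment(..., zoops=False)` exists purely as the diagnostic
  hook for the counting-oracle equivalence; production scoring always
  normalises.
- The density interpretation (1/n-normalised Parzen estimate) is
  motivational only; the implemented score is the ZOOPS-normalised sum,
  which is not a probability density.

## Limitations

- Empirical p-values are granular at 1/n_samples; the defaults are the
  minimum that resolves the strictest threshold, not a convergence claim.
- The k* rule inherits k-means' sensitivity to rare GC profiles; clusters
  much smaller than an input's c_i make sampling fail loudly rather than
  silently reuse sequences.
- Conservation and weak-site tests assume the pre-scanned genomic site
  lists and the score track cover every promoter they touch; missing data
  is an error by design.
- No FDR control beyond the width-dependent thresholds; regions from
  different motifs are never de-duplicated against each other.
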