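# Methods

## Scope and model

`icmaldi` implements the data-analysis half of intact-cell MALDI-TOF
microbial typing. The measurement model is: each strain has an underlying
line spectrum of peptide/protein ion species over *m/z* 1000–20,000
(predominantly singly protonated, unresolved isotopic envelopes, so
positions track *average* molecular masses). A replicate acquisition
observes a corrupted version of this fingerprint — peak positions shifted by
a small reproducibility error (here ≤ ±2 Da), some peaks missing, some
spurious peaks present, intensities scattered. All downstream operations are
built on this model; nothing in the package models the physics of
desorption, detector response or isotope structure.

## Peak picking

Profile traces are reduced to centroided peak lists in three steps.

*Baseline.* A rolling minimum followed by a rolling mean, both over a
window of 200 Da (converted to grid points via the median grid step). The
minimum tracks the slowly varying chemical background underneath peaks; the
mean smooths the staircase the minimum produces.

*Noise and SNR.* The baseline-subtracted residual is recentred on its
median before anything else: a rolling-minimum baseline sits systematically
below the noise band (by roughly 2–3 noise SDs for Gaussian noise), and
without recentring pure noise would appear to have positive SNR everywhere.
Noise is then the median absolute deviation of the recentred residual
scaled by 1.4826 (the Gaussian consistency constant), which is insensitive
to the peaks themselves and makes the SNR threshold scale-free: multiplying
the whole trace by a constant changes no picked position.

*Centroiding.* A peak is a strict local maximum within ±5 Da with
SNR ≥ 3; its *m/z* is the intensity-weighted centroid of the contiguous
region above half the apex height. Half-maximum centroiding is stable under
point-wise intensity noise and lands well within the ±2 Da tolerance used
everywhere downstream (sub-0.01 Da error on clean synthetic Gaussians). The
defaults (SNR 3, window 5 Da, range 1000–20,000 Da) are chosen so that
synthetic spectra with the jitter regime described below are recovered
essentially completely; acquisition software settings vary by vendor and no
attempt is made to replicate any particular product's peak lists.

## Consensus ("virtual") spectra

A sample's replicate peak lists are pooled, sorted, and partitioned by
single-linkage with a gap threshold equal to the tolerance (2 Da default): a
new cluster starts wherever the gap between adjacent pooled peaks exceeds
the tolerance. Within a cluster each replicate may contribute at most one
member (its most intense), so a replicate cannot attest twice to one
consensus peak. A cluster is kept iff its support — the number of distinct
contributing replicates — is at least ⌈min_fraction · n_replicates⌉; "at
least 70 %" of 10 replicates therefore means support ≥ 7. The consensus
*m/z* is the median of the members (robust to a single outlier inside the
window) and the reported intensity is their arithmetic mean. Because a
single-linkage chain can grow beyond the tolerance, any cluster whose span
exceeds twice the tolerance is split at its largest internal gap and
re-tested recursively (span repair). The construction is independent of the
order of the input peak lists; replicates are indexed by sorted replicate id
and pooled peaks are ordered by (m/z, intensity, replicate) before
clustering.

The tolerance is specified as a bound on peak-maximum positions, not as an
algorithm, so the clustering rule is this package's own resolution; span
repair is what makes the ±tol membership statement hold approximately (every
member is within the cluster span ≤ 2·tol of the median, and in the
realistic jitter regime well within ±tol). An exhaustive-partition oracle in
the test suite scores all contiguous tolerance-respecting partitions of
small pooled sets by (number of kept peaks, total support); the greedy
construction agrees with the optimum on kept-peak count in ≥ 95 % of
fixtures *whose ground-truth peaks obey the generator's minimum-gap
constraint* (see below). On adversarial pools with uniformly smeared peaks
and no gap structure, agreement drops to ~75–90 % — single-linkage is a
heuristic there, and the tests document rather than hide this.

## Shared-peak similarity and trees

The similarity of an inspected spectrum against a reference is the
percentage of the inspected spectrum's peaks that find a counterpart in the
reference within the tolerance (closed interval, |Δ| ≤ tol). Matching is
one-to-one: candidate pairs are certified nearest-first, ties toward the
lower-*m/z* query peak, and each reference peak certifies at most one query
peak — this prevents one reference peak from matching several query peaks
and makes score(A, A) = 100 exact. An empty inspected spectrum scores 0.
Greedy nearest-first matching is not guaranteed to reach maximum cardinality
on arbitrary inputs (chains of overlapping tolerance windows can defeat it),
but on inputs with the replicate-spectrum structure — counterpart peaks
jittered by ≲ 1 Da, remaining peaks far apart — it coincides with
maximum-cardinality bipartite matching; the test suite asserts this on 500
seeded instances against a `scipy.sparse.csgraph` oracle.

The score is directed (its denominator is the inspected spectrum), so for
tree building the two directions are averaged: d(i, j) = 100 − (sᵢⱼ+sⱼᵢ)/2,
d(i, i) = 0. Agglomeration (UPGMA default; complete and single linkage
available) is implemented directly rather than via `scipy.cluster` because
the tie-break is part of the contract: equally distant cluster pairs merge
in order of their lexicographically smallest leaf label, making the topology
deterministic under input permutation. Node heights are half the merge
distance, so tip-to-tip path lengths reproduce the cophenetic distances and
the UPGMA tree is ultrametric (verified against `scipy` average linkage on
tie-free matrices). Trees are exported as Newick via scikit-bio.

The heat map uses a continuous colour ramp anchored at red = 0,
yellow = 50, dark green = 100 with orange and light-green intermediates —
the conventional display for percent-similarity matrices of spectral
libraries.

## Protein masses, Met loss, pI, assignment

Masses are sums of standard residue masses plus one water
(monoisotopic 18.01056 Da, average 18.01528 Da), computed at full precision
and rounded to 0.1 Da only in reports; the monoisotopic table is verified
against pyteomics in the tests (average tables differ between sources at the
0.01–0.05 Da level on multi-kDa chains, which is far below the assignment
tolerance). Every sequence starting with Met gets "−Met" variants by
subtracting one Met residue (monoisotopic 131.04049 Da, average
131.19261 Da) — unconditionally, with no second-residue specificity rule,
because both forms are informative when matching intact-cell peaks and the
enzymatic specificity of Met aminopeptidase is out of scope.

The isoelectric point solves net-charge(pH) = 0 by bisection on [0, 14] to
0.01 pH, with a Henderson–Hasselbalch charge model over the termini and the
D, E, C, Y, H, K, R side chains using the Bjellqvist pKa set (N-term 7.5,
C-term 3.55, D 4.05, E 4.45, H 5.98, C 9.0, Y 10.0, K 10.0, R 12.0).
Different pKa sets shift pI by a few tenths of a pH unit; the tests compare
against Biopython's calculator at 0.3 pH tolerance.

Assignment: for each candidate protein, the (variant, peak) pair minimising
|Δ| over the enabled variants and all observed peaks is selected and emitted
iff |Δ| is within tolerance — absolute Da (default ±6 Da) or ppm. Each
protein yields at most one assignment; peaks may be shared by several
proteins, since distinct proteins genuinely can sit under one unresolved
peak. The default variant set is {avg, avg_noMet}: the instrument
calibration and the unresolved envelopes both live on the average-mass
scale. The ±6 Da default reproduces the shipped CCALA 043 reference
assignments, whose largest deviation is 5.8 Da (plastocyanin); no tolerance
was reported with the original table, so this is an inference from the
printed values. Peaks are compared to neutral masses by default; a proton
switch (−/+1.00728 Da) is available, the shift being small against the 6 Da
tolerance.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes: panels of
3 clades × 4 strains, 30 true peaks per strain of which 70 % come from a
clade-shared pool, 10 replicates per sample, Gaussian *m/z* jitter with
SD 0.6 Da (≈ 99.9 % of draws within ±2 Da, the stated reproducibility
regime), 10 % peak dropout, Poisson(2) uniformly placed spurious peaks per
replicate, and log-normal intensity scatter (CV 0.3, unit mean). True peaks
are rejection-sampled with pairwise gaps > 5 Da (> 2× tolerance) within and
across strains, so every consensus or matched peak has a unique ground-truth
counterpart and recovery metrics are well defined. All draws flow from one
`numpy.random.default_rng(seed)`, giving bit-reproducible studies.

What the generator does **not** emulate: realistic TOF peak shapes and
resolution–mass dependence, detector saturation, isotope envelopes,
mass-dependent intensity trends, matrix cluster chemistry, or correlated
(systematic) calibration drift across a spot. Passing the recovery suite
therefore shows the pipeline is correct and robust under the stated
statistical structure — not that any particular instrument/organism
combination will reach the same recovery rates.

With these defaults the acceptance suite checks, over 20 seeded runs:
≥ 95 % of true peaks recovered in the consensus spectra, ≤ 5 % false
consensus peaks, and clade monophyly of the UPGMA tree in ≥ 18 runs (the
observed runs give ~98.6 % recovery, 0 false peaks and 20/20 monophyly).
Problem sizes throughout the suite (12-strain panels, ≤ 20-peak oracle
pools, 150–500 oracle fixtures) were chosen as the smallest sizes at which
the statistical assertions are stable.

## Degenerate inputs and numerical choices

- Duplicate *m/z* on load are merged by intensity summation (preserves total
  ion signal, restores strict monotonicity).
- Empty in-range signal yields an empty peak list, not an error; an empty
  replicate set or mixed sample ids raise.
- All tolerance comparisons use closed intervals.
- Matrix CSV entries are written to one decimal; peak-list CSVs to four.
- Peak-list and consensus structures validate their invariants (sorted,
  strictly increasing *m/z*; non-negative intensities) at construction.

## Limitations

- The consensus construction and the similarity score are generic
  re-implementations of the reproducibility-filter / shared-peak paradigm;
  they are not bug-for-bug replicas of any vendor's or web tool's scoring,
  and numeric scores will differ from proprietary implementations.
- mzML support is a minimal reader/writer pair (base64 float arrays,
  optional zlib, MS1 only) sufficient for interchange of these line and
  profile spectra, not a general-purpose mzML implementation.
- Charge states other than +1, post-translational modifications other than
  N-terminal Met loss, and chromophore-carrying proteins (whose masses are
  shifted by variable modification) are out of scope for assignment.
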