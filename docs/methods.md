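# Methods

## Distances and haplotypes

All sequence comparisons use the raw p-distance with pairwise deletion:
for a pair of aligned sequences, every site carrying a symbol outside
{A, C, G, T} (IUPAC ambiguity codes, `N`, `-`) in either member is excluded,
and the distance is the fraction of differing sites among those compared.
Input is case-insensitive and `U` is read as `T`. A pair with zero jointly
unambiguous sites has no defined distance; such pairs flag the matrix
incomplete and block ordination and G_ST with an explicit error rather than
propagating NaNs. No model correction (K2P etc.) is applied — at
intraspecific barcode divergences the difference is negligible and raw
p-distances keep H_T/H_S decompositions exact.

Specimens are collapsed into haplotypes by the **transitive closure** of the
zero-distance relation (union-find). The closure is deterministic and
order-independent, at the price that a short, partially ambiguous sequence
can bridge two otherwise distinct haplotypes; bridge merges are counted and
logged so datasets with heavy masking can be audited. The representative of
a haplotype is its most informative member (most unambiguous sites, ties by
lexicographic specimen id); mutational steps between haplotypes are counted
between representatives, matching what a network display labels.

The ≥ 500-unambiguous-site filter treats gaps and all ambiguity codes as
missing. Sequences are assumed pre-aligned (the COI barcode is
length-conserved in butterflies); ragged lengths are an input error.

## Diversity indices

- π: mean pairwise p-distance over *specimens* (not unique haplotypes),
  so haplotype frequencies weight the average.
- h: Nei's haplotype diversity with the small-sample correction,
  h = N/(N−1)·(1 − Σ p_i²), clipped to [0, 1].
- Maximum intraspecific distance: the largest pairwise value.
- Nearest-neighbor distance: minimum p-distance from any focal specimen to
  any heterospecific specimen, ties between species broken alphabetically.
  NND = 0 defines barcode sharing; shared-haplotype counts between species
  pairs use the same zero-distance criterion as collapsing.

## Spatial structure (G_ST)

Coordinates are projected with a Lambert azimuthal equal-area projection on
a spherical Earth (R = 6371.0088 km), centered on the dataset's spherical
centroid — cell areas are then true in km² without assuming a fixed
continental frame. Specimens are binned to square grids by
floor((coordinate − offset)/cell_size) per axis.

For one grid, cells with ≥ 3 specimens qualify; a replicate is eligible
when ≥ 2 qualifying cells jointly hold > 10 specimens. Then

- H_T = mean pairwise p-distance over specimens pooled from qualifying
  cells (pooling only qualifying cells keeps H_T and H_S on the same
  sample, so stray singleton cells cannot inflate the total diversity);
- H_S = unweighted mean over qualifying cells of the within-cell mean
  pairwise p-distance;
- D_ST = H_T − H_S and G_ST = D_ST/H_T ∈ [−1, 1]; a monomorphic pool
  (H_T = 0) is defined as G_ST = 0.

Because the statistic depends on cell size and on the arbitrary placement
of the grid, it is recomputed for cell sizes 100, 200, 300 and 400 km, each
at two grid placements (origin at cell centers and shifted half a cell on
both axes, i.e. centers moved to vertices): 8 replicates. The retained
value is the mean of the defined replicate values, clamped at 0 from below;
negative values arise at small samples when within-cell diversity exceeds
the pooled diversity and carry no structural signal. By default negative
replicates contribute their raw value to the mean and only the mean is
clamped (`clamp_per_replicate=True` switches to clamping each replicate
first). A species whose records collapse to a single haplotype has no
structure by definition: status `single_haplotype_zero`, G_ST = 0. If no
replicate is eligible the species-level value is withheld (`ineligible`),
never reported as 0 — 0 is a meaningful value in this statistic.

## Ordination, colors, networks

Classical PCoA: double-center the squared distance matrix, eigendecompose,
order axes by descending eigenvalue. Negative eigenvalues (p-distance
matrices are only near-Euclidean) are dropped without Cailliez/Lingoes
correction; the deficit is visible in `variance_explained` rather than
corrected away. Degenerate cases are defined explicitly: one haplotype
embeds at the origin, two at ±d/2 on axis 1.

Colors: axes 1–2 are min-max scaled to [0, 1]² (a zero-range axis pins to
0.5) and each haplotype's RGB is the bilinear blend of four corner colors,
default white (0,0), yellow (1,0), blue (0,1), black (1,1). The corner
orientation is configurable; the default keeps the dominant axis on the
blue–yellow diagonal, legible under the common forms of color blindness.

Networks: a canonical minimum spanning tree over the mutational-step matrix
(Kruskal; ties among equal-weight edges broken lexicographically by
haplotype-id pair) gives the primary topology. Because ties are pervasive at
barcode scales, the MST is recomputed under seeded random edge orderings
(default 50); edges appearing in some minimum tree but not the canonical one
are flagged `alternative`. Every emitted tree attains the global minimum
weight (asserted — a matroid property of MSTs). Map pies aggregate records
per grid cell (default 200 km) with the centroid of member points, total n
(pie radius ∝ n) and the haplotype composition in the shared color scheme.

## Completeness

Abundance-based framework (the sampling unit is a sequenced specimen).
With f1 singleton and f2 doubleton haplotypes among N specimens:

    S_est = S_obs + (N−1)/N · f1²/(2 f2)        (f2 > 0)
    S_est = S_obs + (N−1)/N · f1(f1−1)/2        (f2 = 0)

R = S_obs/S_est, L = S_est − S_obs (reported unrounded; rounding is a
display concern). Rarefaction uses the exact hypergeometric expectation
E[S(m)] = S_obs − Σ_i C(N−n_i, m)/C(N, m), computed in log-gamma space for
stability; extrapolation beyond N (allowed to 2N) follows the Chao-type
approach curve S_obs + f0(1 − (1 − f1/(N f0 + f1))^(m−N)). Estimates are
withheld at N ≤ 10, where the asymptote is driven by noise. No
coverage-based standardization and no Hill numbers for q > 0.

## Synthetic data

The generator emulates a georeferenced multi-species barcode compilation:
a random ancestral sequence (default 658 sites); species roots at a
configurable divergence (default 25 substitutions ≈ 3.8%, a typical
interspecific COI gap); per species, demes with Gaussian km scatter around
their centers; per deme, a haplotype pool mixing a species-wide shared pool
(fraction `share_fraction`) with private haplotypes derived from a deme
ancestor `deme_divergence` substitutions from the root; uniform haplotype
sampling; optional per-site masking to `N`; and optional verbatim copying
of haplotypes between species. Mutations are uniform random substitutions
without back-mutation bookkeeping — truth tracks sequence identity.

Presets fix the study conditions used throughout the tests:

- `monomorphic` — 1 deme, 1 haplotype, n = 20.
- `panmictic` — 4 demes 300 km apart sharing one pool of 5 shallow
  haplotypes at identical frequencies, n = 25/deme, 0.5% masking.
- `two_deme_split` — 2 demes 600 km apart, fully private pools separated by
  10 ancestral substitutions (≈ 1.5% divergence, a deep intraspecific
  break), 3 haplotypes/deme with ≤ 1 further substitution, n = 30/deme.
- `gradient` — 5 demes in a 300-km line, shared-pool fraction 1.0 → 0.0.
- `shared_pair` — two panmictic species with one haplotype copied verbatim
  between them, no masking (so sharing detection is exact).

These sizes (n = 60–100 per species) keep full pipeline runs under a
second while giving G_ST sampling noise of a few percent; the recovery
tests average 20 seeds. What the generator does *not* emulate: coalescent
genealogies, selection, uneven sampling effort, sequencing error beyond
uniform masking, and NUMT contamination. Passing recovery tests therefore
show the estimators respond correctly to spatial haplotype-frequency
structure, not that they are robust to every artefact of real compilations.

## Numerical choices and limitations

- Distance matrices are exact rational fractions represented in floats;
  the diff-count invariant (distance × compared sites is an integer) is
  asserted in tests to 1e-9.
- PCoA eigenvalue positivity threshold: max(1e-12, 1e-10·λ_max).
- Haplotype ids are assigned by descending count, then first member id, so
  outputs are byte-stable under a fixed seed.
- The equal-area projection is spherical, not ellipsoidal; at continental
  extents the distortion (< 0.3%) is far below the grid-size granularity
  of the G_ST design.
- Joint analyses share one pooled PCoA; a highly divergent species pair
  compresses within-species color variation — intended, since the joint
  view is for closely related, potentially introgressing species.
- G_ST replicate eligibility can differ across cell sizes for sparse
  species; the mean is taken over defined replicates only, so the
  effective replicate count is recorded per species in the JSON report.
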