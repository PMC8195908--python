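# Methods note

## Volume conductor

The head model is three concentric spheres — brain, skull, scalp — with
radii 0.87, 0.92, 1.0 (normalized by the scalp radius) and relative
conductivities 1.0, 0.0125, 1.0 (classical Rush–Driscoll values). For a
current dipole at radius `b < 0.87` the scalp potential against a
reference at infinity is

```
V(e) = 1 / (4 pi sigma_1 r1^2) * sum_n T_n (b/r1)^(n-1)
       [ n m_r P_n(cos g) + P_n'(cos g) (m . (e_hat - cos g r0_hat)) ]
```

with `g` the angle between electrode and source, `m_r` the radial moment
component, and `T_n` the per-degree transfer coefficient obtained by
solving the 5×5 linear system expressing continuity of potential and
radial current density at the two shell interfaces. The radial bases are
scaled per layer so the system stays well conditioned at high degree.

**Validation.** In the homogeneous limit (skull conductivity set to 1) the
series matches an independently derived closed form (generating-function
summation of the boundary-corrected series) to relative error < 1e-9 over
1,000 random dipole/electrode pairs; the solution is rotation invariant to
1e-10 and linear in the dipole moment.

**Series truncation.** Terms decay like `(b/r1)^(n-1) n |T_n|`. The
default equivalent-source cap sits at radius 0.869 inside a brain sphere
of 0.87, so the ratio is 0.9989 relative to the cap and ~330 terms are
needed for the default tolerance of 1e-12; the series cap is
`n_terms_max = 500` with early termination after two consecutive
below-tolerance terms, and a `SeriesConvergenceWarning` if the cap is hit.
Doubling `n_terms_max` changes the default lead field by less than
10 × the tolerance.

## Equivalent-source layer

3,000 unit dipoles close a surface inside the brain: 2,600 radial dipoles
on a spherical cap of radius 0.869 placed by a Fibonacci spiral (equal
area in z, golden-angle azimuths; nearest-neighbor spacing has CV < 0.25)
and 400 +z dipoles on the closing transverse plane at z = −0.076 in a
sunflower layout. All counts and geometry are configurable.

## Interpolators

* **RESIT.** Restrict the infinity-reference lead field to the N−k good
  channels, transform it to the data's reference (subtract the row mean
  for the average reference; subtract the reference electrode's row for a
  point reference), form the Moore–Penrose pseudoinverse with relative
  singular-value cutoff `pinv_rtol = 1e-8`, estimate sources and forward
  project to all N electrodes. The effective rank is logged (`rank_`);
  for an average-referenced montage it is N−k−1. With k = 0 the map is
  exactly REST reference standardization.
* **SSI.** Perrin-style spherical splines: kernel
  `g(x) = 1/(4 pi) sum (2n+1)/(n(n+1))^4 P_n(x)` truncated at 50 terms,
  exact interpolation with the zero-sum coefficient constraint imposed
  through a bordered linear system factorized once per montage/bad split.
  The transfer matrix matches MNE-Python's implementation with its
  Tikhonov term disabled to 6e-10; no regularization is applied, matching
  the classical formulation.
* **NI.** Unweighted mean of the 4 nearest good channels by angular
  distance, ties broken by label for determinism.

All three are linear operators for a fixed montage/bad split and are
exposed as scikit-learn transformers.

## Synthetic data

The simulator uses the same three-shell physics but independent sources:
dipoles drawn uniformly in a ball of radius 0.8 with random orientations,
explicitly kept off the equivalent-source nodes (no inverse crime) unless
`inverse_crime=True` deliberately places them on grid nodes with grid
orientations for exact-recovery tests. Signal models: 1–30 Hz filtered
noise (resting), 10 Hz sinusoids (alpha), and an epoched ERP with a
dominant positive peak at 300–400 ms. The clean scalp RMS is scaled to
10 µV and white sensor noise of 2 µV SD is added (SNR 5).

## Assessment protocol

Channels are declared bad at fractions 2%–85% of the montage, scattered
(uniform without replacement) or as one adjacent patch (single-linkage
growth from a uniform seed channel), with 20 repeated draws per fraction;
`k = round(fraction × N)`, clamped to ≥ 1 and rejected if fewer than 3
good channels remain. Reconstructions are scored against the recorded
data (as in benchmarking on real recordings) by MAE, relative absolute
error and mean per-channel Pearson r; RESIT output is re-referenced to
the average before scoring so all methods share a reference frame. The
per-cell RNG is `SeedSequence((seed, fraction_index, repeat))`.

## Known quantitative limits

These are measured properties of the method, encoded as expected-failure
acceptance tests (left failing rather than weakened):

1. **Inverse-crime recovery is not exact.** With 56 good channels the
   average-referenced lead field has exact rank 55 (singular values fall
   off smoothly to sigma_54/sigma_0 ≈ 2.6e-2, then machine zero), so the
   minimum-norm estimate projects the true source vector onto a rank-55
   subspace of the 3,000-dimensional source space. For sparse grid
   sources the component lost by this projection is generically visible
   at the bad channels: with 10 grid sources, zero noise and 10% scattered
   bads, the worst per-channel correlation is typically 0.97–0.99
   (observed minimum 0.92), crossing 0.99 on all channels in only ~2/10
   seeds. The shortfall concentrates at electrodes adjacent to an active
   source and at low/rim electrodes below the source cap, and is
   independent of `pinv_rtol` anywhere in (1e-15, 2e-2). For dense
   (full-grid) sources RESIT numerically attains the optimal linear
   predictor of bad from good channels, confirming the solver itself is
   exact.
2. **Adjacent-patch dominance saturates.** At adjacent fractions ≥ 25%
   (16–31 contiguous bad channels) every method approaches the
   sensor-noise floor (MAE ≈ 3.0 µV at SNR 5) and per-seed sign tests
   between RESIT and NI are near chance, although RESIT dominates both
   baselines at every scattered fraction and at small adjacent fractions.
3. **SSI error is not monotone in the adjacent fraction.** Exact
   (unregularized) spline interpolation overfits sensor noise; its
   adjacent-case MAE dips between 10% and 50% before rising at 85%.

## Problem sizes and runtimes (single CPU)

* Default lead field (62 × 3,000): ~1.5 s including the Legendre series.
* RESIT fit (SVD of 56 × 3,000): ~0.2 s; transform is a matrix product.
* Full 20-seed benchmark (2 cases × 5 fractions × 20 repeats × 3
  methods): ~90 s.
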