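# Methods

## Problem and targets

The package learns two closely related targets from atomic structure
(atomic numbers Z_i and positions R_i in Å):

* **levels head** — the 16 highest occupied level energies in eV, ordered
  descending so index 0 is the HOMO. Molecules with fewer than 16 occupied
  levels are excluded at dataset assembly (they simply carry no label row).
* **spectrum head** — the occupied density of states obtained by giving
  each level a unit-area Gaussian of width σ = 0.5 eV and sampling the sum
  on a uniform 300-point grid over [−30, 0] eV (both endpoints included;
  spacing 30/299 ≈ 0.100 eV). With unit-area broadening the spectrum
  integrates to the number of levels in range, which fixes the intensity
  scale (states/eV) and makes the 0.1 screening threshold meaningful.

The 0.5 eV width is interpreted as the Gaussian σ; a FWHM reading is
available behind a flag (`width_is_fwhm`), as is the height-normalized
convention, but the defaults above are used everywhere in the package.

## Representations

**Coulomb matrix** (MLP/CNN input): C_ij = Z_i Z_j / d_ij with d_ij in
Bohr (1 Å = 1.8897261254578281 Bohr), diagonal C_ii = 0.5 Z_i^2.4, zero-
padded to the dataset's largest atom count n_max. Because the matrix is
only defined up to atom relabeling, rows/columns are simultaneously sorted
by descending row norm (ties: descending diagonal, then original index)
before flattening; this gives a deterministic canonical form and makes
MLP/CNN predictions invariant to input atom order whenever row norms are
distinct. Random-permutation augmentation is deliberately not implemented.

**Distance expansion** (DTNN input): the pair-distance matrix is expanded
on a uniform grid of Gaussians, exp(−(d_ij − μ_g)²/2w²). The default grid
is 0–4 Å in steps of 0.2 Å with width 0.2 Å — wide enough to cover bonded
and next-neighbor separations in small organics — and is configurable;
these are this package's defaults, not values taken from elsewhere.
Diagonal and padding entries expand to the zero vector.

## Architectures

All three models end in a linear layer to 16 (levels) or 300 (spectrum)
outputs. Outputs are unconstrained: the levels head is not forced to be
monotone (states are treated as fixed slots, and a sorting layer would
scramble per-state error attribution; a monotonicity-violation counter is
available), and the spectrum head may produce small negative intensities,
which are flagged but not clipped.

* **MLP**: affine layers with rectifier nonlinearity on the flattened
  upper triangle (length n_max(n_max+1)/2); zero hidden layers degenerate
  to a single affine map.
* **CNN**: valid convolutions (stride 1) + rectifier + max pooling
  (average pooling available), repeated, then a dense head. Feature maps
  are cropped to a multiple of the pooling window.
* **DTNN**: each atom starts from a per-element embedding c_i⁰ ∈ R^d.
  One interaction pass updates every atom by a sum over neighbors,

      c_i ← c_i + Σ_{j≠i} tanh( W_fc [ (W_cf c_j + b_cf)
                                    ⊙ (W_df g(d_ij) + b_df) ] ),

  where g(d) is the Gaussian distance expansion and ⊙ the element-wise
  product; the projection weights are shared across passes, so the
  distance projection is computed once. After T passes a per-atom network
  (tanh) is applied, summed over real atoms (padding is masked out of
  every sum), and mapped linearly to the output. Sum pooling gives exact
  permutation invariance; distances-only input gives rotation/translation
  invariance. T = 0 degenerates to a bag-of-atoms model. The gated update
  is one reconstruction of the tensor-interaction idea and is isolated in
  a single method so alternative update rules can be swapped in.

The networks are differentiated by a small reverse-mode autodiff engine
(`levelnet.autodiff`) written for exactly the operations the models need;
gradients are verified against central finite differences in the test
suite.

## Training protocol

90% of the data trains the model; the remaining 10% is split equally into
validation and test (round(N·0.05) each, remainder to train, so N = 1000
gives 900/50/50). Loss is mean squared error on the head's targets — for
spectra, pointwise on the grid, matching the RMSE-style reporting. Adam
(β₁ = 0.9, β₂ = 0.999) with minibatches, early stopping on validation
loss, restore-best-epoch, and an optional reduce-on-plateau learning-rate
schedule (factor 0.5 after 8 flat epochs by default). Targets are
standardized per output dimension on train-split statistics and
de-standardized inside the model; Coulomb-matrix inputs are standardized
per feature the same way (distance expansions are already in [0, 1]). All
randomness — geometry generation, splits, initialization, batch order —
flows from named integer seeds, so runs are bit-reproducible; the test set
never influences any trained parameter.

Metrics: per-state RMSE and squared Pearson correlation across test
molecules (the coefficient of determination is reported alongside, Pearson²
is the headline number); for spectra, the relative spectral error
RSE = Σ_g |pred_g − ref_g| / Σ_g ref_g, an L1-relative deviation — 0 for a
perfect prediction, 1 for an all-zero one, |c − 1| for a spectrum scaled
by c. An L2 variant was considered and rejected to keep the error
interpretable as misplaced spectral mass. Exemplar triage picks the
best / closest-to-mean / worst test molecules by RSE with lexicographic
tie-breaks.

Hyperparameter search is sequential model-based optimization: a
Matérn-5/2 Gaussian-process surrogate over the unit-cube-encoded search
space with expected-improvement acquisition maximized over a seeded
candidate cloud, after a few random initial trials; a seeded random-search
strategy shares the interface. Fully discrete spaces small enough to
enumerate within budget are enumerated exactly.

## Synthetic data

The generator stands in for quantum-chemistry labels. Geometries: 16–23
atoms (uniform), elements drawn from {H: 0.50, C: 0.30, N: 0.10, O: 0.07,
F: 0.03}, positions uniform in an 8 Å box rejection-sampled to keep all
pairs ≥ 0.9 Å apart. Labels: the 16 largest eigenvalues of
H_ii = α(Z_i), H_ij = −β exp(−d_ij/r0) with on-site energies
α = −14/−20/−23/−26/−29 eV for H/C/N/O/F, β = 8 eV, r0 = 1.5 Å. Candidate
molecules whose 16 levels do not all lie inside (−30, 0) eV are rejected
and regenerated (not clipped), so every record passes the 16-level filter
and fits the grid exactly.

This surrogate shares the symmetries and smoothness of real orbital
energies (invariant under rigid motions and relabeling; Lipschitz in the
coordinates) and is genuinely distance-dependent, so the DTNN's inductive
bias is exercised and learning curves are meaningful. It does **not**
reproduce chemistry: no bonding/valence constraints, no shell structure,
no correlation between composition and geometry. Passing tests therefore
demonstrate that the pipeline and architectures work and rank as expected
on a learnable geometric task — not that any accuracy level carries over
to DFT-labeled molecules.

## Screening

Given predicted spectra for a library: the presence histogram counts, at
each grid energy, the molecules whose intensity exceeds 0.1 (a molecule is
counted at every grid point it exceeds the threshold, not once per peak);
the average spectrum is the pointwise mean; low-energy outliers are
molecules with above-threshold intensity below −18 eV, ordered by their
lowest such energy; the ionization ranking takes the k = 6 largest −ε₀
from the levels head (Koopmans reading — the only ionization proxy the
model provides). The ±1σ confidence band comes from an ensemble of
independently seeded retrainings (default 3): pointwise mean ± one sample
standard deviation across members, then averaged over molecules. The −18 eV
bound and 0.1 threshold are configuration defaults, not constants. On the
synthetic distribution the −18 eV default flags nearly every molecule
(surrogate levels intentionally span the whole grid), so the screening
tests validate outlier recovery on explicitly planted signals instead.

## Problem sizes

The test suite trains on small synthetic sets (100–800 molecules) for unit
checks; the learning comparison and the acceptance script use
1200–2000-molecule datasets with the DTNN at T = 2, embedding dimension
32, readout (96, 96), trained for roughly 80–170 epochs — sizes chosen so a full run
completes in minutes on a single CPU while the DTNN still clearly
outperforms both the mean-spectrum baseline and an equally budgeted MLP.
Headline accuracies at these sizes are properties of the synthetic task at
desk scale, not estimates of any published number.

## Known limitations

* The CNN is the weakest of the three at small data sizes and is provided
  for architectural completeness; no pooling variant rescues it at n ≲ 10³.
* Predicted spectra are unconstrained, so small negative intensities occur;
  they are flagged (`Spectrum.has_negative`) but intentionally not clipped.
* The Bayesian optimizer assumes a smooth objective over the encoded cube;
  categorical dimensions are handled by binning, which the GP smooths over.
* HDF5 caches store zero-padded coordinate arrays; atom count is recovered
  from nonzero atomic numbers, so a hypothetical Z = 0 entry is not
  representable (not a real element, so not a practical limit).
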