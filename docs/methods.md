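# Methods

## Scope and model

`itemfive` analyses stepwise collision-induced dissociation (CID) of
non-covalent protein homo-oligomer ions measured by native electrospray
mass spectrometry.  A mass-selected precursor (here: the quintuply
protonated homo-trimer of a 27-residue trimerization-domain peptide and
its engineered variants) is accelerated into a collision cell at a series
of collision-voltage differences (dCV).  At each step the surviving educt
(trimer 5+) and the released products (dimer 3+, monomer 2+) are
monitored; the *survival yield* SY(dCV) is the educt's share of the summed
monitored intensities, normalized to 100 %.

The analysis chain is:

1. **Extraction and normalization.**  Target-ion intensities are summed
   inside a closed +/-0.5 u/charge window around the sequence-derived m/z
   values; species intensities are normalized to 100 % per spectrum and
   averaged across replicates.  The window is closed (|dm| <= tol) because
   the extraction threshold is stated as a symmetric tolerance; boundary
   peaks are included.  Baseline/noise removal keeps peaks at or above the
   configured threshold (strict removal below it); the threshold value
   itself is explicit configuration, not inferred from the data.
2. **Boltzmann fit.**  SY(dCV) is fitted with the four-parameter sigmoid
   y = A2 + (A1-A2)/(1+exp((x-x0)/dx)).  Plateaus are free by default
   (sodium adducts and residual signals can shift them); a pinned 100/0
   variant is a flag.  Initialization: A1 = max, A2 = min, x0 from linear
   interpolation of the half-height crossing (falling back to the nearest
   point), dx = dCV-range/10 with two alternative widths tried and the
   lowest chi-square kept.  The sigmoid is evaluated through the logistic
   function, so steep trial widths cannot overflow.
3. **Tangent linearization.**  The analytic tangent at the midpoint has
   slope (A2-A1)/(4 dx) and passes through (A1+A2)/2.  Five points, evenly
   spaced where the tangent's SY lies in [10 %, 90 %], feed the kinetic
   treatment; the bounds keep all logarithms finite.  Results are
   insensitive to the number of points on a line by construction (any
   n >= 2 reproduces slope and intercept exactly for noiseless input).
4. **Temperature transform.**  dCV maps to an effective collision
   temperature through the centre-of-mass collision energy:
   T_coll = T_amb + z e dCV (m_gas/(m_gas+m_ion)) / (dof_factor k_B).
   `dof_factor` is the effective number of internal degrees of freedom
   sharing the deposited energy; it is an explicit instrument constant.
5. **Rates and free energies.**  k# = -ln(SY)/residence_factor is the
   dimensionless apparent rate constant of a quasi-first-order decay over
   a fixed residence interval; dG#(T) = -R T ln(k# h/(k_B T)) is its
   Eyring-form activation free energy.
6. **Linear diagrams and extrapolation.**  ln k# vs 1/T (Arrhenius) and
   dG# vs T (Ellingham) are fitted by least squares and evaluated at
   T_amb, giving the "m0g" quantities (mean charge state, zero external
   energy, gas phase): k#_m0g, KD#_m0g = exp(-dG#/(R T_amb)), dG#_m0g,
   dH#_m0g (Ellingham intercept) and T_amb dS#_m0g.  dG# = dH# - T dS#
   holds exactly by construction.

## Instrument constants and calibration

The two constants that set the absolute scale - `dof_factor` and
`residence_factor` - are instrument- and method-dependent and cannot be
derived from first principles for a travelling-wave instrument.  They are
therefore explicit fields of `CollisionConditions`, and
`thermo.calibrate_conditions` solves them at run time from a published
reference pair (dH#, T_amb dS#) of one analyte measured on the same
instrument.  The nonlinear system has several isolated roots; the root
kept is the one whose two extrapolation routes (Arrhenius rate vs Eyring
free energy) agree best at T_amb - a physical consistency criterion.  For
the reference trimer this yields dof_factor ~ 22 effective degrees of
freedom and residence_factor ~ 2e-13 (of order a vibrational period),
both physically plausible magnitudes.  Constants calibrated on the
reference analyte transfer to the other variants of the same series
(same instrument, gas, charge state; per-analyte ion masses).

With calibrated constants the pipeline reproduces the reference
thermodynamic triple exactly and the equilibrium-type constant to ~1 %;
the Arrhenius-route rate constant agrees with the published value to
within ~20 % (the published rate and equilibrium columns are not exactly
Eyring-consistent with the published free energy at any single ambient
temperature, so order-of-magnitude agreement is the appropriate
validation there).  The ambient temperature used in analysis configs is
295 K, the value at which the published rate, equilibrium constant and
free energy of the reference trimer are mutually consistent; the library
default remains 298.15 K.

## Synthetic study conditions

The generator emulates the reference experiment, and its defaults are the
study conditions: an 11-step dCV schedule (0, 2, 5, 7, 10, 12, 15, 20,
30, 40, 50 V), two independent replicates, trimer 5+/dimer 3+/monomer 2+
targets at sequence-derived m/z, Gaussian peaks (sigma 0.08 u/charge),
and 2 % Gaussian noise applied to the normalized educt fraction (noise on
fractions, not raw counts, because the analysis operates on normalized
intensities; a Poisson raw-count mode is out of scope).  The dissociated
signal is split between dimer and monomer with a share that decays as the
transition proceeds, mimicking the observed mid-curve dimer maximum; this
split does not enter any quantitative result.

The Boltzmann width truth is dx = 2.0 V.  This value is set once from the
reported spectra phenomenology (roughly one third of trimers surviving at
15 V and near-complete dissociation at 20 V for a 13.5 V midpoint) and is
also the smallest width for which a physical (dof_factor,
residence_factor) pair reproduces the published reference enthalpy and
entropy; narrower transitions admit no solution under the
centre-of-mass/Eyring treatment.

What the generator does *not* emulate: isotope patterns, sodium adducts,
charge stripping, detector saturation, truncated-monomer satellites, and
drift of the m/z axis.  Passing tests therefore demonstrate correctness
of the analysis chain and its estimators under controlled conditions, not
robustness to every artifact of real spectra.

## Mobility calibration

Travelling-wave CCS calibration follows the standard published procedure:
dead-time correction t' = td - EDC sqrt(m/z)/1000, charge/reduced-mass
normalization CCS' = CCS sqrt(mu)/z with nitrogen (28.0134 u) as the
default buffer gas, and either a log-log power-law fit (default) or a
linear fit of CCS' vs t'.  The EDC coefficient is a required instrument
constant with no hidden default (0 in synthetic tests).  Arrival-time
profiles are summarized by intensity-weighted centroid and sd and by a
linearly interpolated FWHM; a single nonzero bin reports the grid spacing
as its FWHM.

## Structure metrics

Contacts are classified by geometric criteria on heavy atoms: van der
Waals contacts as carbon-carbon pairs within 4.0 A (excluding pairs
within one residue or between sequence-adjacent residues of the same
chain as covalent/1-3 neighbours), hydrogen bonds as donor (N or hydroxyl
O) to acceptor (O) pairs within 3.5 A without an angle term (the target
crystal/NMR structures lack hydrogens), and salt bridges as Asp/Glu
carboxylate O to Arg/Lys/His basic N pairs within 4.0 A.  Between-chain
(intercatenane) contacts must additionally satisfy the <= 4 A
intercatenane criterion.  Published interface tables produced with
third-party tools use partly undisclosed per-type cutoffs, so count
agreement with them is qualitative, not digit-exact.

Per-residue interchain C-alpha distances match residues by position after
renumbering each chain from its first resolved residue (insertion codes
unsupported); the global sum over all positions and chain pairs is the
compactness measure.  SASA is the Shrake-Rupley number computed by
biotite with a 1.4 A probe; it is deterministic for a fixed sphere-point
count and its absolute value depends on the van der Waals radius set
(ProtOr group radii by default), so cross-tool comparisons carry a
few-percent radius-set uncertainty.

Synthetic three-fold-symmetric trimers place every C-alpha at radius
d/sqrt(3) from the symmetry axis, making all three interchain distances
per position equal to d exactly; contact counts on these fixtures are
verified against a brute-force all-pairs enumeration.  Real deposited
coordinate files are read with the same `read_structure` entry point
(model selection for NMR ensembles, occupancy-resolved altlocs, waters
excluded); no network fetch happens inside the library.

## Problem sizes and numerical choices

Default analyses use 11-point curves, 2 replicates, 5 tangent points, and
100-seed ensembles for estimator contracts; synthetic trimers use 8-27
residues.  These sizes match the emulated experiment and keep the full
suite and the acceptance script in the seconds-to-minutes range.
Determinism: all randomness flows from explicit integer seeds through
`numpy.random.default_rng`; repeated runs are byte-identical.  Degenerate
inputs (all-zero intensities, neutral ions, non-positive survival yields,
singular fit designs, unmatched chains) raise informative errors rather
than propagating NaNs.

## Known limitations

* The absolute kinetic/thermodynamic scale depends on the calibrated
  instrument constants; only differences between analytes measured under
  identical conditions are instrument-independent.
* Single-step sigmoids only; multi-step dissociation (double sigmoids)
  and product-rise fitting are out of scope.
* The text peak-list dialect is the only reader; profile-mode peak
  picking, charge deconvolution and vendor raw files are out of scope.
* Hydrogen-bond detection is distance-only by default; directional terms
  would require modeled hydrogens.
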