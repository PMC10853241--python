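# Methods

This note documents the models behind each `cryostab` stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that matter for reproducing results.

## Coordinate model

PDB files are parsed by fixed columns (v3.3 ATOM/HETATM layout). Multi-model
files (MODEL/ENDMDL) are treated as conformational ensembles over the atom
roster of the first model; a model whose atom count or identity order differs
from the roster is an error, not a warning. Alternate locations are resolved
to the highest-occupancy conformer, ties to the alphabetically first altloc —
deterministic and conventional. Waters (HOH) are dropped on read; other
heteroatoms stay on the atom list but are excluded from the residue index
unless requested, because every downstream computation is protein-only.
Residues are identified by author numbering with insertion codes throughout,
since that is how mutation sites are communicated. Coordinates round-trip
through the writer at PDB precision (1e-3 Å). mmCIF, symmetry expansion and
hydrogen handling are out of scope.

## Flexibility (RMSF) profiling

Frames are superposed by the Kabsch algorithm (SVD of the weighted covariance;
a reflection is corrected by flipping the sign of the smallest singular
vector, so the rotation is always proper). Numerically degenerate inputs
(< 3 points, collinear sets) are rejected rather than silently fit.

The ensemble is aligned to its *mean* structure, iteratively: superpose all
frames on the current mean, recompute the mean, repeat until the mean moves
by less than 1e-6 Å (at most 10 iterations). This removes the arbitrary
choice of a reference frame. The fit selection defaults to Cα atoms,
unweighted — mass-weighting is a tradition from MD packages, not a
requirement of the statistic, and an unweighted Cα fit is deterministic and
easy to reason about. Per-atom RMSF is the root-mean-square deviation from
the mean position over frames; the per-residue value is the mean over the
residue's profile atoms (Cα by default, optionally backbone or all heavy
atoms). A strictly static ensemble short-circuits to exactly zero so SVD
roundoff cannot manufacture ~1e-14 Å of apparent motion.

Caveat used by the recovery tests: superposition *absorbs* fluctuation into
the 6 fitted rigid-body degrees of freedom. With only ~50 fit atoms this
biases recovered RMSF low by ~2%; fitting on all atoms reduces the effect
below 1%. Real MD analyses rarely notice because the atom count is large.

Flexible regions are maximal runs of consecutive residues at or above a
user threshold with a minimum run length; the mean and peak RMSF of each run
are reported. Thresholds are data-dependent by design (profiles from
different ensembles have different scales), so the pipeline default is the
75th percentile of the profile.

## Disulfide candidate scan

Design criteria, quantified:

* **Flexibility** — at least one residue of the pair has RMSF at or above the
  threshold (default: profile 75th percentile).
* **Cβ separation** — within [3.0, 5.0] Å, target 4.0 Å. The window brackets
  Cβ–Cβ distances observed in natural disulfides; it is configurable.
* **Ice-binding site** — neither residue within 8 Å (any-atom minimum
  distance) of a user-supplied IBS residue list. The IBS is an *input*: the
  flat ice-docking sheet cannot be derived from coordinates alone.
* **Sequence separation** ≥ 3 residues, to exclude trivially adjacent pairs.

Glycines (or any residue without a stored Cβ) get an idealized virtual Cβ
constructed from the N/CA/C frame at 1.53 Å with L-amino-acid chirality, so
flexible glycine-containing sites remain scannable.

The geometry screen places idealized Sγ atoms (Cβ–Sγ 1.81 Å, Cα–Cβ–Sγ 114°)
on both residues over a χ1 grid and minimizes

    penalty = (d(Sγ,Sγ) − 2.05 Å)² · 1 Å⁻²  +  (dev(χ3)/30°)²

where dev(χ3) is the angular distance of the Cβ–Sγ–Sγ–Cβ torsion from the
nearest of ±87°. The default scan uses a 10° grid followed by a deterministic
1° local refinement around every competitive coarse basin (within 2.0 of the
coarse minimum, capped at 200 points). The refinement makes the reported
score insensitive to the coarse step: it agrees with an exhaustive 1° grid
to well under 0.05 in the test suite. The score is a *screening* heuristic —
it ignores sterics, backbone relaxation and energetics, which is appropriate
for ranking candidates that will be verified experimentally, and pairs with
penalty above 10 are discarded.

Ranking: `flex / (1 + penalty + |d − target|)`, flex = mean pair RMSF; ties
break on lower penalty, then residue identity, so output order is total and
reproducible. The scan is brute force over all pairs — protein-sized inputs
make smarter data structures unnecessary — and the test suite holds it equal,
item for item, to an independently coded filter.

## Thermal-shift (melt-curve) analysis

The observable is the F350/F330 intrinsic-fluorescence ratio on a 35–95 °C
ramp (ramp rate is metadata; no kinetic modeling). Two estimators:

* **Derivative method** — Savitzky–Golay smoothing (window 7, order 3,
  with the filter's own first derivative; the extrapolated half-window at
  each edge is clamped), additional second-order smoothing of |d ratio/dT|
  (window 21) for peak localization, then a least-squares parabola over the
  peak ±7 points. Curves whose smoothed swing is within 10× the residual
  noise, whose peak does not stand 2× above the median slope, or whose peak
  sits in the edge guard zone raise `NoTransitionError` instead of returning
  a number.
* **Two-state fit** (default reportable) — nonlinear least squares of the
  van 't Hoff two-state model with linear folded/unfolded baselines,
  initialized from the derivative estimate and endpoint baselines, Tm bounded
  to the scanned range, ΔH ∈ [1, 5000] kJ/mol, with up to 3 jittered restarts
  (fixed sub-seeds) on failure. A fitted Tm within 2 °C of a scan edge is
  flagged `at_boundary` — never reported as a silent interior Tm.

The two methods cross-validate each other (median agreement ≪ 0.5 °C on
synthetic curves); the instrument's internal algorithm is proprietary, so
this cross-check stands in for it.

Chemical series (Tm vs co-solvent concentration, must include 0) are grouped
by total shift `Tm(max conc) − Tm(0)`: |shift| ≤ 2 °C → group A (flat),
≥ 10 °C → group C (drastic), else group B. Both thresholds are configurable;
they encode "relatively unchanged" vs "drastic" and make the grouping
deterministic. A positive shift marks a stabilizer (glycerol-like). With two
proteins, the series also reports whether the inter-protein Tm gap is
preserved within the flat tolerance at every concentration; for one or more
than two proteins that field is None. Multi-protein total shift is the mean
of per-protein shifts.

## CD deconvolution

Spectra are Δε (M⁻¹cm⁻¹) on a 190–250 nm grid (0.5 nm steps by default;
other uniform grids are linearly resampled onto the overlap, which must span
≥ 50 nm). Each spectrum is decomposed into four fractions (helix, β-strand,
turn, other) by non-negative least squares with a sum-to-one constraint
imposed through an augmented equation weighted at 100× the mean basis-row
norm, then renormalized exactly onto the simplex. Fractions are therefore
always non-negative and sum to 1 for *any* input; the residual tells you
whether the decomposition is meaningful. Scaling a spectrum without scaling
the basis changes the fractions — the constraint pins the overall scale —
which is intended and tested.

The packaged basis is **synthetic**: four Gaussian-band spectra with textbook
far-UV features (helix: positive ~192 nm, negative 208/222 nm; β: positive
~196, negative ~218; turn: negative ~190, positive ~205; other/coil: strong
negative ~198). Band amplitudes were set so the four components are
well-conditioned as a linear system — a requirement for the deconvolution to
be identifiable at realistic noise. It is *not* a measured protein reference
set, so absolute fractions are comparable only within this package;
published reference-library fractions for real proteins are not reproduction
targets. Multi-state melt deconvolution (e.g. a two-step denaturation seen
in some stabilized mutants) is flagged by a rising residual but not modeled.

**Onset detection**: baseline = mean and per-wavelength SD of the 3
lowest-temperature spectra; each spectrum's departure is the RMS over
wavelengths of (s−μ)/σ. Because a 3-sample SD has t₂ tails, each
wavelength's σ is floored at the median per-wavelength σ — without this the
false-positive rate on pure noise is not controllable. The onset is the
lowest temperature whose departure exceeds z (default 3) *and stays exceeded
at every higher temperature*; the persistence requirement prevents
single-spectrum noise triggers. Returns None when the series never departs.

**Single-wavelength Tm**: the Δε(T) trace at the nearest grid wavelength
(default 210 nm, which tracks the helix band) is fit with the same two-state
machinery as the fluorescence module, with the derivative method as a
fallback when the fit fails or pins to the scan edge. Fluorescence and CD
report different observables — the two Tm values are never reconciled.

## IRI (splat-assay) quantification

Grain boundaries image dark between bright birefringent grains. The boundary
mask is every pixel below 20% of the image's min–max intensity range. A
fixed fraction of the *range* (rather than an image quantile) separates a
bimodal dark-boundary/bright-grain histogram regardless of how much of the
field the boundaries cover; a quantile threshold would start eating the
dimmest grains whenever boundaries cover less of the field than the chosen
percentile. An absolute threshold and an inverted mode (bright boundaries)
are exposed for real micrographs with different illumination.

Grains are 4-connected components of the complement; components under
10 pixels are despeckled; components touching the image border are excluded
from statistics by default because their full dimension is unobservable
(configurable). Each grain's largest dimension is its max Feret diameter —
the exact maximum pairwise distance over its pixels — computed via convex
hull + rotating calipers, with all-pairs brute force for small or degenerate
(collinear) grains. On integer pixel coordinates both routes are exact and
agree bitwise. MGS is the mean of the k = 30 largest dimensions (all grains,
with a warning, when fewer are present), and relative MGS divides by a
no-IBP control measured at the same pixel scale.

## Synthetic generators

All generators are pure functions of (parameters, integer seed); the same
seed reproduces output byte-for-byte, and every generator's output is
accepted by its consuming module at defaults.

* **Toy scaffolds** — rigid idealized alanine units (N/CA/C/O/CB) spaced
  6.5 Å along a circular arc whose radius grows with chain length, side
  chains outward, small seeded orientation jitter. An optional planted pair
  is posed in *exact* ideal disulfide geometry (Sγ–Sγ 2.05 Å, χ3 = +87°,
  Cα–Cβ–Sγ 114° both sides, Cβ–Cβ tuned to exactly 4.0 Å by solving for the
  Cβ–Sγ–Sγ angles) and lifted off the arc plane; construction verifies that
  every other pair falls outside the [3, 5] Å scan window and raises if the
  planting is infeasible. These are scan fixtures, not protein models: the
  units are not peptide-bonded.
* **Trajectories** — frame = reference + i.i.d. per-atom Gaussian
  displacement (per-residue σ, per coordinate) + a random global rigid
  motion to exercise superposition. Under this model per-atom
  RMSF = σ√3. This emulates the *stationary positional statistics* RMSF
  assumes — not MD physics: no covariance between atoms, no time
  correlation, no anisotropy. A green recovery test establishes estimator
  correctness, not realism of any force field.
* **Melt curves** — the exact two-state ratio model plus i.i.d. Gaussian
  noise on a 35–95 °C, 0.5 °C grid. Default baselines (0.85 + 0.0002·T
  folded, 1.05 + 0.0005·T unfolded) mimic typical 350/330 ratio ranges;
  default noise σ = 0.002 ratio units is instrument-realistic. No
  aggregation, scattering, or scan-rate effects.
* **CD series** — spectra are simplex mixtures of the packaged basis plus
  Gaussian noise scaled to a fraction (default 1%) of the basis maximum, on
  the 20–90 °C / 2 °C ramp; a helper builds two-state (van 't Hoff) fraction
  schedules between folded and unfolded compositions. Linear mixing is the
  same assumption the deconvolution makes, so these tests check inversion,
  not spectroscopy.
* **Splat images** — Voronoi tessellation of uniformly scattered seeds
  (rejection-sampled to a minimum separation; failure to place them raises
  "too dense"), per-grain constant brightness in [0.7, 1.0], dark (0.05)
  boundary channels where the two nearest-seed distances differ by less than
  the channel width, quantized to 8-bit. Ground truth per grain is the max
  Feret diameter of the *rasterized interior* cell (computed by brute force
  at generation time) plus a border flag — the continuous polygon diameter
  is systematically larger than anything observable in the image because the
  dark channel erodes cell corners, so the rasterized value is the right
  reference for pipeline comparisons. No birefringence texture or optics.

## Pipeline and reproducibility

The `run` pipeline validates its YAML config strictly (unknown keys are
errors before any stage runs), derives one sub-seed per stage from the root
seed via named `SeedSequence` spawn keys, executes stages in dependency
order, and aborts on the first failure naming the stage. Every run writes a
manifest (package version, resolved config, per-stage seeds and outputs);
with a fixed seed all reports are byte-identical across reruns except the
manifest timestamp.

## Known limitations

* The geometry screen is not an energy; it will happily accept a pair whose
  side chains clash with neighbors.
* RMSF thresholds and the candidate ranking are heuristics; the ranked list
  is a shortlist for experiments, not a prediction of which bridges form.
* The CD basis is synthetic; fractions are internally consistent, not
  comparable to published reference-set deconvolutions.
* Segmentation assumes bimodal dark-boundary images; real crossed-polarizer
  micrographs with texture inside grains need the absolute-threshold or
  inverted modes, or external preprocessing.
* Acceptance testing is oracle- and recovery-based on synthetic data:
  laboratory headline numbers (absolute Tm values of real proteins, thermal
  hysteresis activity, absolute grain sizes) are instrument- and
  sample-dependent and are not desk-reproducible targets.
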