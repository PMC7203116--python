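# Methods

`pilax` implements the computational chain used to characterise helical
protein filaments of the type IV pilus (T4P) family: inferring the helical
symmetry of a filament from the power spectra of its projection images,
expanding a single pilin subunit into an atomic filament model by that
symmetry, analysing the inter-subunit contacts and salt bridges that hold
the filament together, and classifying filament populations by centreline
curvature. Every stage can be driven end to end on synthetic data with
known ground truth.

## Helical lattice model

A 1-start helical filament is described by its **rise** Δz (axial
translation per subunit, Å) and **twist** Δφ (azimuthal rotation per
subunit, degrees). Derived quantities:

- pitch `P = Δz · 360/Δφ` (axial length of one turn),
- subunits per turn `N = 360/Δφ`,
- exact repeat: the smallest coprime pair (u subunits, t turns) with
  `u/t ≈ N`; the repeat length is `c = u·Δz`.

Layer lines in the Fourier transform of a filament appear at axial
frequencies `l/c` for integer l; the Bessel orders n permitted on line l
obey the selection rule `l = t·n + u·m`. Two consequences used throughout:
the line at `l = t` has order 1 and sits at `1/P`, and the line at `l = u`
admits order 0 (the meridional reflection) at `1/Δz`. Reading the
meridional and order-1 spacings off a spectrum therefore gives
`N = P/Δz` directly.

`best_rational_repeat` scans every denominator `t = 1..max_turns`
(default 20), reduces `round(N·t)/t` to lowest terms and keeps the
fraction minimising `|u/t − N|`, ties going to the smaller `t` — the
lowest-index order-1 line is the one read off a real spectrum. For the
wide-pilus value N = 3.89 this yields (35, 9): the helix repeats after
nine turns.

Twist is stored unsigned with a separate handedness flag defaulting to
right-handed. This is a convention, not a result: amplitude spectra are
blind to hand (a test asserts the mirror identity exactly), so nothing in
the pipeline can or does determine it.

Comparisons against published tables use the tables' printed precision
(rise 2 dp, twist 1 dp, subunits/turn 2 dp); all internal arithmetic is
full double precision, with rounding applied only at the reporting edge.

## Filament building

`build_filament` applies the screw operation (rotate `i·Δφ` about z,
translate `i·Δz` along z) to a rigid subunit for `i = 0..n−1`. Subunit 0
is untransformed; chain IDs run A, B, C, … in subunit order. PDB I/O goes
through gemmi; coordinates are Cartesian Å with the helical axis on z, and
no crystallographic records are emitted. The 62-chain PDB ID space bounds
the writable filament length.

Charge classes are derived from residue and atom names at read time:
Asp OD1/OD2 and Glu OE1/OE2 are acidic; Lys NZ and Arg NE/NH1/NH2 basic;
the backbone N of the first residue is the (charged) N-terminal amine and
the O/OXT of the last residue the C-terminal carboxylate. Histidine is
treated as neutral.

## Projection, power spectra and symmetry scoring

Atoms are rendered as unit-integral 2D Gaussians (σ = 1.5 Å, pixel 1.0 Å
by default — enough to resolve a ~9 Å meridional while keeping 512-px
boxes) summed along the viewing axis, filament axis vertical. Spectra use
a raised-cosine (10% taper) window to suppress box-edge ringing and a
unitary FFT so total spectral energy equals windowed image energy.

Layer-line detection takes the per-row maximum over columns for positive
axial frequencies, picks peaks with prominence ≥ 10% of the profile
maximum, and refines each peak position by quadratic interpolation of the
log profile (sub-sample accuracy; the residual error is bounded by one
Fourier sample, 1/(box length)). A line is flagged meridional when its
peak sits within 2 columns of zero radial frequency.

The pitch estimate is the spacing of the **strongest** off-meridional
line, not the largest-spacing one: when the exact repeat is long, weak
high-order Bessel lines can appear at spacings beyond the pitch (for the
narrow-form parameters, the l = 8 line of the (47, 11) repeat lies near
66 Å), while the order-1 line dominates.

Candidate symmetries are scored as in simulated-versus-experimental
transform comparison: build a filament at the candidate (pitch, N),
project it with the observed geometry, and correlate `log(1+amplitude)`
against the observed spectrum over an annulus excluding the equator row
and radial frequencies below 1/diameter (where the equatorial envelope
dominates every candidate equally). `recover_symmetry` averages the power
spectra of the input images, estimates the pitch (or takes a hint, as when
the pitch is known from 2D class averages), enumerates an N grid at that
pitch (default step 0.01) and ranks candidates by score. The procedure is
deterministic given its inputs.

## Contact and salt-bridge analysis

Two subunits are *physical interaction partners* when ≥ 1 heavy-atom pair
lies within 4.5 Å; a *salt bridge* is an acidic–basic group pair within
4.0 Å. Both cutoffs are standard structural-biology conventions — the
published partner counts (6 per direction for the wide form, 7 for the
narrow) were stated without explicit criteria, and counts can shift at
other values, so every output records the cutoff used. The production
search uses a k-d tree; an all-pairs brute-force oracle is kept in the
package and the test suite asserts exact agreement on every fixture.

Intermolecular bridges are reported modulo the helical symmetry: one
representative per (acidic residue, basic residue, subunit offset) with
the closest atom-pair distance. `nearest_acidic_to_nterm` reports, per
subunit, the closest acidic group to the N-terminal amine nitrogen and
whether it is intramolecular — the distance is always reported and the
salt-bridge label applied only by the cutoff rule, since "nearest" and
"bridging" are distinct claims. Formal charge sums −1 per Asp/Glu, +1 per
Lys/Arg, 0 for His, with charged termini contributing a cancelling ±1.

## Curvature of traced filaments

Traces (ordered 2D points, µm) are deduplicated, resampled at uniform arc
length (interval = median input spacing), and smoothed with cubic
smoothing splines in each coordinate (residual budget `s = smoothing · n`,
default 1e-4 µm² per point — sized for a few nm of digitisation noise).
Curvature is `κ = |x′y″ − y′x″| / (x′² + y′²)^{3/2}` at the interior
samples; the two samples at each open end are excluded, where spline
derivatives are least reliable. A population is classified by the fraction
of traces whose per-trace summary exceeds a threshold (default 2 µm⁻¹).
The summary statistic is configurable (mean | median | max); mean is the
default because it is exact for the constant-curvature arcs used as
synthetic truth, and because the statistic used for the published 40%/13%
split is not specified — those percentages are therefore *emulated* by the
generator, not re-derived from data.

## Synthetic data: what it does and does not emulate

- **Toy subunit** (`make_toy_subunit`): a seeded, elongated, internally
  asymmetric point cloud reaching exactly the stated maximal radius (35 Å
  for a 70 Å-wide filament, 22.5 Å for a 45 Å one), with a compact "core"
  knot near the axis whose z-coherence across subunits produces the
  meridional reflection — the role the tightly packed N-terminal helix
  bundle plays in a real pilus. No secondary structure, glycans, B-factors
  or scattering contrast.
- **Charged probes**: acidic/basic atom pairs placed on dedicated radial
  rings outside the body so that, after symmetry expansion, exactly the
  requested bridge (offset, distance) exists; verified internally.
- **Contact fixtures** (`make_contact_fixture`): per requested offset k, a
  two-atom "lane" engineered so subunit i touches subunit i±k at 3.0 Å and
  nothing else approaches within the 4.5 Å cutoff; brute-force verified at
  generation time, raising on infeasible geometry (e.g. rise below contact
  range).
- **Images** (`make_filament_image`): noiseless projection plus seeded
  Gaussian noise scaled to the clean image's standard deviation, so
  SNR = 1/noise_sigma. No CTF, detector statistics or out-of-plane tilt.
- **Trace populations** (`make_trace_population`): constant-curvature arcs
  with exactly `round(n·fraction_high)` curvatures drawn above the
  threshold (2.5–6 µm⁻¹) and the rest below (0.2–1.5 µm⁻¹), lengths
  1–3 µm, optional point jitter. Real pili bend with varying local
  curvature; constant-curvature arcs are the cleanest truth for testing
  the estimator, not a physical model of filament mechanics.

Every generator is a pure function of its parameter record; regeneration
is bit-identical, and each returns a serialisable ground-truth sidecar.

Passing the synthetic end-to-end checks shows the *algorithms* are
correct under these conditions; it does not validate performance on real
micrographs (CTF, structured noise, flexible filaments) or reproduce
measurements that require the deposited experimental models.

## Problem sizes and numerical choices

End-to-end symmetry recovery runs on two 512² images per form (48 or 40
subunits, SNR 5), with grid steps of 0.01 subunits/turn over 3.5–4.5
(wide) and 4.0–4.5 (narrow) — a desk-scale analogue of classifying tens of
thousands of segments. Degenerate inputs fail loudly: empty image lists,
sub-3-point traces, non-coprime repeats, equator spacing requests and
out-of-range centre subunits all raise with explicit messages. Scoring a
candidate whose filament would overflow the box shortens the filament to
fit rather than failing, so long-pitch candidates remain comparable.

## Known limitations

- Handedness is a convention throughout; ± twist cannot be distinguished.
- Layer-line indexing assumes a single filament, axis vertical, roughly
  centred; no in-plane rotation search is performed.
- The contact analysis treats all heavy atoms equally; no
  buried-surface-area or continuum electrostatics.
- Curvature is 2D (projected); real filaments curve in 3D.
- The 6-vs-7 partner distinction on *experimental* models depends on the
  distance cutoff; here it is demonstrated on engineered fixtures whose
  truth is fixed by construction.
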