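# Methods

This note documents the models implemented in `hsp90kit`, the defaults
and their rationale, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Structures and trajectories

PDB files are parsed with Bio.PDB in strict mode; ATOM and HETATM
records are both retained, alternate locations are resolved to the
highest-occupancy conformer (first on ties, Biopython's default), and
atoms are re-sorted by serial number so the in-memory table follows file
order. Insertion codes are carried alongside the residue number and
participate in atom identity. A trajectory is a list of models over one
fixed atom set with strictly increasing frame times (ns); only
multi-model PDB is supported — synthetic frames are written in the same
format, so no binary trajectory reader is needed. Centre of mass uses
standard atomic weights keyed by element symbol; hydrogen-free
(crystal-style) selections are expected and fine. Rigid superposition is
the Kabsch least-squares problem, solved via
`scipy.spatial.transform.Rotation.align_vectors` after centroid removal;
the returned rotation is always proper.

## Conformational observables

*Ion pairs.* A pair is defined by two named atoms (by default the
field's reference atoms: Glu Cδ, Asp Cγ, Arg Cζ, Lys/methyl-Lys Nζ). The
per-frame Euclidean distance feeds the open/closed classifier: closed is
strictly *r* < threshold with a 5 Å default, so a frame exactly at the
threshold counts as open (the convention "closed: r < 5 Å" is taken
literally). Transitions are state changes between consecutive frames;
the occurrence histogram uses 0.25 Å bins and sums to 100 %.

*Salt bridges.* A bridge between two atom groups is an acidic/basic
residue pair (one residue from each group) whose minimum charged
heavy-atom distance is under the cutoff; each residue pair counts once.
Charged atoms: Asp OD1/OD2, Glu OE1/OE2, Lys NZ, Arg NH1/NH2/NE;
histidine (ND1/NE2) is available but off by default, and mono-methyl
lysine (MLZ) is treated as lysine-equivalent since it retains the charge
on NZ. The default cutoff is 4.0 Å between charged heavy atoms — a
common literature convention, configurable because no single criterion
is canonical. The default yeast Hsp82 domain map (NTD 1–216, linker
217–261, M 262–526, CTD 527–709) ships as editable configuration, not as
asserted truth.

*Helix pairs and RMSD.* Helix-pair distances are centre-of-mass
distances between two residue-range selections per frame; the helix
ranges are configuration inputs. Backbone RMSD superposes each frame
onto a reference frame before computing the RMSD; the default selection
is the full backbone (N, CA, C, O), with a Cα-only option, since the
superposition convention is not uniquely determined by common practice.

## Dimer stoichiometry

With per-protomer modification probability *p* and independent random
assortment of protomers into dimers, the dimer pool is binomial:
(1−*p*)², 2*p*(1−*p*), *p*². At *p* = 0.3 this gives 0.49/0.42/0.09 and
a 51 % total modified-species fraction. The independence assumption is
exactly what the arithmetic of those published fractions implies; it is
exposed as a documented assumption rather than re-derived from data.
Whether hetero- and doubly-modified dimers truly share one kinetic time
constant is not resolvable from this model — the weighted kinetic fit
lumps them at combined weight 1 − (1−*p*)², as the assay analysis did.

## Kinetic fits

All nonlinear least squares go through lmfit (Levenberg–Marquardt,
relative tolerances of 1e-10 or tighter on parameters and cost). Initialisation of
exponential fits is deterministic: offset from the mean of the last
decile of points, amplitude from the first point minus the offset, time
constant from the first crossing of (1 − 1/e) of the span. Rising
(closing) traces are handled by a negative amplitude — the model form is
sign-agnostic, so no separate rising model exists. Degenerate inputs are
flagged rather than rejected: a constant trace yields a negligible
amplitude and an `time_constant_unidentifiable` flag.

The species-weighted bi-exponential holds the fast time constant fixed
(the unmodified protein's value) and the weights fixed (from the
binomial species distribution), freeing only the shared amplitude, the
slow time constant and the offset. A zero modified-species weight is
rejected with a pointer to the mono-exponential fit, since the second
component would be absent and t₂ meaningless. When the data were
generated with t₂ = t₁ the model collapses to a single exponential; the
fitted amplitude is still recovered and t₂'s confidence interval spans
t₁.

A wording note: the chase protocol describes a "tenfold excess (4 µM)"
of unlabelled protein over 200 nM labelled protein, which is arithmetically
a 20-fold molar excess. This inconsistency is recorded here for
completeness; it does not enter any computation.

## SEC dimerization

The elution-time isotherm treats the injected (total) monomer
concentration as the independent variable, as the apparent-K_D framing
requires; no on-column concentration profile or free-monomer speciation
is modelled. Initialisation takes ET_mono from the lowest concentration,
ET_dimer from the highest, and K_D(app) from the geometric mean of the
concentration range. The fitted curve is monotone between the two limits
by construction.

The dilution factor is implemented as observed peak width divided by the
theoretical injection-plug width (volume/flow), giving a factor ≥ 1 when
peaks broaden; the published description words the quotient the other
way around, which is dimensionally inconsistent with on-column dilution
(broadening to 1.6 min from a 0.4 min plug must dilute, factor 4). The
orientation is documented here and the arithmetic is exposed as a plain
function, so either convention can be applied deliberately.

## Sedimentation velocity dc/dt

Consecutive scan pairs on a common radial grid are differenced; each
radius maps to s\* = ln(r/r_meniscus)/(ω²·t̄) with t̄ the pair's mean
time, and per-pair profiles are averaged on a 200-point linearly
interpolated common s\* grid. The derivative is taken as −Δc/Δt so a
depletion boundary appears as a positive peak (the standard
presentation). Per-scan baselines are estimated from the outermost 5 %
of radii and subtracted before differencing. The meniscus is a required
input: auto-detection is fragile and the synthetic scans know it
exactly. Radial dilution is not corrected — the data of interest are
fluorescence-detected and used comparatively; this is a documented
limitation, as is the absence of any Lamm-equation (c(s)-style)
modelling.

Peaks are fitted as a sum of Gaussians initialised at the most prominent
local maxima. The dominant peak is the largest-amplitude one; a
complex-formation shift is the difference of dominant-peak centers
(mixture − free), and indistinguishable top amplitudes raise an
ambiguity error instead of guessing.

Two systematic effects deserve note. First, diffusive spreading of the
boundary contributes its own term to dc/dt and biases the apparent peak
outward; the bias shrinks as ln(r_b/r_m) grows, which is why the
synthetic scans default to late times (9000–9600 s at 42,000 rpm), as in
practice, where the residual bias for a 3 S / ~100 kDa-like species is
about 3 %. Second, the finite scan interval adds a discretization error
scaling as Δt²; at Δt ≤ 240 s it is orders of magnitude below the
diffusion bias, so the test isolating it uses a constant-shape boundary
and measures convergence toward the small-Δt limit.

## ATPase rates

Turnover assumes 1:1 coupling of ATP hydrolysed to NADH oxidised (the
regenerating-system stoichiometry) and uses ε(NADH, 340 nm) =
6220 M⁻¹cm⁻¹ with a 1 cm path by default, both configurable since assay
hardware varies. Rates are normalised per protomer concentration as
pipetted (3 µM yeast, 10 µM human are the typical conditions); per-dimer
reporting is available behind a flag because the normalisation
convention is genuinely ambiguous in common usage. The
Hsp90-independent background slope, measured in a window after inhibitor
(radicicol) addition, is subtracted from the assay-window slope; a
positive corrected slope is floored at zero with a warning. The
coupled-enzyme lag phase is not modelled — windows should start after
it.

## Synthetic data: what it emulates, what it does not

Every generator evaluates the exact forward model of its analysis stage
plus additive i.i.d. Gaussian noise, returns its ground truth, and is a
pure function of (parameters, seed). Defaults are the study conditions
of the assays emulated: two-state ion-pair means 3.5 Å (closed) and
8.0 Å (open) with 0.4 Å jitter around the 5 Å threshold; Eq.-style
weighted closing traces with weights 0.49/0.51 (p = 0.3); SEC
concentrations 16 nM–2 µM over 12 log-spaced points with K_D(app)
truth 180 nM, observed peak width 1.6 min against the 0.4 min plug
(dilution factor 4, corrected K_D 45 nM, inside the reported
30–60 nM yeast range); boundaries at 3 S (free species) and 8 S
(complex) at 42,000 rpm with meniscus at 6.0 cm and a diffusion-width
coefficient of 9×10⁻⁴ cm·s^(−1/2) (D ≈ 4×10⁻⁷ cm²/s, typical for a
~100 kDa protein); NADH curves at 3 µM enzyme with an inhibitor phase
after 30 min. Where the underlying reports are silent (noise magnitudes,
scan times, meniscus position), values are declared once here and in the
generator defaults.

The generators deliberately do not emulate: force-field dynamics or any
realistic MD energetics (the toy trajectories place designated atoms at
prescribed distances and keep everything else rigid), full
Lamm-equation transport (the boundary is an error function with
prescribed drift and spreading), coupled-enzyme lag kinetics,
photophysics, or instrument drift. Passing tests therefore demonstrate
the correctness and statistical calibration of the *analysis* chain —
they cannot certify behaviour on real detector artefacts, non-Gaussian
noise, or model misspecification.

## Statistical conventions in tests

Parameter-recovery suites run 100 seeded replicates and assert that the
ensemble-mean estimate and the median per-replicate error stay within
the stated tolerance; at a few-percent noise a per-replicate guarantee
would be a claim about noise tails that the generating conditions do not
control (for the SEC isotherm at 0.5 % elution-time noise the single-fit
scatter of K_D(app) is ~18 %, while the ensemble mean is within 4 %).
Occupancy checks compare against the analytic stationary distribution of
the two-state chain, with the standard error inflated by the chain's
autocorrelation (var = π(1−π)(2−r)/(n·r), r the sum of switching
probabilities).

## Known limitations

- No mmCIF or binary trajectory formats; no bond inference or topology.
- Salt-bridge and ion-pair criteria are conventions, exposed as
  configuration; results depend on them.
- The dc/dt peak center carries the diffusion bias discussed above;
  comparative shifts (free vs. complex) largely cancel it.
- Eq.-2-style fits return an apparent K_D of the injected-concentration
  hyperbola; the dilution correction is a scalar adjustment, not a
  transport model.
- One structural check (the ~70 Å switch-point-to-ATP distance in the
  closed dimer) requires the 2CG9 PDB entry, which the repository cannot
  ship; the corresponding test fails with a clear message when the file
  is absent.
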