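# Methods

## Optical model

The SLM is modeled as a rectangular lattice of `n_rows × n_cols` phase-only
pixels of pitch p, centred on the optical axis of a system with equivalent
focal length f illuminated at wavelength λ. Pixel (i, j) sits at physical
coordinates ((j − (n_cols−1)/2)·p, (i − (n_rows−1)/2)·p). Under the
Fourier-optics thin-element approximation a target focus at image-space
coordinates (x, y, z) corresponds to the pupil phase

    ϕ(x′, y′) = (π z / λ f²)(x′² + y′²) + (2π / λ f)(x x′ + y y′),

a pure combination of tip, tilt and defocus. No pixel fill-factor,
dispersion, aberration or zero-order effects are modeled; blocking the
undiffracted zero order is a hardware concern.

The continuous pupil integral defining the complex amplitude delivered to
spot n is discretized as a **mean over the active pixels**,

    cₙ = (1/M) Σₘ exp(i(ϕ_cgh,m − ϕₙ,m)),

so |cₙ| ≤ 1 independently of pixel count, with equality iff the phase
difference is constant. Spot intensity is Iₙ = |cₙ|², and a perfect
single-spot hologram scores exactly 1. With this normalization total pupil
throughput is 1 and efficiency is e = Σₙ Iₙ. Intensity is the single
on-axis focal value per target, not a camera-window sum: for distinct,
well-separated spots the single-point fields are nearly orthogonal and
e ≤ 1 holds to numerical precision, but coincident or near-coincident
targets make the fields collinear and e can then exceed 1. The benchmark
patterns keep spots separated; duplicate-spot inputs are legal but their
efficiency should not be read as a physical fraction.

Units: the public file/CLI boundary uses nm (wavelength), mm (focal
length) and µm (pixel pitch, spot coordinates); everything is converted to
SI metres once on input. Internal phases are kept unwrapped; wrapping into
[0, 2π) happens only at mask export.

An optional `aperture: circular` config flag restricts the active pixel
set to the inscribed ellipse of the panel; all sums (and the M of the cost
model) then run over active pixels only. Default is the full rectangle,
matching a beam that uniformly overfills the active area.

## Algorithms

All five variants synthesize the mask as the phase of the weighted
superposition ϕ_cgh = arg Σₙ ωₙ e^{i(ϕₙ+θₙ)}. The sign convention is the
self-consistent pair {superpose with +i, project with e^{i(ϕ_cgh−ϕₙ)}}: in
the single-spot limit the projection recovers θ exactly, making N = 1 a
fixed point with e = u = 1.

* **rs** — θₙ ~ U[0, 2π), uniform weights, one superposition.
* **gs** — iteration 1 *is* the RS initialization; each subsequent
  iteration sets θₙ ← arg cₙ from the current mask, then superposes.
  `gs` with K = 1 is therefore bit-identical to `rs`.
* **wgs** — as gs, but before each superposition the weights are updated
  with the **modulus ratio** ωₙ ← ωₙ·⟨|c|⟩/|cₙ| (then renormalized; the
  superposition phase is scale-invariant). The update drives all |cₙ| to
  the common mean, i.e. the intensities to equality. Using the squared
  modulus here instead over-corrects — the spot amplitude responds roughly
  linearly to its weight, so an intensity-ratio step has log-gain ≈ 2 and
  oscillates into divergence; the amplitude ratio is the stable form and
  the one that reproduces the expected WGS behavior.
* **cs-gs** — one pixel subset of max(1, round(cM)) distinct pixels is
  drawn uniformly at the start of the run (c = 1 yields all pixels in
  canonical order); iterations 1..K−1 run GS with all means taken over the
  subset (dividing by |subset|, which keeps the θ updates unbiased
  estimates of the full-pupil ones); the K-th iteration computes θ from
  the last subset state and performs one full-pupil superposition, with no
  further full-pupil θ refinement. `resample_subset=True` redraws the
  subset before every compressed superposition instead.
* **cs-wgs** (K ≥ 2) — K−1 compressed GS iterations, a full-pupil
  superposition of that state, then exactly one full-pupil WGS iteration
  (θ and ω both update from full-pupil amplitudes). At c = 1 this equals
  gs(K−1) followed by one weighted step.

Determinism: each run owns one seeded NumPy generator that draws the θ
initialization first and the pixel subset(s) second; every variant is a
pure function of (grid, spots, params).

Degenerate inputs: a superposed field that cancels to exactly zero at a
pixel takes phase 0 (the `arg 0 = 0` convention); if a spot's intensity
falls below ε = 1e−12 during a weight update, its ratio is clamped to at
most 10× per iteration so a dark spot cannot blow up the weights.

Per-spot **target weights** (optional) request relative spot intensities:
initial amplitude weights are ∝ √target, and the WGS ratio is computed on
moduli normalized by √target, so the update drives Iₙ toward the requested
proportions. Uniform targets reduce exactly to the equations above.

## Cost model and instrumentation

`op_count` accumulates N·P for every synthesis (superposition) pass over P
pixels. θ and intensity updates reuse the per-spot unit fields of the pass
that produced the current mask and add nothing — in an implementation that
streams the fields this is exactly the per-pass caching any practical code
would do. The counter therefore reproduces the closed forms

    RS:      N·M
    GS/WGS:  K·N·M
    CS-GS:   (K−1)·N·cM + N·M
    CS-WGS:  (K−1)·N·cM + 2·N·M

exactly (diagnostic trace evaluations are not counted). The CS-WGS final
stage costs two full passes — the full superposition of the compressed
state plus the weighted iteration — which is why it roughly doubles CS-GS
when c·K ≪ 1.

Implementation note: the N per-spot unit fields e^{iϕₙ} over the active
pixels are cached as an N×M complex array when that fits a 2 GiB cap,
turning every pass into a BLAS mat-vec; above the cap the same math runs
as a streaming per-spot loop with O(M) memory. The dense array is only
ever used row-wise — no linear system is formed or solved.

## Benchmark protocol

Quality metrics: e = Σ Iₙ and u = 1 − (I_max − I_min)/(I_max + I_min).
u is scale-invariant; e is invariant under global phase shifts of the
mask. (The alternative uniformity estimator based on the standard
deviation of peak intensities, used for camera data, is *not* implemented;
the metrics here operate on simulated intensities only.)

Replicate statistics rerun the solver with seeds base_seed + r,
r = 0..R−1 (default R = 10), reporting mean and standard deviation per
condition. Default compression sweep levels: 1, 1/2, …, 1/256. Convergence
traces record full-pupil (e, u) after every iteration; for compressed
iterations the full-pupil superposition of the current (θ, ω) state is
evaluated as an uncounted diagnostic, which is what makes the single final
weighted iteration of CS-WGS visible as a jump in the last trace entry.

Standard conditions (chosen once; the benchmark generators scale patterns
to the pupil's addressable field x_max = λf/2p laterally and
z_max = λf²/4·r_max·p axially — the half-Nyquist defocus at the pupil-edge
radius r_max):

* optics: λ = 800 nm, f = 18 mm, pitch 9.2 µm (a Ti:Sapphire two-photon
  system with a 20×/1.0 NA objective behind a 2× relay);
* pupil: 256×256 pixels for the cloud/grid benchmarks, 512×512 for the
  letter-pattern protocol — sizes that keep the full replicate protocol in
  minutes on one core while leaving cM ≫ N at c = 1/32;
* patterns: 100-spot random 3D cloud spanning 0.6·x_max laterally and
  0.5·z_max axially (seed 7); 10×10 in-plane grid at 0.12·x_max spacing
  (the uniformity worst case — the lattice's regular geometry maximizes
  crosstalk between spot fields); 25-point "TUD" block-letter pattern
  spanning 1.4·x_max total width;
* solvers: K = 50 iterations (K = 100 for the letter protocol),
  c = 1/32 (0.05 for the letter protocol), R = 10 replicates (5 for the
  letter protocol).

The glyph sampler places points at equal arc-length steps along fixed
block-letter polylines; it is a deterministic source of spread-out planar
coordinates, not typography.

## What the synthetic benchmarks do and do not show

All inputs are synthetic and the forward model is the same discrete
operator the solvers optimize, so the benchmarks measure algorithmic
quality (projection efficiency and intensity balance of the ideal scalar
field), not experimental performance: SLM phase quantization (masks are
exported at 8–16 bit), pixel cross-talk, aberrations, laser-power and
sample effects are outside the model. Passing tests show the solvers
reproduce the expected ordering (RS < GS in efficiency, GS < WGS in
uniformity, CS variants tracking their full-pupil counterparts at
c ≥ 1/32) under ideal-optics conditions.

## Numerical choices

* float64 phases, complex128 fields throughout;
* subset field matrices are forced C-contiguous so BLAS takes the same
  code path as the full-pupil ones and c = 1 reduces bit-identically;
* mask export rounds wrap(ϕ)/2π·L to the nearest integer after wrapping,
  so a phase just below 2π maps to L, never to 0; level L and level 0
  represent the same physical phase, which real SLM calibrations expect;
* grey level L is configurable (default 255) because hardware 2π
  calibrations commonly sit below the full bit depth.

## Known limitations

* Spot intensity is a single-point field sample; efficiency of
  (near-)coincident spots exceeds 1 and the metrics lose their physical
  reading there.
* The K-th CS-GS iteration trusts the subset-estimated θ; at extreme
  compression (cM approaching N, where a warning is emitted) those
  estimates are noisy and quality degrades smoothly toward RS.
* WGS equalizes the on-axis intensities of the model field, not measured
  camera peaks; experimental uniformity additionally depends on system
  aberrations.
* Fixed iteration count only — no adaptive stopping rule.
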