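# Methods

This note documents the models implemented in `mwbrain`, the parameter
choices that matter, what the synthetic data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Acquisition model

The system is a monostatic frequency-sweep radar: one directional
ultra-wideband antenna measures the complex reflection coefficient
S_n(f_m) at N equiangular positions around the head, M = 284 uniform
frequency samples over 0.75–2.55 GHz (fractional bandwidth 109%). The
default scan keeps a constant 15 mm standoff from the skin
(`make_offset_scan`), which is what makes the air–skin echo nearly
identical across positions and hence cancellable; a parabolic profile
r(θ) = r₁ + (r₂ − r₁)(θ̃/π)² (θ̃ the angle wrapped to (−π, π], circle when
r₁ = r₂) is provided as an alternative equiangular trajectory. All
geometry lives in the 2-D plane of the scanned layer, in millimetres,
origin at the scan centre.

## Signal chain

1. **Range conversion.** Per position, an inverse DFT over the band:
   s_n(t_k) = (1/M) Σ_m S_n(f_m) e^{+j2πf_m t_k} on the grid
   t_k = k/(K·Δf), with K = 4M (4× zero padding, for smooth sub-sample
   peak interpolation). The transform is exactly invertible on the
   in-band bins; an optional Hann window is off by default.
2. **Clutter removal.** Adjacent average subtraction on the ring: each
   position's signal minus the mean of its two neighbours, each neighbour
   first shifted by the integer lag (bounded to ±5% of the record) that
   maximises its cross-correlation with the centre signal (Woody
   average). Sub-sample alignment is deliberately omitted: integer lags
   keep the operation exactly reproducible and linear per lag choice.
3. **Gain normalisation.** Each scattered signal is scaled to unit peak
   absolute amplitude, compensating the antenna's gain variation over the
   wide band; all-zero positions are left untouched and flagged.

The excitation pulse is a Gaussian-modulated sinusoid with carrier
1.6 GHz and stated width τ = 1.7 ns. The width is interpreted as the
total pulse duration with envelope standard deviation σ = τ/7, chosen so
that the pulse's −10 dB spectral extent spans the 0.75–2.55 GHz operating
band — the stated design intent of the excitation. Noise is complex
white Gaussian, scaled to a dataset-wide SNR (one SNR per experiment, not
per position), seeded and reproducible.

## Effective head permittivity

A signal entering the skin sees, in order, thin high-permittivity skin,
thick low-permittivity fat and skull, then high-permittivity CSF and
brain. The single dielectric constant that reproduces the accumulated
delay over penetration depth d is therefore small near the entry and
saturates deep inside. The model is

    ε_eff(d) = ε_max (1 − c₁ e^{−c₂ d/a}),

with a the entry-point-to-centre distance, clamped beyond d = 2a (no ray
penetrates past the far boundary). The exponential-saturation form is the
simplest three-parameter law satisfying the qualitative constraints
(small at d = 0⁺, monotone, bounded by ε_max); the band-wide reference
constants for a realistic adult head are ε_max = 46.8, c₁ = 0.75,
c₂ = 6.4. Calibration reverses the construction: ε_eff = (c·Δt/d)² from
differential arrival times at probes placed along inward rays from
several entry angles, the per-angle curves are normalised by their own a,
averaged on the common normalised-depth axis, and fitted by unweighted
nonlinear least squares from three fixed starting points (deterministic,
seed-free). For the synthetic phantom the calibration probes start at
15 mm depth — inside the brain, past the ~12 mm skin/fat/skull/CSF shell,
where the saturating form actually holds (the shell itself makes the
first few millimetres non-monotone). The legacy algorithms' constant
head permittivity is available as `kind="fixed"`.

## Travel times and imaging

The path to a cell is decomposed as free space to an entry vertex on the
discrete head boundary plus a single straight in-head segment whose
delay uses ε_eff evaluated at the segment length (endpoint evaluation,
no intra-head refraction). Following Fermat's principle the entry vertex
minimises the total electrical path; the search is exhaustive over the
candidate vertices, so the result is deterministic at a given boundary
resolution (default 180–360 vertices).

Candidates are restricted twice. First to the line-of-sight arc between
the antenna's two tangent points (the vertices a direct wave can reach).
Second — and this matters quantitatively — to vertices within ±45° of
boresight. The imaged medium is ~6× slower than air, so an unrestricted
minimisation happily routes deep cells through glancing entries near the
tangent points: a long, fast air leg plus a shortened interior segment
can undercut the direct route by ~0.5 ns, which exceeds the pulse width
and destroys the coherent summation. Physically those glancing entries
receive negligible energy from the directional antenna (80°/100°
half-power beamwidths in the two principal planes), so excluding them is
a statement about illumination, not a tuning knob; ±45° sits inside the
stated beamwidths. Setting `beam_halfwidth_deg=None` recovers the pure
tangent-arc search. For the same reason, restricting to the visible arc
is not merely a computational shortcut: shadowed far-side vertices can
(unphysically) undercut the visible minimum, so the restriction is part
of the model.

DAS sums the complex scattered signals at the tabulated round-trip
delays (linear interpolation between time samples; delays beyond the
record contribute zero) and takes the absolute value **after** the sum —
no envelope detection, preserving the cancellation of incoherent
contributions. The image is max-normalised over the in-head cells; the
pre-normalisation maximum is kept, since its absolute scale separates
strong coherent targets (raw maxima ~10–20 in the synthetic study) from
target-free heads (~2–3).

Grids: the native resolution is 0.5 mm cells over the 300×300 mm area.
The study reconstructions in the tests and the acceptance script use
1 mm cells (the bleed is 20 mm; 1 mm sampling resolves δ comfortably),
and the sub-millimetre impulse-consistency check uses the 0.5 mm grid on
a 60×60 mm homogeneous disc. These sizes are the package's default study
conditions, not hard limits.

## Metrics

With Ω_head the in-head cells and Ω_target the axis-aligned rectangle of
the inserted bleed: γ = max over Ω_target / max over Ω_head∖Ω_target
(γ > 1 ⇔ the global maximum is inside the true target), Q = mean over
Ω_target / mean over the rest (no guard band around the target), and
δ = Euclidean distance from the true centre to the argmax cell centre
(cell-centre arithmetic, no sub-cell peak interpolation; ties break to
the lowest (p, q) index). γ and Q are invariant to global intensity
scaling, so they agree on raw and normalised images; a target region
holding the sole nonzero cell yields γ = +inf as a sentinel. The
accuracy map re-runs simulate → reconstruct → metrics over a systematic
sweep of target centres, reusing the travel-time table, and differential
maps between two models are element-wise differences over the same
positions.

## The synthetic phantom and forward model

The phantom is a 2-D elliptic head section, semi-axes 90 × 110 mm,
concentric skin (2 mm), fat (1 mm), skull (7 mm) and CSF (2 mm) layers, a
30 mm gray-matter shell and a white-matter core, with an optional
rectangular blood target (default 20 × 20 mm, matching the inserted-bleed
scenario; 15 × 20 mm mirrors the smaller measured target). Band-edge
permittivities: skin 50→44, CSF 69→66.2, dura 44→41.9 and muscle
55→52.6 across 0.75–2.55 GHz; fat 5.5→5.2, skull 12.4→11.3, gray
52.3→48.4, white 38.6→35.5 and blood 61.1→57.2 are package defaults in
the spirit of the standard tissue databases, as are all conductivities.
Values are interpolated linearly in frequency within the band.

The forward model is Born-type single scattering along straight rays:
per position the response is Σ_e A_e P(f) e^{−j2πf·2τ_e} with P(f) the
pulse spectrum. The air–skin echo carries the Fresnel amplitude
(1−√ε_skin)/(1+√ε_skin) with 1/d amplitude decay (cylindrical spreading
in 2-D; exponent configurable) and a per-position skin-thickness jitter
(seeded Gaussian, default off, 0.3 mm in the healthy-head study) that
perturbs its optical delay. The target echo sits at the straight-ray
delay through the true layered tissues with amplitude proportional to
the blood/background Fresnel contrast — so gray-matter backgrounds give
weaker echoes than white-matter ones, consistent with the smaller
blood/gray wave-impedance contrast (9.2–5.2% across the band from the
band-edge impedance magnitudes). Optional seeded point clutter is
available. Datasets are bit-reproducible under a fixed seed, and the
target echo is exactly additive on top of the target-free response.

What the generator does **not** emulate, and what passing tests
therefore do not show about real data: conductive penetration loss (so
the real system's decrease of Q with target depth does not appear in the
synthetic data), dispersion within an echo beyond the pulse spectrum,
multiple scattering and mutual shadowing, antenna ringing and cable
artifacts, and 3-D out-of-plane propagation. The forward propagation
(straight rays through true layers) intentionally differs from the
imaging model (Fermat two-segment paths with ε_eff), which is what makes
the proposed-vs-fixed model comparisons meaningful rather than circular.

## Safety calculators

Incident power density uses spherical spreading, S = P_tx·G/(4πr²) with
G a **linear** gain factor: 1 mW, G = 3.5 and r = 15 mm give
1.24 W/m² = 0.124 mW/cm², an order of magnitude under the 1 mW/cm²
limit. Direct computation confirms the linear reading: treating 3.5 as
dBi (factor 2.24) would give 0.79 W/m² instead; `dbi_to_linear` lets both
readings be evaluated explicitly.

Skin heating uses the classical erfc solution for a semi-infinite slab
absorbing the transmitted power fraction exponentially over the power
penetration depth L:

    ΔT(t) = (S·T_tr·L/k) · [ 2√(x/π) + e^x erfc(√x) − 1 ],  x = t/τ_th,

with T_tr = 1 − |Γ|² the surface transmission (Γ from the complex skin
permittivity at the operating frequency), k = 0.37 W/m/K the thermal
conductivity, thermal inertia kρc with ρ = 1109 kg/m³ and
c = 3390 J/kg/K (standard skin values, configurable), and thermal time
constant τ_th = L²ρc/k — the time for the thermal wave to diffuse one
skin depth. L comes from the attenuation constant of the lossy skin
(ε′ 50→44, σ 0.9→1.8 S/m across the band). The short-time behaviour of
this solution is linear in t (adiabatic volumetric heating,
ΔT ≈ S·T_tr·t/(ρcL)), verified against its series expansion; ΔT is
strictly increasing, linear in transmit power, and larger at higher
frequencies at matched power density because the shrinking skin depth
concentrates the loss at the surface. A frequency sweep exposes each
frequency only for its dwell fraction, so the effective rise is the
duty-cycle-weighted sum of per-frequency rises; an hour-long uniform
sweep at 1 mW stays below 0.02 °C.

## Known limitations

- The effective-permittivity model compresses a direction-dependent
  quantity to a function of depth alone; residual per-antenna delay
  errors of ~0.05–0.1 ns remain on the synthetic phantom and set the
  ~1–3 mm localization floor away from the head centre.
- The discrete entry-vertex search quantises the air path at the
  boundary resolution; accuracy is controlled by the vertex count, not
  by a continuous optimiser (a determinism trade-off).
- Woody alignment uses integer lags only and aligns on the dominant
  (skin) echo; with the skin echo fully cancelled and no jitter it
  aligns on whatever residual structure exists.
- Touchstone support covers one-port files (RI/MA/DB, any standard
  frequency unit) with a JSON manifest; multi-port and noise-parameter
  sections are out of scope.
- The safety model is analytic surface heating; it is not a SAR or
  bioheat (perfusion) computation.
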