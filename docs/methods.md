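# Methods

## The problem and the reconstruction

A 1H–13C HSQC acquired *without* decoupling shows every proton as a
doublet split by the one-bond coupling 1J(CH) (≈115–220 Hz): the two
components sit at δ(1H) ± J/2 and carry the full homonuclear multiplet
fine structure.  Broadband-decoupled HSQC collapses the doublet but, to
keep decoupler duty cycles safe, limits the acquisition time (typically
100 ms), throwing that fine structure away.  Virtual decoupling gets
both: from a clean in-phase / clean anti-phase (CLIP/CLAP) pair it
rebuilds a spectrum with one peak per 1H/13C pair at the true shift and
at the full digital resolution of the undecoupled acquisition.

The pipeline (`virtual_decouple`) is:

1. **Resolution destruction.** The CLAP is reprocessed with only
   `lowres_points` (default 1024) t2 points, collapsing each doublet
   component's multiplet into a single broad peak.  In the CLAP the two
   components have opposite sign, which is the recognition handle.
2. **Dual-sign peak picking.** Local 8-neighbourhood extrema above a
   threshold are picked twice, once per sign, and their direct-dimension
   position is refined by an intensity-weighted centroid.
3. **Row clustering and pairing.** Peaks sharing a 13C digital row are
   clustered.  A cluster of exactly one positive and one negative peak
   whose separation lies in [j_min, j_max] becomes a doublet pair; the
   pair midpoint is the proton shift and the separation the J estimate,
   *individually per pair*.
4. **Back-shift.** A window of half-width J/2 centred on the upfield
   component of the *full-resolution* CLIP row is shifted downfield by
   J/2 onto the doublet centre and added into the (zero-initialized) vd
   matrix.

Every stage is deterministic; identical inputs and configuration give a
bit-identical result.

## Signal model (simulator)

Each 1H–13C moiety is simulated in the weak-coupling (first-order)
limit as a t2 signal

    a · exp(−π·lw_H·t2) · Π_k cos(π·J_k·t2)^{n_k} · M(t2) · e^{iΩ_H t2}

with `M = cos(π·J_CH·t2)` (CLIP), `i·sin(π·J_CH·t2)` (CLAP) or 1
(decoupled, t2 capped at 100 ms by default), States-style hypercomplex
t1 modulation at Ω_C with Lorentzian decay, and optional Gaussian noise
added per time point under a single seed.  `alpha`/`beta` modes generate
the spin-state-selective subspectra; clip = alpha + beta and
clap = alpha − beta hold exactly at the FID level, so the IPAP identity
is inherited by any linear processing.

Phasing is ideal, so the downfield CLAP component comes out positive.
This is a simulator convention: the pairing algorithm only uses the
*opposite* signs, never which one is which, because the absolute sign of
real data depends on phasing.

**What the generator does not emulate:** strong coupling (second-order
multiplets), phase and baseline distortion, t1 noise, solvent signals,
13C satellites’ isotope shift (explicitly neglected), and the
phase-twist lineshape of real 2D J spectra (`simulate_jres` produces an
idealized tilted absorption spectrum for use as a comparison reference
only).  Passing tests therefore demonstrate the correctness of the
algorithmic chain on first-order spectra with ideal phase, not
robustness to instrumental artefacts.

## Processing choices

* **Frequency mapping.** Index 0 of every dimension is the downfield
  (left, highest-ppm) edge; ppm→index maps are linear in Hz.  An axis is
  stored as (sw_ppm, sfo_MHz, left-edge ppm, n_points); zero filling
  changes only n_points.
* **Windows.** `em` (exponential), `gm` (Lorentz-to-Gauss), `sine`
  (cosine bell) and `qsine` (squared cosine) are available.  The
  indirect dimension defaults to `qsine`, whose truncation sidelobes
  (≲2.5 %) stay below the detection floor; the plain cosine bell rings
  at ≈7 % and produced spurious duplicate detections on neighbouring
  rows.
* **Full-resolution CLIP processing** defaults to Lorentz-to-Gauss with
  lb = −1 Hz, gb = 0.1, matched to the ~1 Hz linewidth typical of
  small-molecule spectra.  The motivation is quantitative: multiplet
  lines are integrated between flanking minima, and the 1/Δν² tails of
  Lorentzian lines bias such integrals by ~5–10 % at 4–7 Hz line
  separations (closed-form arctan tail integrals), which would mask the
  1:2:1 and 10:1 patterns the method is meant to recover.  Gaussian
  lines of ≈1.5 Hz width have no tails at those distances.  gb = 0.1
  keeps the Gaussian decayed to < e⁻⁶ by the end of even a ~0.5 s FID
  (no truncation ringing).  Fully configurable via `VdConfig.clip_proc`.
* **First-point halving** before each FT removes the DC baseline offset.
* **Reduced-resolution CLAP.** Truncation to 1024 points is the
  structure-destroying step; a `qsine` taper over the kept points
  suppresses the sinc sidelobes of the hard cut (first lobe ≈21 %
  untapered), and 2 Hz of exponential broadening (a repository default —
  the choice is not dictated by the method) smooths further.  The
  truncated FID is zero filled 4× so the component centroid can be read
  off a finer grid; zero filling adds no J information, it only
  interpolates.  The centroid window (±2 digital points) is scaled by
  the zero-fill factor so its physical width is unchanged.
* **Hilbert fallback.** When only a processed real spectrum is
  available, complex rows are rebuilt by Hilbert transform and
  inverse-transformed before truncation.  The result carries the window
  of the original processing on top of the new one and is only valid for
  truncation to at most half the grid; it is flagged
  (`hilbert_reconstructed`) in the provenance metadata.

## Detection and pairing parameters

| parameter | default | meaning |
|---|---|---|
| `lowres_points` | 1024 | t2 points kept for the CLAP reprocessing |
| `lowres_zero_fill` | 4×1024 | digital grid of the low-res spectrum |
| `lowres_lb_hz` | 2 Hz | exponential broadening on the truncated FID |
| `threshold_factor` | 6 | peak threshold in units of the noise σ |
| `min_threshold_rel` | 0.05 | threshold floor, fraction of max intensity |
| `j_min`, `j_max` | 110, 220 Hz | plausible one-bond coupling range |
| `row_tolerance` | 0 | 13C rows merged into one cluster |
| `window_halfwidth_hz` | J/2 | extraction window around the upfield component |
| `subpoint_shift` | on | Fourier-interpolated fractional-point shift |

Noise σ is 1.4826 × the median absolute deviation of the matrix (or of
a user region) — robust against sparse peaks.  The relative floor
exists because for noiseless synthetic input 6σ of numerical baseline is
meaninglessly small; 5 % of the maximum keeps apodization sidelobes and
zero-fill scalloping out while still catching components 20× weaker
than the strongest signal.  With realistic noise the 6σ term governs.

Clustering uses the strict "same digital row" rule by default
(`row_tolerance = 0`), with an opt-in ±1 for lineshapes straddling a row
boundary.  Clusters with more than one peak per sign are resolved by
enumerating all perfect matchings between positive and negative members
(clusters are small; enumeration is capped at 6 per sign), discarding
matchings with any pair outside [j_min, j_max], and choosing the one
minimizing Σ| |I⁺| − |I⁻| | — the two components of one doublet carry
equal intensity.  Ties fall to the first enumeration order
(deterministic).  Anything unresolvable is reported as *ambiguous*, and
a manual pairing file (JSON, peak ids in detection order) can override
the automatic treatment — the scriptable replacement for an interactive
selection dialog.  Every picked peak ends up in exactly one of
pairs / ambiguous / rejected, with a reason.

## Back-shift numerics

The window spans [δ − J, δ] in Hz (half-width J/2 around the upfield
component), covering the full homonuclear multiplet while excluding the
downfield partner at δ + J/2.  The shift J/2 is computed in Hz and
applied on the full-resolution grid: rounded to an integer number of
points (`subpoint_shift = off`, worst-case placement error half a
point), or with its fractional part applied as a circular Fourier phase
ramp within the window (`on`, placement error limited by the J estimate
itself — measured ≈0.1 point at the 16384-point geometry).  Both
variants conserve the window integral (the Fourier shift leaves the DC
bin untouched).  Windows that would leave the axis are clipped with a
warning; overlapping shifted windows on one row are *summed* and
flagged, never averaged — summation matches spectral linearity and the
flag preserves auditability.  When upfield components of two pairs lie
within J/2 of each other, each extraction window necessarily carries a
copy of the neighbour's multiplet shifted by the wrong J/2; these ghosts
are inherent to the window-shift construction and are the reason the
overlap flag exists.

## Synthetic study conditions

The bundled fixture (`make_zebra_fixture`) emulates the trimethylamine
region (3.1–3.3 ppm ¹H, 38–56 ppm ¹³C) of a mollusc polar extract: two
singlets 0.006 ppm apart on one carbon (55.623 ppm) with 10:1
amplitudes; three dd systems with 6.5/6.8 Hz passive couplings
(pseudo-triplets), one at 43.298 ppm and two sharing 38.426 ppm; and a
lone singlet at 3.271 ppm whose proton falls inside the broad decoupled
lineshape of the dd protons.  Proton shifts, couplings and amplitudes of
the dd systems are plausible placeholders, not measured values.  The
default grid is 12.0172 ppm × 16384 ¹H points and 60 ppm × 256 ¹³C
increments (zero filled to 1024); the spectrometer frequency, which no
printed acquisition table fixes, is taken as 700.13 MHz (¹H) /
176.05 MHz (¹³C), a common high-field configuration.  All linewidths
are 1 Hz (¹H) / 2 Hz (¹³C).

Test and acceptance runs use this geometry where the claim depends on it
(pattern integrals, shift restoration) and a 4096-point t2 / 32-increment
t1 grid for the 20-system J-recovery ensemble, which is insensitive to
the grid beyond the low-res digital resolution entering its bound.

## Known limitations

* First-order analysis only: strongly coupled multiplets violate both
  the simulator model and the equal-intensity pairing cost.
* Overlapped upfield components within J/2 produce summed ghost copies
  (flagged); no lineshape fitting or deconvolution is attempted.
* The J estimate rides on the low-resolution centroid; its accuracy
  (≈0.1 Hz on clean peaks, ~1–2 Hz for partially merged ones) bounds
  the restored-shift accuracy at J-error/2.
* The Bruker-style reader handles little-endian int32 processed data
  (`2rr` + `procs`/`proc2s`, XDIM submatrices) read-only; raw Bruker
  time-domain data, NUS, and 3D/4D spectra are out of scope.
* `estimate_noise` assumes the matrix is mostly baseline; a spectrum
  dense with signal inflates σ and hence the threshold.
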