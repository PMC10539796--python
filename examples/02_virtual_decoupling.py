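"""Full virtual-decoupling run on the zebra-mussel-like fixture.

Six spin systems emulate the trimethylamine region of a mollusc extract:
two nearly degenerate singlets (10:1 amplitude) on one carbon, three
pseudo-triplets and one extra singlet.  The pipeline reprocesses the CLAP
at low resolution, pairs the sign-split doublet components per 13C row
and back-shifts the upfield CLIP component of each pair by J/2.
"""

import numpy as np

import vdhsqc as v

systems = v.make_zebra_fixture()
clip = v.simulate_hsqc(systems, v.zebra_acquisition("clip"))
clap = v.simulate_hsqc(systems, v.zebra_acquisition("clap"))

result = v.virtual_decouple(clip, clap)
rep = result.report

print(f"{len(rep.pairs)} pairs, {len(rep.ambiguous_clusters)} ambiguous, "
      f"{len(rep.rejected)} rejected")
print(f"{'13C/ppm':>9} {'1H/ppm':>8} {'J/Hz':>7}")
for p in rep.pairs:
    f1_ppm = float(result.vd.f1_axis.index_to_ppm(p.f1_index))
    print(f"{f1_ppm:9.3f} {p.center_ppm:8.4f} {p.j_hz:7.2f}")

# the reconstructed trace of the 43.298 ppm carbon shows its 1:2:1 triplet
tr = v.extract_row(result.vd, 43.298)
m = v.multiplet_metrics(tr, threshold=0.05 * tr.intensities.max())
print(f"\ntrace at {tr.origin['f1_ppm']:.3f} ppm: {m.n_resolved} lines, "
      f"integrals {np.round(m.integrals, 3)}")
print("Each J estimate individualizes the back-shift; the 55.6 ppm pair is")
print("the merged 10:1 singlet doublet, restored as two resolved lines.")
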