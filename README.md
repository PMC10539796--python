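# vdhsqc — virtual decoupling of CLIP/CLAP HSQC spectra

`vdhsqc` reconstructs a **virtually decoupled** 1H–13C HSQC (vd-HSQC)
from a clean in-phase / clean anti-phase (CLIP/CLAP) spectrum pair.  It
is aimed at NMR metabolomics practitioners who need both things a
conventional HSQC cannot give at once: a single peak per 1H/13C pair
*and* proton multiplet fine structure at full resolution, so that 2D
cross peaks can be matched against high-resolution 1D and J-resolved
spectra during metabolite identification.

## The method

Without decoupling, each proton of a 1H–13C pair resonates at
δ<sub>H</sub> ± ¹J<sub>CH</sub>/2 (¹J<sub>CH</sub> ≈ 115–220 Hz).  In
the CLIP spectrum both doublet components are positive; in the CLAP
spectrum they have opposite sign.  The pipeline:

1. reprocesses the CLAP with only 1024 t2 points, deliberately
   destroying the J<sub>HH</sub> fine structure so each doublet
   component becomes a single peak;
2. picks peaks twice — once positive, once negative — and clusters them
   by 13C row;
3. pairs opposite-sign peaks whose separation is a plausible
   ¹J<sub>CH</sub>; the pair midpoint gives δ<sub>H</sub> and the
   separation gives J, individually for every 1H/13C pair;
4. extracts the window around the **upfield** component from the
   **full-resolution** CLIP row and shifts it downfield by J/2, placing
   the complete homonuclear multiplet at its true chemical shift.

A declarative spin-system simulator (CLIP, CLAP, decoupled-HSQC and
idealized J-res modes) provides ground truth for every stage, and
comparison utilities (trace correlation, multiplet metrics, region
zeroing, row scanning) reproduce the downstream identification logic.
See `docs/methods.md` for the model, the numerical choices and their
rationale.

## Worked example

`examples/02_virtual_decoupling.py` simulates a six-system fixture
emulating the trimethylamine region of a mollusc extract and runs the
full pipeline:

```
5 pairs, 0 ambiguous, 0 rejected
  13C/ppm   1H/ppm    J/Hz
   55.605   3.1186  144.93
   43.300   3.2520  141.98
   39.199   3.2710  139.98
   38.437   3.2418  128.40
   38.437   3.2602  136.90

trace at 43.300 ppm: 3 lines, integrals [1. 2. 1.]
```

Each line is one recovered 1H/13C pair: its carbon row, the restored
proton shift (the doublet midpoint) and the per-pair one-bond coupling
used for the back-shift.  The 55.6 ppm entry is two nearly degenerate
singlets (0.006 ppm apart, 10:1 in amplitude) whose merged doublet is
restored as two resolved lines — a separation a short-acquisition
decoupled HSQC cannot make.  The extracted trace of the 43.3 ppm carbon
shows the expected 1:2:1 pseudo-triplet of its two ~6.7 Hz couplings.

The other examples show the CLIP/CLAP doublet sign structure
(`examples/01_simulate_clip_clap.py`) and how a J-res multiplet trace
identifies its carbon row in the vd spectrum by coupling-pattern
matching (`examples/03_match_jres.py`).

## Command line

```sh
vdhsqc simulate --systems systems.json --out-prefix sim --modes clip,clap
vdhsqc run --clip sim/clip --clap sim/clap --out vd --report report.json
vdhsqc trace --spec vd --f1 43.298 --out trace.tsv
vdhsqc metrics --trace trace.tsv --threshold 100
vdhsqc match --vd vd --query trace.tsv --region 3.1,3.3
```

`report.json` is the machine-readable pairing report: every detected
peak appears exactly once among pairs, ambiguous clusters and
rejections, each with a reason, plus the configuration echo.

## Container format

A spectrum container is a directory with `data.bin` (row-major float64,
or complex128 for raw data) and `meta.json`:

```json
{
 "kind": "spectrum2d",          // or "rawfid2d"
 "dtype": "float64",
 "shape": [1024, 16384],
 "f1_axis": {"sw_ppm": 60.0, "sfo_mhz": 176.05,
             "left_edge_ppm": 79.98, "n_points": 1024},
 "f2_axis": {"sw_ppm": 12.0172, "sfo_mhz": 700.13,
             "left_edge_ppm": 9.5, "n_points": 16384},
 "label": "clip",
 "provenance": {}
}
```

Raw-data containers additionally record the States t1 interleaving and
the number of acquired t2 points.  A read-only reader for Bruker-style
processed data (`2rr` + `procs`/`proc2s`, including XDIM submatrix
blocking) is provided (`read_bruker_processed`).

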