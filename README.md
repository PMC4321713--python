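# nanospring

Quantitative analysis of **elastomeric, intrinsically disordered proteins**
— the silk-like springs found, for example, in the wall of cnidarian
nematocysts, whose explosive discharge is powered by the recoil of
stretched, disordered wall proteins such as Cnidoin.

The package re-implements, as a tested and reusable pipeline, the five
analyses by which such a protein's elastomeric character is established:

1. **Worm-like chain (WLC) mechanics** (`nanospring.wlc`) — the
   Marko–Siggia force–extension law
   `F(x) = (kB·T/Lp)·[1/(4(1−x/Lc)²) − 1/4 + x/Lc]`,
   its bracketed inverse, nonlinear least-squares fitting, and the
   residue-count contour-length estimate `Lc = N·0.32 nm + linker`.
2. **AFM force spectroscopy** (`nanospring.afm`) — parsing retract traces,
   baseline/contact correction, the contour-length transform, detection of
   the cohesin–dockerin specificity fingerprint (terminal double rupture
   separated by 8 nm in contour-length space), per-trace WLC fits and
   population histograms of Lp and Lc.
3. **Umbrella sampling / WHAM** (`nanospring.pmf`) — self-consistent
   reconstruction of the potential of mean force along the end-to-end
   distance from harmonically biased windows, and the mean-force profile
   `F(z) = dG/dz` that is fitted with a WLC to give an effective
   persistence length.
4. **Collapse kinetics** (`nanospring.collapse`) — first-passage detection
   at the 1.5 nm collapsed-state threshold, cumulative event curves, the
   exponential lifetime fit `N(t) = n·(1 − e^(−t/τ))` with parametric
   bootstrap confidence intervals, and the polyproline-II dihedral
   fraction.
5. **Amide-I FTIR decomposition** (`nanospring.ftir`) — preprocessing
   (region restriction, background removal, vector normalisation),
   replicate medians, 1–13-component Gaussian mixture fits from seeded
   random starts, corrected-AIC model averaging
   (`w_i = e^(−ΔAICc_i/2)/Σ_j e^(−ΔAICc_j/2)`), and the width analysis of
   the disorder-indicative band near 1,645 cm⁻¹.
6. **Sequence disorder metrics** (`nanospring.sequence`) — amino-acid
   composition, the charge–hydropathy (Uversky) classification with the
   boundary `R = 2.785·H − 1.151`, and elastic-motif scanning (GXGQQ).

A seeded synthetic-data module (`nanospring.synth`) stands in for the AFM
instrument, the MD engine and the FTIR spectrometer, emitting data in
exactly the formats the analysis modules read, together with ground truth.

## Worked example

Generate a synthetic AFM cohort and recover the population elasticity:

```python
import numpy as np
from nanospring import afm, synth

traces, truth = synth.gen_fd_traces(n_traces=100, seed=11)
fits = []
for trace in traces:
    corrected = afm.correct_baseline(trace)
    event = afm.detect_specific_event(corrected, persistence_length_nm=0.4)
    if event.specific:
        fits.append(afm.analyze_trace(corrected, event))

pop = afm.summarize_population(fits, n_total=len(traces))
print(f"accepted {pop.n_accepted}/{pop.n_total} traces")
print(f"Lc = {pop.contour_mean_nm:.1f} +- {pop.contour_sd_nm:.1f} nm")
print(f"Lp = {pop.persistence_mean_nm:.3f} +- {pop.persistence_sd_nm:.3f} nm")
```

prints

```
accepted 84/100 traces
Lc = 90.9 +- 36.8 nm
Lp = 0.359 +- 0.042 nm
```

84 of the 100 traces carry the double-rupture fingerprint and are accepted
(the cohort was generated with an 80% specific fraction; 84 specific
traces were drawn); the fitted population mean contour length (90.9 nm)
and persistence length (0.359 nm)
recover the generating distribution (Lc ~ Normal(94, 43) truncated above
20 nm, Lp = 0.37 nm) despite 5 pN of force noise. The low persistence
length — well below the ~1 nm of a structured polypeptide under load — is
the mechanical signature of a disordered, highly flexible chain.

The same workflow is available from the shell:

```bash
nanospring simulate afm --seed 11 --n 100 --out traces/
nanospring afm --traces traces/ --out afm_report.json
```

and `nanospring run --config pipeline.toml` orchestrates all stages from a
single TOML file.

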