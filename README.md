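# nmrbind

Quantitative analysis of fast-exchange ¹H NMR observables for a small
aromatic drug candidate interacting with itself and with a nicked DNA
duplex — the model system for topoisomerase-I poisons of the camptothecin
family, where the compound must bind inside the transient single-strand
break.  The package was built around a study of two 5-substituted SN38
diastereomers and a nicked DNA decamer, whose data tables ship with it,
but every stage is generic.

It is a library first (import `nmrbind`), with narrative scripts in
`examples/` and a thin `nmrbind` CLI for shell use.

## What it computes

**Self-association from dilution series** (`nmrbind.selfassoc`).
Stacking of an aromatic solute L is described by the isodesmic
(indefinite, equal-K) model, every step `L_n + L ⇌ L_{n+1}` sharing one
constant `K_a`.  The observed shift change of each proton follows

    Δδ_obs(c) = Δδ_max · (2C + 1 − √(4C + 1)) / (2C),   C = K_a·c,

with `c` the total concentration (mM) and `Δδ_max` the limiting
monomer-to-stack shift (Hz, sign free).  `fit_isodesmic` estimates
(`K_a`, `Δδ_max`) per proton by nonlinear least squares; `summarize_ka`
averages the per-proton constants with explicit exclusions.

**1:1 binding constants from DOSY** (`nmrbind.dosy`).  Under fast
exchange the ligand's observed diffusion coefficient is the population
average `D_obs = MF_L·D_L + (1 − MF_L)·D_complex`, so with the free-ligand
coefficient (from the most dilute sample) and the complex coefficient
(approximated by the duplex coefficient in the mixture) the bound fraction,
the complex concentration `[DNA·L] = (1 − MF_L)·C_L`, and

    K_a = [DNA·L] / ((C_DNA − [DNA·L])(C_L − [DNA·L]))

follow in closed form, with delta-method uncertainty propagation.

**Binding-site mapping from chemical-shift perturbations**
(`nmrbind.csp`).  `Δδ = δ_free − δ_complex` (ppm, positive = upfield) is
computed per proton, flagged at the 0.02 ppm level, and flagged DNA
protons are located relative to the nick of the duplex.

**Synthetic data** (`nmrbind.synthetic`) draws from the same three forward
models with seeded Gaussian noise, for exact-inversion tests and
parameter-recovery studies.

## Worked example

```python
from nmrbind import fit_isodesmic, summarize_ka, analyze_binding
from nmrbind.datasets import load_dilution_series, load_dosy_experiment

fits = [fit_isodesmic(s) for s in load_dilution_series("1")]
print(summarize_ka(fits, excluded=("H12",)).mean_ka)   # 6.88 mM^-1

result = analyze_binding(load_dosy_experiment("1"))
print(result.mf_bound, result.ka)                      # 0.862, 75.8 mM^-1
```

Running `python examples/self_association.py` prints the per-proton fits
for both diastereomers, e.g. for compound 1:

```
  H9       Ka =  4.536 mM^-1   ddmax =   111.9 Hz
  ...
  mean Ka = 6.4 +/- 2.3 mM^-1; without H12: 6.9 +/- 1.6 mM^-1
```

— the stacking constant of the 5R diastereomer is about twice that of 5S
(6.4 vs 2.9 mM⁻¹), i.e. it aggregates more readily.  `examples/dosy_binding.py`
prints the binding side:

```
  D_obs(ligand) = 0.93 -> bound fraction 0.86, [complex] = 0.52 mM
  Ka = 76 +/- 58 mM^-1 ...
```

and `examples/csp_nick_mapping.py` lists the flagged DNA protons (T5, G6,
C15, A16 H1′ and G6, T7, A16 H6/H8 for compound 1), all of which sit in
the base pairs flanking the nick — the data-level evidence that the ligand
binds inside the strand break.

The same stages run from the shell:

```sh
nmrbind run --out reports/           # full pipeline on the packaged tables
nmrbind selfassoc --input my_dilution.csv --exclude H12 --out fit.json
nmrbind binding --input my_dosy.csv --cl 0.6 --cdna 0.6
nmrbind csp --input my_shifts.csv --nick-map nick.json
nmrbind simulate dilution --seed 7 --out synth/
```

## Layout

```
src/nmrbind/        tables.py (I/O + data model), selfassoc.py, dosy.py,
                    csp.py, synthetic.py, datasets.py (packaged tables),
                    pipeline.py, cli.py
src/nmrbind/data/   CSV transcriptions of the study tables + nick map
examples/           one narrative script per capability
docs/methods.md     models, assumptions, numerical choices, limitations
```
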