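# shiftprobe

Quantitative analysis toolkit for solution-NMR and biochemistry studies of
membrane-protein/ligand interactions, built around the workflow used to
characterize a small α-helical oxidase subunit in detergent micelles and its
weak (millimolar) nucleotide binding:

- **Chemical-shift-perturbation (CSP) mapping** of an HSQC titration series:
  peak tracking across steps, weighted shift changes, and robust
  classification of significantly perturbed residues.
- **Global Kd fitting** of the fast-exchange, ligand-depletion binding
  isotherm, one shared Kd across residues, with covariance and bootstrap
  uncertainties.
- **PRE topology profiling**: I/I<sub>ref</sub> attenuation profiles for
  water-soluble vs detergent-partitioning paramagnetic probes, exclusion
  rules, error propagation and Gaussian sequence-weighted smoothing.
- **Secondary-shift helix delineation** from Cα shifts against a bundled
  random-coil reference.
- **CD preprocessing** to mean residue molar ellipticity (MRE).
- **Oxidase turnover kinetics**: rate extraction from oxygen-electrode
  traces (4 e⁻ per O₂) and one/two-component hyperbolic (Michaelis–Menten)
  fits with F-test model comparison.
- A **synthetic-data generator** whose defaults encode the study design, so
  every stage is verifiable by parameter recovery without any downloads.

## The models

CSPs combine ¹H and ¹⁵N shift changes as
CSP = √(Δδ<sub>H</sub>² + (α·Δδ<sub>N</sub>)²), with α = 0.2 for glycine and
0.14 otherwise. In fast exchange the CSP tracks the bound fraction, which for
a 1:1 complex at *total* concentrations P and L is the quadratic root

CSP(P, L) = CSP<sub>max</sub> · [(P + L + K<sub>d</sub>) − √((P + L + K<sub>d</sub>)² − 4PL)] / (2P),

fitted globally (one K<sub>d</sub>, one CSP<sub>max</sub> per residue).
Enzyme rate curves are sums of hyperbolae v(c) = Σ<sub>k</sub> V<sub>k</sub>·c/(K<sub>m,k</sub> + c);
an extra-sum-of-squares F-test decides between one and two components.

## Worked example

`python examples/01_csp_titration_kd.py` simulates the study titration
design (0.135 mM protein, ligand ratios 2–100, true K<sub>d</sub> 15 mM,
0.01 ppm shift noise), runs the full pipeline and prints:

```
perturbed residues (CSP > 0.024 ppm): [83, 96, 125, 129]
global Kd = 13.8 mM (SE 3.0, 95% CI 9.5-22.5)
  residue 83: csp_max = 0.296 ppm, bound fraction at endpoint = 0.49
  residue 96: csp_max = 0.158 ppm, bound fraction at endpoint = 0.49
  residue 125: csp_max = 0.280 ppm, bound fraction at endpoint = 0.49
  residue 129: csp_max = 0.047 ppm, bound fraction at endpoint = 0.49
```

The fitted K<sub>d</sub> recovers the generating 15 mM within its interval,
the per-residue maximal CSPs recover their ground truth (0.29, 0.18, 0.29
ppm), and the endpoint bound fraction (~0.5) shows the titration reaches
only the onset of saturation — which is why a *global* fit across residues
is needed in this weak-binding regime. The other examples cover PRE
topology, helix segmentation, CD preprocessing and oxidase kinetics, one
capability per script.

A thin command-line layer mirrors the library:

```sh
shiftprobe simulate titration --seed 3 --out sim/
shiftprobe fit-kd --series sim/series.json --residues 81,83,96,125 \
    --boot 500 --max-jump 0.3 --out fit.json
```

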