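"""Chemical-shift-perturbation mapping and global Kd fitting.

Simulates a fast-exchange ATP-style titration (protein at 0.135 mM, ligand
ratios 2x to 100x, shared Kd 15 mM), tracks the amide peaks across steps,
classifies the significantly perturbed residues and fits one global Kd with
bootstrap confidence intervals.
"""

from shiftprobe import (
    PipelineConfig,
    SyntheticSpec,
    run_titration_pipeline,
)

# k_sigma=3 keeps only clearly perturbed residues in the global fit
config = PipelineConfig(seed=7, synthetic=SyntheticSpec(seed=7), n_boot=200, k_sigma=3.0)
report = run_titration_pipeline(config)

cls = report.stages["classification"]
fit = report.stages["binding_fit"]
print(f"perturbed residues (CSP > {cls['threshold_ppm']:.3f} ppm): {cls['residues']}")
print(f"global Kd = {fit['kd_mM']:.1f} mM (SE {fit['kd_se_mM']:.1f}, "
      f"95% CI {fit['kd_ci_mM'][0]:.1f}-{fit['kd_ci_mM'][1]:.1f})")
for res, amp in fit["csp_max_ppm"].items():
    print(f"  residue {res}: csp_max = {amp:.3f} ppm, "
          f"bound fraction at endpoint = {fit['saturation'][res]:.2f}")

# The Kd is in the weak (mM) regime: even at the 100x ratio only about half
# the protein is bound, so the fit leans on the shared curvature across
# residues rather than on saturation of any single curve.
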