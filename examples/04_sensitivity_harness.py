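"""Sensitivity of the strain recovery to noise, intensity and fibers.

Re-runs the phantom registration under degraded conditions - additive
noise on both frames, reduced intensity, perturbed fiber inclination
angles (+/-5%), and with the active contraction ablated - and tabulates
R^2 and %RMSE against ground truth for each condition, mirroring how a
registration method's robustness is characterized.  Each row is one full
registration; the whole script takes on the order of ten minutes.
"""

from warpstrain import (
    BASELINE_FIBER_ANGLES,
    NoiseSpec,
    PhantomSpec,
    add_noise,
    assign_fibers,
    compare_tables,
    local_frames,
    make_phantom_pair,
    perturb_fiber_angles,
    register,
    scale_intensity,
    strain_table_from_displacements,
)

template, target, truth, mesh = make_phantom_pair(PhantomSpec())
frames = local_frames(mesh)


def run(label, tpl, tgt, angles=BASELINE_FIBER_ANGLES, active_on=True):
    fibers = assign_fibers(mesh, angles, frames=frames)
    res = register(tpl, tgt, mesh, fibers, active_on=active_on)
    pred = strain_table_from_displacements(mesh, res.final_displacement, frames)
    st = compare_tables(truth, pred)
    c, r = st["circumferential"], st["radial"]
    print(f"{label:28s} R2c={c.r_squared:.3f} %RMSEc={c.percent_rmse:.3f}  "
          f"R2r={r.r_squared:.3f} %RMSEr={r.percent_rmse:.3f}")


run("validation", template, target)
for snr in (8.0, 4.0):
    ntpl, _ = add_noise(template, NoiseSpec(snr=snr, seed=0))
    ntgt, _ = add_noise(target, NoiseSpec(snr=snr, seed=1))
    run(f"SNR {snr:g}", ntpl, ntgt)
run("20% intensity reduction", scale_intensity(template, 0.2),
    scale_intensity(target, 0.2))
run("fiber angles +5%", template, target,
    perturb_fiber_angles(BASELINE_FIBER_ANGLES, +0.05))
run("fiber angles -5%", template, target,
    perturb_fiber_angles(BASELINE_FIBER_ANGLES, -0.05))
run("no active contraction", template, target, active_on=False)
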