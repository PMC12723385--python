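"""The closed-form force models: grip friction, drag, Reynolds, lever.

Evaluates the grip-friction laws at the escape-threshold compressions,
estimates the struggling Reynolds number, computes the pressure drag of a
broadside-moving body section, and runs the lever escape criterion.
"""

import numpy as np

from tadstruggle import mechanics as mech

print("grip friction (uN) at escape-threshold head compressions:")
for dw in (0.11, 0.124, 0.154, 0.156):
    print(f"  dw = {dw:.3f} h.w. -> fitted {mech.fitted_friction(dw):5.2f}"
          f"   Hooke {mech.hooke_friction(dw):5.2f}")
quad, lin = mech.hooke_coefficients()
print(f"Hooke law expands to {quad:.1f} dw^2 {lin:+.2f} dw "
      f"(mu = tan(4.5 deg) = {mech.friction_coefficient(4.5):.3f})")

re = mech.reynolds(0.085, 0.002)
print(f"struggling Reynolds number: {re:.1f} "
      f"(pressure drag dominates skin friction)")

body = mech.BodyModel()
areas = mech.section_areas(body, 5, span=(0.0, 2.5))
print("rostral-half section areas (mm^2):",
      np.array2string(areas, precision=2))

# one 1 mm^2 section sweeping broadside at 100 mm/s
times = np.arange(9) / 1000.0
ends = np.zeros((9, 2, 3))
ends[:, 1, 0] = 1.0
ends[:, :, 1] += (100.0 * times)[:, None]
drag = mech.pressure_drag(body, times, ends, areas=np.array([1.0]))
print(f"broadside drag on a 1 mm^2 section at 100 mm/s: "
      f"{drag['Fmag'].iloc[4]:.2f} uN")

state = mech.LeverState(f1=5.0, l1=2.0, l2=1.5, alpha=30.0)
out = mech.lever_escape(state, friction=mech.fitted_friction(0.124))
print(f"lever: F2x = {out.f2x:.2f} uN vs friction "
      f"{mech.fitted_friction(0.124):.2f} uN -> "
      f"{'escapes' if out.escapes else 'stuck'}")
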