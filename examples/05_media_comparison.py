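"""Growth stress read off the density: standard vs carbon-depleted medium.

The published per-replicate growth rates omega and density prefactors
D = C/(B1 B2) for thalli on standard (M2) and carbon-depleted (M0)
media feed the closed-form phase time and the media-comparison tests.
"""

import numpy as np

import mycelia as m
from mycelia import published as pub

for label, omegas in (("M2", pub.M2_OMEGA_PER_H), ("M0", pub.M0_OMEGA_PER_H)):
    omega = float(np.mean(omegas))
    print(f"{label}: mean omega = {omega:.3f} /h  ->  "
          f"t_min = {m.t_min(omega):.1f} h")

f, df1, df2, p = m.one_way_anova(pub.M2_D_H2_PER_MM2, pub.M0_D_H2_PER_MM2)
print(f"one-way ANOVA on D: F({df1},{df2}) = {f:.2f}, p = {p:.4f} "
      f"(means {np.mean(pub.M2_D_H2_PER_MM2):.0f} vs "
      f"{np.mean(pub.M0_D_H2_PER_MM2):.0f} h²/mm²)")
w, p_lev = m.levene_mean_centered(pub.M2_D_H2_PER_MM2, pub.M0_D_H2_PER_MM2)
print(f"mean-centered Levene: p = {p_lev:.4f} "
      f"-> variances equal, the medium shifts the level of D, not its spread")

res = m.binomial_orientation_test(round(0.54 * 198), 198, m_comparisons=3)
print(f"orientation test (54% cw of 198): p = {res.p_value:.2f} "
      f"-> clockwise/counterclockwise equiprobable")
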