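"""Grow one M2-calibrated thallus and look at its network anatomy.

Six germ tubes leave the ascospore, tips elongate under the ramping
velocity law and branch apically (latency 180 µm, then a memoryless
base-2 law) and laterally (never within 480 µm of the owning apex).
"""

import mycelia as m

traj = m.run(m.reference_config(seed=0, t_end_h=13.0))
graph = traj.final_graph
counts = m.classify_vertices(graph)
tort = m.tortuosity(graph)

print(f"grew {len(traj.hyphae)} hyphae, {len(traj.events)} branch events "
      f"in {traj.t_end_h:.0f} h")
print(f"vertex classes: V1={counts.v1} V1l={counts.v1l} "
      f"V3={counts.v3} V3l={counts.v3l} crossings V3i={counts.v3i}")
print(f"one-body ratio (V1+V1l)/(V3+V3l+V3i): "
      f"{m.one_body_ratio(counts):.3f}")
print(f"total length {tort.l_tot_um/1000:.1f} mm, "
      f"tortuosity alpha = {tort.alpha:.3f}  (measured in vivo: 0.038)")

# tips = junctions + one base and one apex per germ tube
n_init = traj.config.germination.n_initial_hyphae
assert counts.one_body == counts.v3 + counts.v3l + 2 * n_init
print("binary-tree identity holds: #tips = #junctions + 2 x germ tubes")
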