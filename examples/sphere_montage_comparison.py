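"""Standard vs high-definition montage on a mouse-like layered sphere.

Builds a four-shell sphere phantom (gray matter 4 mm, CSF 4.4, bone 4.8,
skin 5.2 mm; mouse-head scale) and compares two montages targeting the
dorsal pole:

* ``1xBack``  — one 0.6 mm disc anode (+0.2 mA) at the target and a large
  return pad on the opposite side (distant return);
* ``1x4``     — the same anode surrounded by four disc cathodes
  (-0.05 mA each) on a 2 mm ring (center-surround, "high definition").

Reports whole-"brain" mean field magnitude, direction homogeneity and the
mean normalized components.
"""

import numpy as np

import mousefield as mf

shells = [
    mf.Layer("gray_matter", 0.275, 4.0),
    mf.Layer("csf", 1.654, 4.4),
    mf.Layer("bone", 0.01, 4.8),
    mf.Layer("soft_tissue", 0.465, 5.2),
]
sphere = mf.make_layered_sphere(shells, subdiv=3)
target = (0.0, 0.0, 5.2)

results = {}
for name in ("1xBack", "1x4"):
    montage = mf.preset_montage(name, target, back_size_mm=(4.0, 4.0), ring_radius_mm=2.0)
    applied = mf.apply_montage(sphere.mesh, sphere.tissues, montage)
    solution = mf.solve(mf.build_problem(applied))
    brain = mf.select_tissue_region(applied.mesh, [sphere.label_of["gray_matter"]], "brain")
    results[name] = mf.summarize(solution, brain)

for name, summary in results.items():
    print(f"--- {name} (whole sphere 'brain', {summary.n} nodes) ---")
    print(summary.to_text())
    print()

ratio = (
    results["1xBack"].stats.loc["eMag", "mean"] / results["1x4"].stats.loc["eMag", "mean"]
)
print(f"standard / high-definition mean eMag ratio: {ratio:.1f}")
print()
print("The tight center-surround montage shunts most of the injected current")
print("through the skin between its closely spaced electrodes, so the brain")
print("field is many times weaker (and less uniformly oriented) than with a")
print("distant return electrode. The dominant -z component of the 1xBack")
print("montage is the dorsal-to-ventral direction.")
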