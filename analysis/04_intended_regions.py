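#!/usr/bin/env python
"""Step 2: presenting two visual-field directions with intended-region
placements.

Runs the one-direction placements i-iv and the two-direction pairs I-III
under both phase conditions, classifies each montage's per-eye peaks
against its intended eyeball-surface zones, and quantifies interference
via the off-target/on-target ratio and the composed differences.
"""
from _common import get_solver, outdir, seed_from_argv
from ocufield.evaluation import run_step2_intended_regions

solver = get_solver(seed_from_argv())
report = run_step2_intended_regions(solver)
report.write(outdir())

print("peak classification (montage, phase -> per-eye zone hits):")
for row in report.summary["classification"]:
    print(f"  {row['montage']:>4s} {row['phase']:>4s}: "
          f"intended zones hit = {row['all_zones_hit']}, "
          f"interference score = {row['interference_score']:.3f}")
d = report.differences
comp = d[d.kind == "composed"]
print(f"composed differences (pairs I-III): range "
      f"[{comp.difference.min():.3f}, {comp.difference.max():.3f}] V/m")
print(f"wrote step2_* tables to {outdir()}")
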