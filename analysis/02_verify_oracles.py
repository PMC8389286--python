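#!/usr/bin/env python
"""Cross-validate the FEM solver before any study runs.

Three independent routes to the same box problem — P1 finite elements,
a 7-point finite-difference scheme, and the closed-form two-monopole
potential — must agree within their stated tolerances (3% and 5%); a
failure here blocks the downstream studies.
"""
import json
import os

from _common import outdir
from ocufield.oracles import run_box_verification

report = run_box_verification()
out = outdir()
with open(os.path.join(out, "verify_report.json"), "w") as f:
    json.dump(report, f, indent=2)

print(f"FEM vs closed form: max {report['max_rel_err_vs_closed_form']:.2%} "
      f"(tolerance {report['tol_closed_form']:.0%})")
print(f"FEM vs finite differences: max {report['max_rel_err_fem_vs_fd']:.2%} "
      f"(tolerance {report['tol_fem_vs_fd']:.0%})")
print(f"flux asymmetry: FEM {report['fem_flux_asymmetry_rel']:.1e}, "
      f"FD {report['fd_flux_asymmetry_rel']:.1e}")
print("verification " + ("PASSED" if report["passed"] else "FAILED"))
if not report["passed"]:
    raise SystemExit(1)
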