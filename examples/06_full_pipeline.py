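"""Run the complete pipeline: simulate -> features -> score -> reaction
norms -> DHGLM -> welfare association.

Every stage writes delimited-text outputs under the run directory, so any
stage can be re-run in isolation or fed real data in the same formats.
"""

import json
import tempfile
from pathlib import Path

import hennorm

outdir = Path(tempfile.mkdtemp()) / "demo_run"
cfg = hennorm.RunConfig(outdir=outdir, seed=0, log_level="WARNING")
report = hennorm.run(cfg)

print("stage status:")
for stage, status in report["stages"].items():
    print(f"  {stage:12s} {status}")

print(f"\nrepeatability  {report['repeatability']:.2f} "
      f"{[round(v, 2) for v in report['repeatability_ci']]}")
print(f"CVp            {report['cvp']:.2f} "
      f"{[round(v, 2) for v in report['cvp_ci']]}")
peak = report["peak_day"]
print(f"peak day       {peak:.0f}" if peak else "peak day       n/a")
print(f"beta(predictability) {report['welfare_beta_predictability']:.1f}")
print(f"beta(no-trans days)  {report['welfare_beta_ntd']:.1f}")

print("\nfiles written:")
for p in sorted(outdir.iterdir()):
    print(f"  {p.name}")
print(f"\nfull report: {outdir / 'report.json'}")
print(json.dumps(report["lrt"], indent=2))
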