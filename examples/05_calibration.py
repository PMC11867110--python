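"""A miniature simulation-based calibration run (4 replicates).

Full-scale checks (30 replicates x 2e5 iterations) are run by
scripts/acceptance.py; this prints the shape of the report.
"""
from gestaltree.validation import (CalibrationChainConfig,
                                   CalibrationSimConfig, run_calibration)

report = run_calibration(
    n_replicates=4,
    sim_config=CalibrationSimConfig(n_tips=6),
    chain_config=CalibrationChainConfig(iterations=10_000, thin=20),
    seed=1)
print(report.table.pivot(index="level", columns="param",
                         values="coverage").to_string())
print("converged replicates:", report.converged)
# with matched priors the coverage column should track the level column;
# binomial bands at n=4 are wide, so this is only an API illustration
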