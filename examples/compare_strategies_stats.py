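"""Statistical comparison of prompting strategies.

Builds a benchmark run (as in run_benchmark.py, but 10 cycles), then per
complexity level forms the strategies x {executable, not executable}
contingency table, runs a chi-square test of independence, and adjusts the
per-level p-values with the Benjamini-Hochberg step-up procedure.
"""

from pathlib import Path

from execbench import run_trials, SelfCorrectConfig, strategy_comparison_table
from execbench.fixtures import make_bernoulli_agent_factory, materialize_suite

data_dir = Path("scratch/example-suite")
tasks = materialize_suite(data_dir, seed=1)

records = run_trials(
    tasks,
    ["simple", "selfCorrect"],
    make_bernoulli_agent_factory(seed=1),
    cycles=10,
    config=SelfCorrectConfig(language_backend="python", dependency_policy="forbid"),
    data_dir=data_dir,
)

frame = strategy_comparison_table(records)
cols = ["complexity", "statistic_display", "p_display", "adjusted_p_display", "significance"]
print(frame[cols].to_string(index=False))
print(
    "\nEach row: does executability differ between strategies at that\n"
    "complexity? Small adjusted p (**, ***) = the strategies differ; ns = no\n"
    "detectable difference. Levels where every trial executed are skipped\n"
    "(the test is undefined there)."
)
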