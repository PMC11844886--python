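"""Run a small executability benchmark with a stochastic mock model.

Each trial's mock replies succeed with a complexity-dependent probability p,
so the 'simple' strategy's executable fraction tracks p while the
self-correction strategy (up to 3 attempts) tracks 1 - (1-p)^3 — the
recovery arithmetic that makes error feedback the strongest strategy.
A real benchmark run replaces the factory with a live agent handle.
"""

from pathlib import Path

from execbench import aggregate_frame, run_trials, SelfCorrectConfig
from execbench.fixtures import (
    DEFAULT_SUCCESS_PROBABILITIES,
    make_bernoulli_agent_factory,
    materialize_suite,
)

data_dir = Path("scratch/example-suite")
tasks = materialize_suite(data_dir, seed=1)

records = run_trials(
    tasks,
    ["simple", "selfCorrect"],
    make_bernoulli_agent_factory(seed=1),
    cycles=3,
    config=SelfCorrectConfig(language_backend="python", dependency_policy="forbid"),
    data_dir=data_dir,
)

print(f"trial records: {len(records)}  (20 tasks x 2 strategies x 3 cycles)")
frame = aggregate_frame(records)
print(frame[["strategy", "complexity", "n_trials", "fraction_executable"]].to_string(index=False))
print("\nper-attempt success probabilities p:", DEFAULT_SUCCESS_PROBABILITIES)
print("selfCorrect fractions should sit near 1-(1-p)^3, simple near p.")
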