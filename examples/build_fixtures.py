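"""Materialize the synthetic 20-task suite and its data files.

The suite has 4 tasks at each complexity level 1-5, where complexity counts
the components a task involves (file reading, wrangling, visualization,
ML/statistics, multiple datasets).  The data files are deterministic
functions of the seed.
"""

from collections import Counter
from pathlib import Path

from execbench import materialize_suite
from execbench.prompts import build_file_header_addendum

out = Path("scratch/example-suite")
tasks = materialize_suite(out, seed=1)

print(f"tasks: {len(tasks)}")
print("tasks per complexity:", dict(sorted(Counter(t.complexity for t in tasks).items())))

task = next(t for t in tasks if t.id == "c1_subjects_dims")
print(f"\nexample task ({task.id}, complexity {task.complexity}):")
print(task.prompt_text)

# The same header extraction that file-content prompting uses:
print()
print(build_file_header_addendum(list(task.data_files), out, n_lines=2))
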