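# Methods

## The procedure

`execbench` automates one round-trip of LLM-assisted data analysis and
instruments it end to end. A *task* is a plain-text description of an
analysis over one or more tabular data files. One *trial* proceeds:

1. **Prompt construction.** A fixed system prompt selects the strategy:
   `simple` (bare instruction to return code in triple backticks as a single
   final block), `actAs` (expert-bioinformatician role framing), or `cot`
   (role framing plus a step-by-step instruction). The templates are frozen
   strings with a single substitution slot for the generated-code language
   (default R; the benchmark here runs the Python backend). With
   file-content inclusion, filenames detected in the task text (tokens of
   word characters/dots/hyphens ending in a recognized data extension) are
   read and the first *n* lines of each (default 2) appended at the end of
   the user prompt as
   `Here are the first two lines of the file <name>:` blocks.
2. **Reply processing.** The reply is normalized (typographic quotes →
   ASCII, zero-width/non-breaking spaces removed, CRLF → LF), the code is
   extracted from the *last* fenced block (the prompts demand a single final
   block; a concatenate-all policy exists for models that split code), and
   dependencies are detected line-wise (`library()`, `require()`, `::`,
   `install.packages()` for R; `import` / `from … import` for Python).
3. **Execution.** The code runs in a brand-new interpreter process whose
   working directory is a per-trial workspace holding *copies* of the
   referenced data files. Nonzero exit → `error` with stderr captured;
   exceeding the timeout → `timeout` and the process group is killed; files
   newly present under the workspace are recorded as artifacts.
4. **Self-correction** (strategy `selfCorrect`). On failure, the next user
   turn is the fixed correction instruction with the error text embedded
   verbatim, appended to the same transcript so the model sees its own prior
   code; the loop stops at the first success or after `max_attempts`
   (default 3) rounds. A reply without any fence is treated as a failed
   attempt with a synthesized "no code block found" error; a timeout feeds
   back "execution exceeded the time limit"; a dependency-installation
   failure feeds back as an error too.

Strategy stacking: `fileCont` = the simple system prompt + file headers;
`selfCorrect` = `fileCont` + the correction loop.

## The benchmark and its statistics

Task complexity is the count (1–5) of components from {read file, wrangle,
visualize, ML/statistics, multiple datasets}. The shipped suite has 20 tasks,
4 per level; a benchmark run evaluates tasks × strategies × cycles (default
10 cycles to average over model stochasticity), recording per trial the
final-reply length in characters, the executable flag, and attempts used.
Response length is measured on the final reply, not the concatenation of all
attempts, so it remains a per-response property. With 4 tasks × 10 cycles
per stratum every executability fraction is a multiple of 1/40 = 0.025.

Per complexity level the strategies × {executable, not executable} table is
tested with Pearson's chi-square test of independence, no continuity
correction (the tables of interest have > 1 degree of freedom; a Yates flag
exists for 2×2 use, default off). A level where one outcome column is empty
(e.g. everything executed) leaves the test undefined and is skipped with
that noted. The per-level p-values are Benjamini–Hochberg adjusted with the
family = the complexity levels tested. Full precision is carried end to end;
display rounding is 3 significant figures, halves away from zero (plain
float rounding is round-half-even and would mis-render e.g. 3.525e-3).

## Synthetic study conditions

The scripted mock backend replays a fixed ordered list of replies (strict or
cycling), making every loop behaviour reproducible bitwise. The stochastic
benchmark mock draws each reply independently: runnable code with
probability *p* set per complexity to

| complexity | 1 | 2 | 3 | 4 | 5 |
|---|---|---|---|---|---|
| p | 0.95 | 0.85 | 0.60 | 0.45 | 0.30 |

— a monotone decline chosen once to mirror the qualitative shape of
baseline single-shot executability on real models (near-certain for
read-a-file tasks, well below half for five-component tasks). Under
independence the self-correction loop's success probability is
1 − (1−p)³, which the end-to-end test checks within 3 binomial standard
errors at 40 trials per stratum. Per-trial randomness is a pure function of
(seed, task id, strategy, cycle).

The data fixtures are log-normal expression matrices (per-gene log-scale
spread 0.3, inflated to 1.5 for a 20% "variable gene" subset, giving the
heavy-tailed variance distribution that top-k-variable-genes tasks need)
and categorical/numeric annotation tables. They emulate the *shape* of real
omics tables — gene names in the first column, samples in columns,
tab-separated — not any real biology: passing tests shows the machinery
(prompting, extraction, execution, accounting, statistics) is correct, not
that any particular model analyses real data well. Live-model executability
also depends on decoding temperature, which providers do not fix by
default; live runs default to temperature 0 for repeatability and record
the effective decoding settings on every trial record.

## Numerical and design choices

- **Problem sizes.** The shipped suite's data files are small
  (40–60 genes × 6–8 samples, ≤ 24 annotation rows) and the end-to-end
  benchmark runs 20 tasks × 10 cycles × 2 strategies; these sizes keep a
  full run to a few hundred real subprocess executions while leaving every
  fraction estimable to ±3 SE. All sizes are parameters.
- **Timeouts** default to 300 s per execution (1 s in tests that exercise
  the timeout path); a timeout counts as non-executable.
- **Warnings** do not fail a run by default — executability is defined by
  error occurrence — but `strict_warnings` flips that for pipelines where
  warnings matter.
- **Dependency policy** defaults to `install_allowlisted` semantics in
  deployment descriptions but `report_only`/`forbid` everywhere in this
  repository's tests: installing arbitrary package names proposed by a
  model is a supply-chain hazard, so only a short allowlist of common
  analysis packages is ever auto-installable.
- **Remote transport** retries transient failures 3 times with exponential
  backoff before surfacing, so API flakiness is not recorded as task
  failure; trials that still fail at transport are flagged
  `infrastructure_error` and excluded from aggregation rather than counted
  as non-executable. Mock errors never retry.
- **Credential hygiene**: agent specs carry only a *reference* (environment
  variable name or file path) to the secret; the secret value never enters
  transcripts, records, or reports.
- **Degenerate inputs**: empty component sets, transcripts that do not
  alternate, tables with zero marginals, p-values outside (0, 1], and
  non-positive timeouts are rejected with specific errors rather than
  propagated.

## Limitations

- The sandbox gives process-level isolation (fresh interpreter, confined
  working directory, timeout), not OS-level containment; running truly
  untrusted code still warrants a container.
- Correctness of executable code is out of scope: trial records carry a
  manual-annotation field (`unassessed`/`correct`/`incorrect`) but nothing
  grades outputs automatically — executable-but-wrong code is a known
  failure mode this package only exposes for human review (the HTML session
  report exists for exactly that).
- The filename detector is an extension allowlist over word-ish tokens; it
  will miss paths with spaces and exotic extensions by design.
- Only wall-clock limits are enforced; memory/CPU quotas are deployment
  concerns.
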