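"""Run one analysis task through the self-correction loop.

A scripted mock model first returns broken code (an undefined variable),
then a corrected version — the shape of the interaction the error-feedback
loop exists to recover.  With a live endpoint you would build the agent from
an AgentSpec(backend_kind="remote", ...) instead; nothing else changes.
"""

from execbench import SelfCorrectConfig, Workspace, build_prompt_bundle, self_correct
from execbench.fixtures import make_mock_script, mock_agent_from_script

agent = mock_agent_from_script(make_mock_script("fail_then_fix", "python"))
bundle = build_prompt_bundle("simple", "Compute the mean of the numbers 1 to 4.",
                             target_code_language="Python")
workspace = Workspace.create()

result = self_correct(agent, bundle, workspace,
                      SelfCorrectConfig(language_backend="python"))

print(f"success:        {result.success}")
print(f"attempts used:  {result.attempts_used}")
print(f"first error:    {result.per_attempt[0].result.error_text.splitlines()[-1]}")
print(f"final code:\n{result.final_code}")
print(f"final stdout:   {result.per_attempt[-1].result.stdout_text.strip()}")

# The loop needed two attempts: the first execution raised a NameError, the
# error text was embedded in a correction prompt, and the second reply ran
# cleanly (mean of 1..4 = 2.5).
workspace.cleanup()
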