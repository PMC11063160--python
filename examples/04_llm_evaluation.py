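"""Prompt construction, response classification, and benchmark evaluation.

Builds the two-round standard prompt for a fly protein, classifies a batch
of simulated answer texts with the key-phrase lexicons, and evaluates
gene-level calls against a benchmark with resampled specificity.
"""

import numpy as np

from vtlkit.llm_eval import (
    build_cot_prompt,
    build_standard_prompt,
    classify_interpretation_response,
    evaluate_predictions,
    positive_response_rate,
    resampled_specificity,
)
from vtlkit.synthetic import simulate_responses

round1, round2 = build_standard_prompt(
    "Dop1R1 (Dopamine 1-like receptor 1, isoform E)", "sleep"
)
print("round-1 prompt:\n ", round1)
print("round-2 prompt (first line):\n ", round2.split("\n")[0][:90], "...")
print("\npairwise CoT prompt:\n ",
      build_cot_prompt("mre11 is a DNA damage repair gene.",
                       "Dop1R1 is a dopamine receptor.")[:100], "...")

# Simulated genome-wide answers with a known 12.5 % positive rate.
responses = simulate_responses(4000, positive_rate=0.125, mode="interpretation", seed=3)
rates = positive_response_rate(responses)
print(f"\npositive response rate (sleep): {100 * rates['sleep']:.1f} %")

# Benchmark evaluation: 200 known genes, a classifier that recalls 25 % of
# them and false-alarms on 7 % of unreported genes.
rng = np.random.default_rng(0)
benchmark = [f"known{i}" for i in range(200)]
pool = [f"unreported{i}" for i in range(3000)]
preds = {g: bool(rng.random() < 0.25) for g in benchmark}
preds |= {g: bool(rng.random() < 0.07) for g in pool}

_, metrics = evaluate_predictions(preds, benchmark, [])
res = resampled_specificity(preds, pool, len(benchmark), rounds=20, seed=1,
                            positive_benchmark=benchmark)
print(f"Sn = {100 * metrics.sn:.1f} %  (fraction of benchmark genes recalled)")
print(f"mean Sp over 20 resampling rounds = {100 * res['sp_mean']:.1f} %")
print(f"mean Ac = {100 * res['ac_mean']:.1f} %  (equals (Sn + Sp) / 2 under 1:1 design)")
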