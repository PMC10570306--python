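"""Select a minimal discriminative protein signature by repeated RFE.

Fifteen planted proteins separate the five disease/mutation groups; repeated
split -> CV-RFE-to-30 -> MLP runs aggregate per-protein selection
frequencies, and the signature is the set selected in >= 85% of runs.
(Scaled here to 8 runs / 120 proteins so the example finishes in seconds;
the library defaults are 100 runs with a threshold of 85.)
"""

from pharmotype import signature as sig
from pharmotype.synth import scenarios, simulate_cohort, simulate_proteomes

config = scenarios.signature_scenario(n_per_class=12, n_proteins=120)
clinical = simulate_cohort(config, seed=3)
matrices, _ = simulate_proteomes(clinical, config, seed=3)
labels = clinical.set_index("patient_id")["group"]

result = sig.select_signature(matrices["granulocyte"], labels,
                              n_runs=8, min_freq=7, base_seed=3)
print("test-score summary over runs:")
print(result.score_summary.round(3).to_string())
top = result.frequencies.sort_values(ascending=False).head(20)
print("\nselection frequencies (top 20):")
print(top.to_string())
print(f"\nsignature (>= {result.min_freq}/{result.n_runs} runs): "
      f"{result.signature}")
planted = [f"SIG{i:02d}" for i in range(1, 16)]
recall = len(set(planted) & set(result.signature)) / len(planted)
print(f"planted-protein recall: {recall:.2f}")
# The 15 planted proteins dominate the frequency ranking; noise proteins fill
# the remaining RFE slots less consistently. At this 8-run toy scale a noise
# protein can still clear the bar by chance; the 100-run default with the
# 85-run threshold separates planted from noise cleanly.
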