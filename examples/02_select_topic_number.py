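"""Topic-number selection via the training-perplexity curve.

Fits one model per candidate K, computes perplexity (exponentiated
negative mean per-token predictive log-probability; lower is better) and
applies the first-inflection rule: the interior K with the largest
positive second difference of the curve.  On data generated by this model
family the curve is typically flat-to-increasing in K — the per-(topic,
timestamp) activity distributions already give a one-topic model the full
per-day predictive power — so treat the selected K as a diagnostic, not
an oracle (see docs/methods.md).
"""

from ttmpath import Hyperparams, generate_corpus, select_topic_number, standard_scenario

sim = generate_corpus(standard_scenario("radiotherapy-like",
                                        n_processes=100), seed=3)
template = Hyperparams(n_topics=2, iterations=200, burn_in=50)
result = select_topic_number(sim.corpus, range(2, 7), template,
                             seeds=[0, 1])

print(result.curve.to_frame().to_string(index=False))
print(f"selected K = {result.k_star}"
      + (" (no clear knee; smallest K reported)" if result.flagged else ""))
print()
print("Each row is the mean training perplexity over the replicate seeds; "
      "'sd' is the spread across seeds (Monte-Carlo noise).")
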