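"""Score discovered topics against expert relevance judgements (NKQM@N).

Domain experts rate each topic's top-ranked activities as very relevant
(2), relevant (1) or not relevant (0); three raters are combined by
majority vote.  NKQM@N is the mean over topics of the discounted
cumulative score of the top N activities, normalised by the ideal all-2
ranking, so 1.0 means every top activity was judged very relevant.
"""

from ttmpath import ScoreTable, majority_vote, nkqm, nkqm_report

# three raters scoring the top 5 activities of two topics
rater1 = [2, 2, 1, 0, 0, 2, 1, 1, 0, 0]
rater2 = [2, 1, 1, 1, 0, 2, 2, 1, 0, 1]
rater3 = [2, 2, 0, 1, 2, 1, 2, 0, 0, 1]

combined = majority_vote(rater1, rater2, rater3)
table = ScoreTable((combined[:5], combined[5:]))
print("majority-vote scores per topic:", table.scores)
for n in (3, 5):
    print(f"NKQM@{n} = {nkqm(table, n):.4f}")
print()
print(nkqm_report(table, (3, 5)).to_string(index=False))
print()
print("Higher is better; the discount log2(rank+1) weights early ranks "
      "most, so a topic whose first activities are judged very relevant "
      "scores close to 1 even if deep ranks are noisy.")
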