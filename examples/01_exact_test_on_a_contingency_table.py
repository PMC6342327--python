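"""Exact test and conditional-MLE odds ratio for one drug's 2x2 table.

A drug with 216 targets in a 2,825-term gene universe, 66 of them
ageing-related out of 454 ageing terms, gives the table
[[66, 150], [388, 2221]].  The p-value is the chance of hitting at least
66 ageing terms; the odds ratio is the enrichment effect size; the
BY-adjusted value corrects for testing 1,147 drugs.
"""

from gerotarget import adjust_by, conditional_mle_odds_ratio, fisher_exact

k, l, m, n = 66, 150, 388, 2221

p = fisher_exact(k, l, m, n)
est = conditional_mle_odds_ratio(k, l, m, n)
adj = adjust_by([p], total_tests=1147)[0]

print(f"contingency table  k={k} l={l} m={m} n={n}")
print(f"exact-test p       {p:.2E}   (upper-tail Fisher)")
print(f"odds ratio (cMLE)  {est:.2f}     (>1 means ageing-enriched)")
print(f"BY-adjusted p      {adj:.2E}   (family of 1,147 drugs)")
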