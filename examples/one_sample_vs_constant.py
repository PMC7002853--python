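"""Effect size of the difference between a sample mean and a known constant.

Compares the sample (0, 0, 1, 2, 2) with the constant 2 — e.g. a simulated
quantity against its theoretical optimum — reporting both the uncorrected
statistic and the unbiased estimator c, with a 99% confidence interval.
"""

from meandiff import estimate_c, summarize

sample = summarize([0, 0, 1, 2, 2])

biased = estimate_c(sample, 2.0, alpha=0.01, unbiased=False)
unbiased = estimate_c(sample, 2.0, alpha=0.01, unbiased=True)

print("uncorrected:", [round(v, 7) for v in biased.as_vector()])
print("unbiased c: ", [round(v, 7) for v in unbiased.as_vector()])

# The four numbers are: estimate, sampling variance, CI lower, CI upper.
# The unbiased values are the uncorrected ones scaled by J(n-1) < 1, which
# removes the small-sample overestimation of the magnitude.
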