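"""Default (JZS) Bayes factors for t designs.

The default Bayes factor places a Cauchy prior (scale r = .707) on the
standardised effect size and integrates it out numerically.  BF10 > 1 favours
the alternative; its reciprocal BF01 favours the null.
"""

import numpy as np

from predlearn import jzs_bf, t_test

# The three test-trial comparisons, from their paired t statistics (n = 18).
for t in (3.73, 1.30, 1.50):
    res = jzs_bf(t, 18)
    print(f"t(17) = {t:4.2f}  ->  {res.report()}")

# The same machinery on data: a paired comparison with a genuine effect.
rng = np.random.default_rng(3)
correlated = 0.13 + rng.normal(0, 0.03, 18)
uncorrelated = 0.07 + rng.normal(0, 0.03, 18)
tt = t_test(correlated, uncorrelated, design="paired")
bf = jzs_bf(tt.t, tt.n)
print(f"\nsimulated dwell data: t({tt.df}) = {tt.t:.2f}, p = {tt.p:.4f}, "
      f"{bf.report()}")
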