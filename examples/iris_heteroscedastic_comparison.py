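"""Compare d and e across the embedded Iris measurements.

The three Iris species have clearly unequal spreads, so this is a natural
testbed for the heteroscedastic effect size: for every species pair and
measurement the script prints d, e, their ratio and the SD ratio.  The
further the SD ratio is from 1, the more d and e diverge.
"""

from itertools import combinations

from meandiff import TwoSampleDesign, estimate_d, estimate_e, iris_group
from meandiff.datasets import MEASUREMENTS, SPECIES

print(f"{'measurement':<14}{'pair':<26}{'d':>8}{'e':>8}{'d/e':>10}{'sd ratio':>10}")
for meas in MEASUREMENTS:
    for sp1, sp2 in combinations(SPECIES, 2):
        design = TwoSampleDesign.from_data(iris_group(sp1, meas), iris_group(sp2, meas))
        d = estimate_d(design).value
        e = estimate_e(design).value
        sd_ratio = design.group1.sd / design.group2.sd
        print(
            f"{meas:<14}{sp1 + ' vs ' + sp2:<26}"
            f"{d:>8.2f}{e:>8.2f}{d / e:>10.6f}{sd_ratio:>10.6f}"
        )
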