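"""Why gene flow shuts down at 2-10% divergence: MEPS availability.

Homologous recombination needs a strictly identical DNA segment (MEPS,
~20-100 bp) to initiate. Counting identical segments between simulated
sequence pairs shows their density collapsing as (1 - d)^L with
divergence d — the proposed mechanism for bacterial species boundaries.
"""

import coreflow as cf

LENGTH = 100_000
print(f"identical segments shared by {LENGTH//1000}-kb sequence pairs (one replicate):")
print()
print("divergence   L=20bp (sim / expected)    L=40bp (sim / expected)")
for d in (0.01, 0.02, 0.05, 0.10):
    pair = cf.simulate_pair(100 * (1 - d), LENGTH, seed=1)
    row = [f"{d:8.2f}"]
    for L in (20, 40):
        sim = cf.count_identical_segments(pair, L)
        exp = cf.expected_identical_fraction(d, L, LENGTH)
        row.append(f"{sim:8d} / {exp:9.0f}")
    print("   ".join(row))
print()
ratio = cf.expected_identical_fraction(0.10, 40, LENGTH) / cf.expected_identical_fraction(
    0.02, 40, LENGTH
)
print(
    f"Moving from 2% to 10% divergence cuts 40-bp MEPS availability to\n"
    f"{100 * ratio:.1f}% of its former level ((0.90/0.98)^40) - an exponential\n"
    "collapse that interrupts gene flow over a narrow divergence range."
)
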