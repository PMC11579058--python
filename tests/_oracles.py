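"""Independent brute-force oracles used by the test suite.

These deliberately avoid numpy vectorisation and any code sharing with the
package: plain-Python loops re-implementing the documented rules, so that
agreement is a genuine cross-check.
"""

import math


def brute_force_threshold(counts, k_sigma=3.0, sd_mode="poisson"):
    """Naive iterative mean + k·SD background loop.

    Returns (background_index_set, mean, sd, n_iterations).
    """
    background = set(range(len(counts)))
    iteration = 0
    while True:
        iteration += 1
        values = [counts[i] for i in sorted(background)]
        if len(values) < 2:
            raise ValueError("no background remains")
        mean = sum(values) / len(values)
        if sd_mode == "poisson":
            sd = math.sqrt(mean)
        else:
            var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
            sd = math.sqrt(var)
        threshold = mean + k_sigma * sd
        removed = {i for i in background if counts[i] > threshold}
        if not removed:
            return background, mean, sd, iteration
        background -= removed


def brute_force_events(counts, threshold, background_mean, merge_gap=0):
    """Naive event grouping: runs of above-threshold dwells, allowing up to
    merge_gap below-threshold dwells inside a run."""
    above = [i for i, c in enumerate(counts) if c > threshold]
    events = []
    for i in above:
        if events and i - events[-1][-1] <= merge_gap + 1:
            events[-1].append(i)
        else:
            events.append([i])
    out = []
    for run in events:
        lo, hi = run[0], run[-1]
        raw = sum(counts[lo : hi + 1])
        net = max(raw - (hi - lo + 1) * background_mean, 0.0)
        out.append((lo, hi - lo + 1, raw, net))
    return out
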