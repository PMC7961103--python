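"""Shared brute-force oracles used by the acceptance checks."""

import numpy as np


def brute_force_alignment(dataset, rel_thresh, min_freq, tol_ppm):
    """O(n^2) replica of the greedy seed-by-intensity alignment rule."""
    base = max(s.intensities.max() for s in dataset if len(s))
    floor = rel_thresh * base
    peaks = [
        (float(m), float(i), px)
        for px, s in enumerate(dataset)
        for m, i in zip(s.mz, s.intensities)
        if i >= floor
    ]
    features = []
    remaining = list(peaks)
    while remaining:
        seed = max(remaining, key=lambda p: p[1])
        members = [
            p for p in remaining if abs(p[0] - seed[0]) / seed[0] * 1e6 <= tol_ppm
        ]
        remaining = [p for p in remaining if p not in members]
        w = sum(p[1] for p in members)
        cmz = sum(p[0] * p[1] for p in members) / w
        vec = np.zeros(len(dataset))
        for m, i, px in members:
            vec[px] += i
        features.append((cmz, vec))
    kept = [f for f in features if (f[1] > 0).mean() >= min_freq]
    kept.sort(key=lambda f: f[0])
    return kept
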