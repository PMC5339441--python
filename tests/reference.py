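"""Independent brute-force reference implementations used as test oracles.

Deliberately written with explicit loops and no vectorisation so they stay
independent of the package's implementation choices.
"""


def brute_force_states(accel, threshold=-0.75):
    return [1 if a > threshold else 0 for a in accel]


def brute_force_smooth(states, half=15, include_center=True):
    n = len(states)
    out = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        window = states[lo:hi]
        lying = sum(window)
        total = len(window)
        if not include_center:
            lying -= states[i]
            total -= 1
        if 2 * lying > total:
            out.append(1)
        elif 2 * lying < total:
            out.append(0)
        else:
            out.append(states[i])
    return out


def brute_force_segments(states, min_dur=30):
    bouts = []
    i, n = 0, len(states)
    while i < n:
        if states[i] == 1:
            j = i
            while j < n and states[j] == 1:
                j += 1
            if j - i >= min_dur:
                bouts.append((i, j))
            i = j
        else:
            i += 1
    return bouts


def brute_force_detect(accel, threshold=-0.75, half=15, min_dur=30):
    """Full single-pass reference detector: start/end index pairs (half-open)."""
    return brute_force_segments(
        brute_force_smooth(brute_force_states(accel, threshold), half), min_dur
    )


def random_trace(rng, n=7200):
    """A random 2 h acceleration trace with alternating posture segments,
    heavy noise and occasional threshold-straddling wander."""
    accel = []
    lying = rng.uniform() < 0.5
    while len(accel) < n:
        seg = int(rng.exponential(300)) + 1
        level = 0.0 if lying else -1.0
        sd = rng.uniform(0.02, 0.3)
        accel.extend(level + rng.normal(0, sd, size=seg))
        if rng.uniform() < 0.1:  # wander near the threshold
            accel.extend(-0.75 + rng.normal(0, 0.05, size=int(rng.integers(1, 60))))
        lying = not lying
    return accel[:n]
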