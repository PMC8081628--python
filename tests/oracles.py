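"""Independent brute-force oracles for the landmark operators.

These enumerate definitions directly (window maxima, rotated-ruler argmax)
without sharing code with the implementation under test.
"""

import math


def brute_tip_tops(profile: dict, K: int, min_prominence: float = 3.0):
    """All interior window-max points of a {x: h} profile, ties collapsed.

    Returns a list of (x, h): a column qualifies iff its height equals the
    maximum over in-domain columns within [x-K, x+K] and it is not the first
    or last column of the domain; consecutive qualifying columns with equal
    height collapse to the middle column of the run, and runs wider than the
    full window (2K+1 columns) are ridges, not tips, and are dropped.
    """
    xs = sorted(profile)
    if len(xs) < 3:
        return []
    qualifying = []
    for x in xs[1:-1]:
        window = [profile[c] for c in xs if abs(c - x) <= K]
        if profile[x] >= max(window):
            qualifying.append(x)
    out = []
    i = 0
    while i < len(qualifying):
        j = i
        while (
            j + 1 < len(qualifying)
            and qualifying[j + 1] == qualifying[j] + 1
            and profile[qualifying[j + 1]] == profile[qualifying[i]]
        ):
            j += 1
        run = qualifying[i:j + 1]
        if len(run) <= 2 * K + 1:
            span = [profile[c] for c in xs
                    if run[0] - K <= c <= run[-1] + K]
            if profile[run[0]] - min(span) >= min_prominence:
                mid = run[(len(run) - 1) // 2]
                out.append((mid, profile[mid]))
        i = j + 1
    return out


def brute_tangent(candidates, side: str):
    """Rotated-ruler argmax over explicit (x, h) candidates at theta = 45 deg.

    B_left = (h - x) cos45, B_right = (h + x) cos45; ties break to the
    outermost x for the given side.
    """
    c = math.cos(math.radians(45.0))
    sign = -1.0 if side == "left" else 1.0
    best = None
    for x, h in candidates:
        score = (h + sign * x) * c
        if best is None or score > best[0]:
            best = (score, x, h)
        elif score == best[0]:
            outer = x < best[1] if side == "left" else x > best[1]
            if outer:
                best = (score, x, h)
    return (best[1], best[2]) if best else None
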