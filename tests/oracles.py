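"""Independent brute-force oracles used only by the tests.

Each is a direct transcription of the defining formula, written as plain
loops over templates/boxes so it shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def apen_bruteforce(x, m: int, r: float) -> float:
    """Approximate entropy by direct O(N^2) template counting, self-matches in."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm: int) -> float:
        n_templ = n - mm + 1
        logs = []
        for i in range(n_templ):
            count = 0
            for j in range(n_templ):
                d = max(abs(x[i + k] - x[j + k]) for k in range(mm))
                if d <= r:
                    count += 1
            logs.append(math.log(count / n_templ))
        return sum(logs) / n_templ

    return phi(m) - phi(m + 1)


def sampen_bruteforce(x, m: int, r: float) -> float:
    """Sample entropy by direct ordered-pair counting, self-matches excluded."""
    x = list(map(float, x))
    n = len(x)
    n_templ = n - m  # same template count for both lengths
    b = a = 0
    for i in range(n_templ):
        for j in range(n_templ):
            if i == j:
                continue
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm <= r:
                b += 1
                dm1 = max(dm, abs(x[i + m] - x[j + m]))
                if dm1 <= r:
                    a += 1
    if a == 0:
        return float("nan")
    return -math.log(a / b)


def dfa_fluctuations(x, n_values) -> list[float]:
    """Textbook DFA F(n): integrate, box-wise polyfit detrend, RMS residual."""
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - x.mean())
    out = []
    for n in n_values:
        n_boxes = len(y) // n
        resid_sq = []
        for b in range(n_boxes):
            seg = y[b * n: (b + 1) * n]
            t = np.arange(n)
            coef = np.polyfit(t, seg, 1)
            trend = np.polyval(coef, t)
            resid_sq.extend((seg - trend) ** 2)
        out.append(float(np.sqrt(np.mean(resid_sq))))
    return out


def dfa_alpha(x, lo: int, hi: int) -> float:
    ns = list(range(lo, hi + 1))
    fl = dfa_fluctuations(x, ns)
    return float(np.polyfit(np.log(ns), np.log(fl), 1)[0])


def tinn_exhaustive(counts, centers, bin_width: float, extend: int = 0) -> float:
    """Grid search for the best-fit triangle baseline width M - N.

    Evaluates the integrated squared error of every bin-aligned (N, M)
    pair at the bin centers, the mode bin apex fixed.
    """
    counts = np.asarray(counts, dtype=float)
    centers = np.asarray(centers, dtype=float)
    mode = int(np.argmax(counts))
    X, Y = centers[mode], counts[mode]
    lo = centers[0] - extend * bin_width
    hi = centers[-1] + extend * bin_width
    grid = np.arange(lo, hi + bin_width / 2, bin_width)
    cvals = np.zeros(grid.size)
    for c, v in zip(centers, counts):
        cvals[int(round((c - lo) / bin_width))] = v
    best_err, best_w = float("inf"), 0.0
    for N in grid[grid <= X]:
        for M in grid[grid >= X]:
            if M <= N:
                continue
            err = 0.0
            for g, v in zip(grid, cvals):
                if g < N or g > M:
                    t = 0.0
                elif g <= X:
                    t = Y * (g - N) / (X - N) if X > N else Y
                else:
                    t = Y * (M - g) / (M - X)
                err += (v - t) ** 2
            if err < best_err - 1e-12:
                best_err, best_w = err, M - N
    return best_w


def berger_value(beat_times, t: float, fs_out: float) -> float:
    """Directly evaluate one Berger sample: fractional intervals in the window."""
    h = 1.0 / fs_out
    lo, hi = t - h, t + h
    count = 0.0
    for a, b in zip(beat_times[:-1], beat_times[1:]):
        overlap = max(0.0, min(b, hi) - max(a, lo))
        if overlap > 0:
            count += overlap / (b - a)
    rate = fs_out / 2.0 * count
    return 1000.0 / rate
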