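"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — direct enumeration or definition-level
computation — and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata

from mirclip.seedscan import EIGHTMER, SEVENMER_A1, SEVENMER_M8, SeedDescriptor


def naive_scan(seq: str, sd: SeedDescriptor) -> list[tuple[int, str]]:
    """Enumerate every pattern substring, then apply 8mer dominance."""
    seq = seq.upper().replace("U", "T")
    raw: list[tuple[int, str]] = []
    for stype in (EIGHTMER, SEVENMER_M8, SEVENMER_A1):
        pat = sd.patterns[stype]
        for i in range(len(seq) - len(pat) + 1):
            if seq[i:i + len(pat)] == pat:
                raw.append((i, stype))
    eight = {i for i, t in raw if t == EIGHTMER}
    out = []
    for i, t in raw:
        if t == SEVENMER_M8 and i in eight:
            continue
        if t == SEVENMER_A1 and (i - 1) in eight:
            continue
        if (t == SEVENMER_A1 and sd.patterns[SEVENMER_A1] == sd.patterns[SEVENMER_M8]):
            continue  # identical patterns collapse onto the stronger class
        out.append((i, t))
    return sorted(out)


def find_offsets(seq: str, pattern: str) -> list[int]:
    return [i for i in range(len(seq) - len(pattern) + 1)
            if seq[i:i + len(pattern)] == pattern]


def mannwhitney_enumeration(x, y) -> tuple[float, float]:
    """Two-sided exact p by enumerating every group relabelling.

    U is computed through midranks (a different route than pair counting).
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = np.array(x + y, float)

    def u_of(idx: tuple[int, ...]) -> float:
        ranks = rankdata(pooled)
        r1 = sum(ranks[i] for i in idx)
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_of(tuple(range(n1)))
    mu = n1 * n2 / 2
    total = extreme = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(comb) - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def enrichment_brute(scores: np.ndarray, hit: np.ndarray, w: float = 1.0
                     ) -> tuple[float, np.ndarray]:
    """Direct summation of the weighted running statistic."""
    n = len(scores)
    nh = int(hit.sum())
    denom_hit = float(np.sum(np.abs(scores[hit]) ** w))
    run = [0.0]
    for i in range(n):
        if hit[i]:
            step = (np.abs(scores[i]) ** w / denom_hit if denom_hit > 0
                    else 1.0 / nh)
        else:
            step = -1.0 / (n - nh)
        run.append(run[-1] + step)
    run = np.array(run)
    return float(run[np.argmax(np.abs(run))]), run


def ecdf_sup(a, b) -> float:
    """sup |ECDF_a - ECDF_b| over the pooled sample points."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    grid = np.concatenate([a, b])
    d = 0.0
    for t in grid:
        d = max(d, abs((a <= t).mean() - (b <= t).mean()))
    return d
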