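"""Independent brute-force oracles used by the equivalence tests.

Everything here is written as plain loops from first principles and stays
independent of the library code paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata


def brute_qc_survivors(values: np.ndarray, cells: list[str], min_umi: int, max_umi: int) -> list[str]:
    """Scan every cell's column sum against the strict UMI bounds."""
    survivors = []
    for j, cell in enumerate(cells):
        total = 0.0
        for i in range(values.shape[0]):
            total += values[i, j]
        if not (total < min_umi or total > max_umi):
            survivors.append(cell)
    return survivors


def brute_pathway_mean(values: np.ndarray, genes: list[str], member_genes: list[str]) -> float:
    """Mean over member genes of the mean over all cells (double loop)."""
    gene_means = []
    for gene in member_genes:
        if gene not in genes:
            continue
        row = genes.index(gene)
        total = 0.0
        for j in range(values.shape[1]):
            total += values[row, j]
        gene_means.append(total / values.shape[1])
    return sum(gene_means) / len(gene_means)


def brute_coexpression_count(a: np.ndarray, b: np.ndarray, threshold: float) -> int:
    n = 0
    for x, y in zip(a, b):
        if x > threshold and y > threshold:
            n += 1
    return n


def brute_wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p: normal approximation with tie and continuity
    correction, derived from the rank-sum definition."""
    n1, n2 = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    sd = np.sqrt(n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1))))
    if sd == 0:
        return 1.0
    u = max(u1, n1 * n2 - u1)
    z = (u - n1 * n2 / 2 - 0.5) / sd
    return float(min(1.0, 2 * norm.sf(z)))


def brute_pfk_window(
    time_min: np.ndarray, a340: np.ndarray, window_minutes: float, r2_gate: float = 0.95
):
    """Enumerate every minimal window spanning >= window_minutes, OLS each,
    and apply the |slope|-max-above-gate / best-r2-fallback rule."""
    candidates = []
    for i in range(len(time_min)):
        j = None
        for k in range(i, len(time_min)):
            if time_min[k] - time_min[i] >= window_minutes:
                j = k
                break
        if j is None:
            break
        if j - i + 1 < 5:
            continue
        t = time_min[i : j + 1]
        y = a340[i : j + 1]
        slope, intercept = np.polyfit(t, y, 1)
        fitted = slope * t + intercept
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 0.0 if ss_tot == 0 else 1 - ((y - fitted) ** 2).sum() / ss_tot
        candidates.append((i, j, float(slope), float(r2)))
    gated = [c for c in candidates if c[3] >= r2_gate]
    pool = gated if gated else candidates
    if gated:
        best = max(pool, key=lambda c: (abs(c[2]), -c[0]))
    else:
        best = max(pool, key=lambda c: (c[3], -c[0]))
    return best  # (i, j, slope, r2)
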