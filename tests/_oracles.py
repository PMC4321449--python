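"""Independent explicit-loop oracles for the greedy LD procedures.

Kept deliberately naive (sets, sorted scans, no vectorization) so they share
no code path with the implementations they check.
"""


def brute_force_bins(R2, pos, threshold):
    """Greedy LD binning: most companions first, lowest position on ties."""
    m = R2.shape[0]
    unbinned = set(range(m))
    n_bins = 0
    partition = {}
    while unbinned:
        best_i, best_count = None, -1
        for i in sorted(unbinned, key=lambda i: pos[i]):
            count = sum(1 for j in unbinned if j != i and R2[i, j] > threshold)
            if count > best_count:
                best_i, best_count = i, count
        group = {best_i} | {
            j for j in unbinned if j != best_i and R2[best_i, j] > threshold
        }
        unbinned -= group
        for g in group:
            partition[g] = n_bins
        n_bins += 1
    return n_bins, partition


def brute_force_clump(pvals, pos, R2, p_max, r2_max):
    """Greedy p-ordered clumping: best p first, drop everything at r2 >= cap."""
    alive = [i for i in range(len(pvals)) if pvals[i] < p_max]
    alive.sort(key=lambda i: (pvals[i], pos[i]))
    chosen = []
    while alive:
        best = alive.pop(0)
        chosen.append(best)
        alive = [j for j in alive if R2[best, j] < r2_max]
    return chosen
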