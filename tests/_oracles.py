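"""Independent oracles shared across test modules (no package code)."""

import numpy as np


def brute_force_pi(rows, deletion):
    """O(n^2 L) nucleotide diversity with plain python loops."""
    n = len(rows)
    missing = {"-", "N"}
    if deletion == "complete":
        keep = [c for c in range(len(rows[0])) if all(r[c] not in missing for r in rows)]
        total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                d = sum(1 for c in keep if rows[i][c] != rows[j][c])
                total += d / len(keep)
    else:
        total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                cols = [
                    c
                    for c in range(len(rows[0]))
                    if rows[i][c] not in missing and rows[j][c] not in missing
                ]
                d = sum(1 for c in cols if rows[i][c] != rows[j][c])
                total += d / len(cols)
    return total / (n * (n - 1) / 2)


def random_alignment(rng, n, L, gap_rate=0.05):
    alphabet = np.array(list("ACGT"))
    base = rng.choice(alphabet, size=(n, L))
    mask = rng.random((n, L)) < gap_rate
    gaps = rng.choice(np.array(["-", "N"]), size=(n, L))
    out = np.where(mask, gaps, base)
    return tuple("".join(row) for row in out)


def random_additive_newick(rng, labels):
    """Random binary tree over labels with uniform branch lengths."""

    def build(group):
        if len(group) == 1:
            return f"{group[0]}:{rng.uniform(0.05, 0.5):.6f}"
        k = int(rng.integers(1, len(group)))
        return f"({build(group[:k])},{build(group[k:])}):{rng.uniform(0.05, 0.5):.6f}"

    shuffled = list(labels)
    rng.shuffle(shuffled)
    k = int(rng.integers(1, len(shuffled)))
    return f"({build(shuffled[:k])},{build(shuffled[k:])});"
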