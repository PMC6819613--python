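"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive results through different code
paths than the package (iterative stack evaluation, exhaustive decoding,
brute-force neighbour search) so that agreement is informative.
"""

from __future__ import annotations

import numpy as np
import pytest

from dfnforest.preprocess import OmicsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_matrix():
    """5 samples x 4 features with two missing entries."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [1.1, 2.1, 3.1, 4.1],
            [0.9, 1.9, 2.9, 3.9],
            [5.0, 6.0, 7.0, 8.0],
            [5.1, 6.1, 0.0, 8.1],
        ]
    )
    mask = np.zeros_like(values, dtype=bool)
    mask[4, 2] = True
    mask[0, 1] = True
    return OmicsMatrix(
        values=values,
        sample_ids=[f"s{i}" for i in range(5)],
        feature_ids=[f"f{j}" for j in range(4)],
        missing_mask=mask,
    )


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def stack_evaluate(tree, x) -> float:
    """Iterative post-order FNT evaluation (independent of the recursive path)."""
    x = np.asarray(x, dtype=float)
    values: dict[int, float] = {}
    stack = [(tree.root, False)]
    while stack:
        node, expanded = stack.pop()
        if node.kind == "terminal":
            values[id(node)] = float(x[node.feature_index])
            continue
        if not expanded:
            stack.append((node, True))
            for child in node.children:
                stack.append((child, False))
        else:
            net = 0.0
            for w, child in zip(node.weights, node.children):
                net += float(w) * values[id(child)]
            values[id(node)] = float(np.exp(-(((net - node.a) / node.b) ** 2)))
    return values[id(tree.root)]


def brute_force_decode_and_vote(code, class_matrices) -> np.ndarray:
    """Exhaustive nearest-codeword decode per forest + explicit vote count."""
    n = class_matrices[0].shape[0]
    labels = np.empty(n, dtype=int)
    for i in range(n):
        votes = []
        for cm in class_matrices:
            best_class, best_dist = None, np.inf
            for c in range(code.n_classes):
                d = float(
                    sum(
                        (cm[i, b] - code.codewords[c][b]) ** 2
                        for b in range(code.code_length)
                    )
                )
                if d < best_dist:
                    best_class, best_dist = c, d
            votes.append(best_class)
        tally = [0] * code.n_classes
        for v in votes:
            tally[v] += 1
        best = max(tally)
        labels[i] = tally.index(best)  # lowest class index on ties
    return labels


def brute_force_knn_value(values, mask, s, f, k) -> float:
    """Exhaustive-distance KNN imputation oracle for one missing entry."""
    n = values.shape[0]
    dists = []
    for j in range(n):
        if j == s:
            continue
        shared = (~mask[s]) & (~mask[j])
        d = float(np.sum((values[s, shared] - values[j, shared]) ** 2))
        dists.append((d, j))
    dists.sort(key=lambda t: (t[0], t[1]))
    neighbours = [j for _, j in dists[:k]]
    donors = [values[j, f] for j in neighbours if not mask[j, f]]
    if donors:
        return float(np.mean(donors))
    observed = [values[j, f] for j in range(n) if not mask[j, f]]
    return float(np.mean(observed))
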