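"""Independent brute-force oracles used by multiple test modules."""

import numpy as np


def greedy_match_oracle(scores, treated_ids, control_ids):
    """Direct simulation of greedy 1:1 nearest-neighbour matching.

    Treated units in decreasing score (ties by id ascending); each takes the
    unused control minimizing (|score difference|, control id).
    """
    scores = np.asarray(scores, dtype=float)
    treated_ids = np.asarray(treated_ids, dtype=int)
    control_ids = np.asarray(control_ids, dtype=int)
    order = np.lexsort((treated_ids, -scores[treated_ids]))
    unused = set(int(c) for c in control_ids)
    pairs = []
    for idx in order:
        if not unused:
            break
        t = int(treated_ids[idx])
        best = min(unused, key=lambda c: (abs(scores[c] - scores[t]), c))
        pairs.append((t, best))
        unused.remove(best)
    return pairs
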