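"""Independent brute-force re-execution of the consolidation pseudocode.

Kept deliberately naive (explicit loops, no numpy argmax) so it is a true
second implementation of the row-by-row chain rule used as a test oracle.
"""


def ca_oracle(matrix, labels, thresh):
    """Literal consolidation pass: for each row whose diagonal is below the
    threshold, map its label to the most-confused partner, chaining through
    an already-mapped partner."""
    g_map = {}
    n = len(labels)
    for r in range(n):
        if matrix[r][r] < thresh:
            best_j, best_v = None, None
            for j in range(n):
                if j == r:
                    continue
                if best_v is None or matrix[r][j] > best_v:
                    best_v = matrix[r][j]
                    best_j = j
            g_j = labels[best_j]
            if g_j not in g_map:
                g_map[labels[r]] = g_j
            else:
                g_map[labels[r]] = g_map[g_j]
    return g_map
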