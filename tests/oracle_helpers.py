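"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with naive loops (or sklearn), never
through the package's production code paths.
"""

import numpy as np

from ecg_graphnet.synthetic import CLASSES


def naive_qrs_centered_pool(H, node_types, c):
    """Loop evaluation of the QRS-centered weighted average:
    row_n = 1/(1+k+j) * sum_{i=-k..j} max(0, 1 - c|i|) * H[n+i]."""
    H = np.asarray(H, dtype=float)
    qrs = [i for i, t in enumerate(node_types) if t == "QRS"]
    m = len(node_types)
    out = []
    for b, n in enumerate(qrs):
        k = n - qrs[b - 1] if b > 0 else n
        j = qrs[b + 1] - n if b < len(qrs) - 1 else m - 1 - n
        acc = np.zeros(H.shape[1])
        for i in range(-k, j + 1):
            acc += max(0.0, 1.0 - c * abs(i)) * H[n + i]
        out.append(acc / (1 + k + j))
    return np.array(out)


def random_node_types(rng, n_beats):
    """Random chronological segment-type sequence with one QRS per beat."""
    types = []
    for _ in range(n_beats):
        if rng.random() < 0.8:
            types.append("P")
        types.append("QRS")
        if rng.random() < 0.9:
            types.append("T")
    return types


def brute_force_metrics(preds, labels):
    """Confusion counts and metrics via direct counting over flat arrays."""
    cm = np.zeros((3, 3))
    for p, y in zip(preds, labels):
        cm[y, p] += 1
    per_class = {}
    f1s = []
    for i, cls in enumerate(CLASSES):
        tp = cm[i, i]
        sn = tp / cm[i].sum() if cm[i].sum() else np.nan
        ppv = tp / cm[:, i].sum() if cm[:, i].sum() else np.nan
        if np.isnan(sn):
            f1 = np.nan
        elif np.isnan(ppv) or sn + ppv == 0:
            f1 = 0.0
        else:
            f1 = 2 * sn * ppv / (sn + ppv)
        per_class[cls] = {"sn": sn, "ppv": ppv, "f1": f1}
        if not np.isnan(f1):
            f1s.append(f1)
    acc = np.trace(cm) / cm.sum()
    return per_class, acc, float(np.mean(f1s))
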