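"""Naive scalar-loop oracles used by several test modules.

These deliberately avoid the vectorised implementation paths: attention is
evaluated score by score with explicit Python loops, and patch handling goes
through the public single-sample API.
"""

import numpy as np

from sensornet.patching import PatchTensor, extract_patches, fold_patches


def naive_attention(qp, kp, vp):
    """(C, P, B) patches -> (weights (C, C, B), attended (C, P, B))."""
    c, p, bb = qp.shape
    weights = np.zeros((c, c, bb))
    out = np.zeros_like(vp)
    for b in range(bb):
        for i in range(c):
            scores = np.empty(c)
            for j in range(c):
                s = 0.0
                for k in range(p):
                    s += (1.0 / (1.0 + np.exp(-qp[i, k, b]))) * kp[j, k, b]
                scores[j] = s
            e = np.exp(scores - scores.max())
            weights[i, :, b] = e / e.sum()
        for i in range(c):
            for k in range(p):
                out[i, k, b] = sum(weights[i, j, b] * vp[j, k, b] for j in range(c))
    return weights, out


def naive_attention_maps(q, k, v, kernel, stride):
    """(N, C, M, H, W) maps -> folded attention output, head by head."""
    n, c, m, h, w = q.shape
    out = np.zeros_like(v)
    for ni in range(n):
        for mi in range(m):
            qp = extract_patches(q[ni, :, mi], kernel, stride)
            kp = extract_patches(k[ni, :, mi], kernel, stride)
            vp = extract_patches(v[ni, :, mi], kernel, stride)
            _, attended = naive_attention(qp.values, kp.values, vp.values)
            out[ni, :, mi] = fold_patches(
                PatchTensor(attended, kernel, stride, (h, w)))
    return out
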