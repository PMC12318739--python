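"""Explicit-loop brute-force oracles for the network's core operations.

These deliberately avoid vectorized numpy computations (beyond scalar
arithmetic) so they stay independent of the implementation they check.
"""

import math


def oracle_structured_embedding(s, w1, b1, w2, b2):
    """Row-wise ReLU((row @ W1 + b1) @ W2 + b2) with explicit loops."""
    n_rows, d_in = len(s), len(s[0])
    h = len(w1[0])
    d_out = len(w2[0])
    out = []
    for r in range(n_rows):
        hidden = [sum(s[r][a] * w1[a][j] for a in range(d_in)) + b1[j]
                  for j in range(h)]
        row = [sum(hidden[j] * w2[j][k] for j in range(h)) + b2[k]
               for k in range(d_out)]
        out.append([max(0.0, v) for v in row])
    return out


def oracle_cross_attention(q, kv, wq, wk, wv, scale_dim=None):
    """softmax((Q Wq)(KV Wk)^T / sqrt(d)) (KV Wv), all with explicit loops."""
    d = len(q[0])
    scale = 1.0 / math.sqrt(scale_dim if scale_dim is not None else d)

    def matmul(x, w):
        return [[sum(x[i][a] * w[a][j] for a in range(len(w)))
                 for j in range(len(w[0]))] for i in range(len(x))]

    qp, kp, vp = matmul(q, wq), matmul(kv, wk), matmul(kv, wv)
    out = []
    for i in range(len(qp)):
        scores = [sum(qp[i][a] * kp[j][a] for a in range(d)) * scale
                  for j in range(len(kp))]
        m = max(scores)
        exps = [math.exp(v - m) for v in scores]
        z = sum(exps)
        weights = [e / z for e in exps]
        out.append([sum(weights[j] * vp[j][a] for j in range(len(vp)))
                    for a in range(d)])
    return out


def oracle_pool_and_normalize(x, gamma, beta, eps=1e-5):
    """Per-token standardization + learned affine, then token-axis mean."""
    n_tokens, d = len(x), len(x[0])
    normed = []
    for row in x:
        mu = sum(row) / d
        var = sum((v - mu) ** 2 for v in row) / d
        inv = 1.0 / math.sqrt(var + eps)
        normed.append([(v - mu) * inv * gamma[k] + beta[k]
                       for k, v in enumerate(row)])
    return [sum(normed[i][k] for i in range(n_tokens)) / n_tokens
            for k in range(d)]


def oracle_fuse_and_classify(s_final, c_final, w, b, true_label):
    """Concatenate, apply the linear head, softmax, and cross-entropy."""
    v = list(s_final) + list(c_final)
    logits = [sum(v[a] * w[a][j] for a in range(len(v))) + b[j]
              for j in range(len(b))]
    m = max(logits)
    exps = [math.exp(z - m) for z in logits]
    total = sum(exps)
    probs = [e / total for e in exps]
    loss = -math.log(probs[true_label])
    return logits, probs, loss


def oracle_metrics(tp, tn, fp, fn):
    """The five confusion-matrix metrics straight from their definitions."""
    nan = float("nan")
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total if total else nan
    precision = tp / (tp + fp) if tp + fp else nan
    sensitivity = tp / (tp + fn) if tp + fn else nan
    specificity = tn / (tn + fp) if tn + fp else nan
    if math.isnan(precision) or math.isnan(sensitivity) \
            or precision + sensitivity == 0:
        f1 = nan
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return {"accuracy": accuracy, "precision": precision,
            "sensitivity": sensitivity, "specificity": specificity, "f1": f1}
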